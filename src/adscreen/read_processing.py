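"""Assign paired-end reads to library elements by minimal edit distance.

Reads (optionally carrying UMIs) are compared against the 5' and 3' ends of
each library element; the element minimizing the summed Levenshtein distance
wins, with ties and over-threshold minima left unassigned. UMI deduplication
collapses PCR duplicates to molecule counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import edlib


@dataclass(frozen=True)
class LibraryElement:
    id: str
    dna: str
    sublibrary: str = ""
    edit_threshold: int = 2

    def __post_init__(self) -> None:
        bad = set(self.dna) - set("ACGT")
        if bad:
            raise ValueError(f"non-ACGT bases in {self.id}: {sorted(bad)}")
        if self.edit_threshold < 0:
            raise ValueError("edit_threshold must be >= 0")


@dataclass(frozen=True)
class ReadPair:
    r1: str
    r2: str
    umi: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.r1 or not self.r2:
            raise ValueError("reads must be non-empty")


UNASSIGNED = None


def levenshtein(a: str, b: str) -> int:
    """Global (NW) Levenshtein edit distance."""
    if a == b:
        return 0
    return int(edlib.align(a, b, mode="NW", task="distance")["editDistance"])


def assign_read(
    pair: ReadPair,
    library: list[LibraryElement],
    threshold: int = 2,
    perfect_only: bool = False,
) -> Optional[str]:
    """Id of the element minimizing d(r1, 5' end) + d(r2, 3' end), or None.

    Unassigned when the minimum exceeds `threshold`, when it is tied between
    two elements, or (perfect_only) when it is nonzero. r2 is expected already
    reverse-complemented into library orientation.
    """
    if not library:
        raise ValueError("library must be non-empty")
    best: Optional[str] = None
    best_d = None
    tied = False
    for el in library:
        d = levenshtein(pair.r1, el.dna[: len(pair.r1)]) + levenshtein(
            pair.r2, el.dna[len(el.dna) - len(pair.r2):]
        )
        if best_d is None or d < best_d:
            best, best_d, tied = el.id, d, False
        elif d == best_d:
            tied = True
    assert best_d is not None
    if tied or best_d > threshold or (perfect_only and best_d > 0):
        return UNASSIGNED
    return best


@dataclass
class DedupResult:
    counts: dict[str, int]
    raw_counts: dict[str, int]
    n_missing_umi: int


def dedup_umis(assignments: Iterable[tuple[str, Optional[str]]]) -> DedupResult:
    """Collapse (element, UMI) pairs to per-element molecule counts.

    Reads lacking a UMI are dropped and tallied in ``n_missing_umi``.
    """
    raw: Counter[str] = Counter()
    seen: set[tuple[str, str]] = set()
    missing = 0
    for element, umi in assignments:
        if umi is None or umi == "":
            missing += 1
            continue
        raw[element] += 1
        seen.add((element, umi))
    dedup: Counter[str] = Counter(el for el, _ in seen)
    return DedupResult(counts=dict(dedup), raw_counts=dict(raw), n_missing_umi=missing)


def process_fastq(
    fastq_r1: str,
    fastq_r2: str,
    library: list[LibraryElement],
    umi_length: int = 0,
    threshold: int = 2,
    perfect_only: bool = False,
) -> DedupResult:
    """Map a paired FASTQ file pair to library elements and deduplicate.

    The UMI is taken as the leading `umi_length` bases of read 1 and trimmed
    before assignment. Reads that fail assignment are counted under the key
    ``"*"`` in raw_counts.
    """
    from Bio import SeqIO

    assignments: list[tuple[str, Optional[str]]] = []
    unassigned = 0
    for rec1, rec2 in zip(
        SeqIO.parse(fastq_r1, "fastq"), SeqIO.parse(fastq_r2, "fastq"), strict=True
    ):
        r1, r2 = str(rec1.seq), str(rec2.seq)
        umi: Optional[str] = None
        if umi_length:
            umi, r1 = r1[:umi_length], r1[umi_length:]
        el = assign_read(ReadPair(r1, r2, umi), library, threshold, perfect_only)
        if el is UNASSIGNED:
            unassigned += 1
        else:
            assignments.append((el, umi if umi_length else f"read{len(assignments)}"))
    result = dedup_umis(assignments)
    result.raw_counts["*"] = unassigned
    return result
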