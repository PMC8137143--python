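"""Protein tiling, mutant-panel design, and constrained DNA encoding.

Proteins are fragmented into 53-aa tiles with >= 40 aa overlap, spaced as
evenly as possible. Peptides are reverse-translated under codon-usage,
GC-content, repeat and homopolymer objectives, and sets of encodings are
iteratively repaired until every pair differs by a minimum edit distance in
the read windows, so that paired-end reads map unambiguously.
"""

from __future__ import annotations

import itertools
import math
import random
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .read_processing import levenshtein
from .seq_features import AMINO_ACIDS, _check_sequence, enumerate_binary_9mers
from .tiles import Tile

TILE_LENGTH = 53
MAX_STEP = 13  # 53 - 40 aa minimum overlap

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

CODONS_FOR = defaultdict(list)
for _codon, _aa in GENETIC_CODE.items():
    CODONS_FOR[_aa].append(_codon)
CODONS_FOR = dict(CODONS_FOR)

# Default mammalian codon-usage frequencies (relative within each amino acid).
# Shipped as a sensible default; any usage table can be supplied instead.
DEFAULT_CODON_USAGE = {
    "F": {"TTT": 0.45, "TTC": 0.55},
    "L": {"TTA": 0.07, "TTG": 0.13, "CTT": 0.13, "CTC": 0.20, "CTA": 0.07, "CTG": 0.40},
    "I": {"ATT": 0.36, "ATC": 0.48, "ATA": 0.16},
    "M": {"ATG": 1.0},
    "V": {"GTT": 0.18, "GTC": 0.24, "GTA": 0.11, "GTG": 0.47},
    "S": {"TCT": 0.19, "TCC": 0.22, "TCA": 0.15, "TCG": 0.06, "AGT": 0.15, "AGC": 0.23},
    "P": {"CCT": 0.28, "CCC": 0.33, "CCA": 0.27, "CCG": 0.12},
    "T": {"ACT": 0.24, "ACC": 0.36, "ACA": 0.28, "ACG": 0.12},
    "A": {"GCT": 0.27, "GCC": 0.40, "GCA": 0.23, "GCG": 0.10},
    "Y": {"TAT": 0.43, "TAC": 0.57},
    "H": {"CAT": 0.42, "CAC": 0.58},
    "Q": {"CAA": 0.26, "CAG": 0.74},
    "N": {"AAT": 0.46, "AAC": 0.54},
    "K": {"AAA": 0.42, "AAG": 0.58},
    "D": {"GAT": 0.46, "GAC": 0.54},
    "E": {"GAA": 0.42, "GAG": 0.58},
    "C": {"TGT": 0.45, "TGC": 0.55},
    "W": {"TGG": 1.0},
    "R": {"CGT": 0.08, "CGC": 0.19, "CGA": 0.11, "CGG": 0.20, "AGA": 0.20, "AGG": 0.22},
    "G": {"GGT": 0.16, "GGC": 0.34, "GGA": 0.25, "GGG": 0.25},
}


@dataclass(frozen=True)
class TilingScheme:
    tile_length: int
    min_overlap: int
    positions: tuple[int, ...]


@dataclass(frozen=True)
class DnaDesignConstraints:
    gc_target: float = 0.45
    gc_window: int = 50
    gc_tolerance: float = 0.10
    max_repeat_len: int = 10
    homopolymer_limits: tuple[tuple[str, int], ...] = (("A", 8), ("T", 8), ("C", 5), ("G", 5))
    kmer_repeat_rules: tuple[tuple[int, int], ...] = ((3, 3), (2, 5))  # (k, n-peats)
    edit_margin: int = 6
    edit_window: int = 48


@dataclass(frozen=True)
class Violation:
    kind: str
    position: int
    span: int
    detail: str = ""


def tile_protein(protein: str, tile_length: int = TILE_LENGTH,
                 max_step: int = MAX_STEP) -> TilingScheme:
    """Evenly distributed tiling with steps of at most `max_step` residues.

    n = 1 + ceil((L - tile_length)/max_step) tiles at starts
    round(i (L - tile_length)/(n - 1)); a protein exactly one tile long gets a
    single tile. Shorter proteins are rejected.
    """
    _check_sequence(protein)
    L = len(protein)
    if L < tile_length:
        raise ValueError(f"protein length {L} below tile length {tile_length}")
    if L == tile_length:
        return TilingScheme(tile_length, tile_length - max_step, (0,))
    n = 1 + math.ceil((L - tile_length) / max_step)
    span = L - tile_length
    starts = tuple(round(i * span / (n - 1)) for i in range(n))
    return TilingScheme(tile_length, tile_length - max_step, starts)


def tiles_for_protein(protein_id: str, seq: str, sublibrary: str = "A",
                      tile_length: int = TILE_LENGTH, max_step: int = MAX_STEP) -> list[Tile]:
    scheme = tile_protein(seq, tile_length, max_step)
    return [
        Tile(protein_id, s, s + tile_length, seq[s:s + tile_length], sublibrary)
        for s in scheme.positions
    ]


def translate(dna: str) -> str:
    if len(dna) % 3:
        raise ValueError("length not a multiple of 3")
    return "".join(GENETIC_CODE[dna[i:i + 3]] for i in range(0, len(dna), 3))


def _gc(s: str) -> float:
    return (s.count("G") + s.count("C")) / len(s) if s else 0.0


def validate_constraints(dna: str, constraints: DnaDesignConstraints = DnaDesignConstraints()
                         ) -> list[Violation]:
    """All constraint violations in a DNA sequence.

    Checks global and windowed GC deviation beyond tolerance, repeated
    subsequences of length >= max_repeat_len occurring twice anywhere,
    homopolymer runs over the per-base limits, and adjacently repeated k-mers
    (3-peats of 3-mers, 5-peats of 2-mers).
    """
    bad = set(dna) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT bases: {sorted(bad)}")
    v: list[Violation] = []
    c = constraints

    if abs(_gc(dna) - c.gc_target) > c.gc_tolerance:
        v.append(Violation("gc_global", 0, len(dna), f"gc={_gc(dna):.3f}"))
    if len(dna) >= c.gc_window:
        for i in range(len(dna) - c.gc_window + 1):
            w = dna[i:i + c.gc_window]
            if abs(_gc(w) - c.gc_target) > c.gc_tolerance:
                v.append(Violation("gc_window", i, c.gc_window, f"gc={_gc(w):.3f}"))

    k = c.max_repeat_len
    seen: dict[str, int] = {}
    flagged: set[int] = set()
    for i in range(len(dna) - k + 1):
        kmer = dna[i:i + k]
        if kmer in seen and i not in flagged:
            v.append(Violation("repeat", i, k, f"also at {seen[kmer]}"))
            flagged.add(i)
        else:
            seen.setdefault(kmer, i)

    for base, limit in c.homopolymer_limits:
        run = 0
        for i, ch in enumerate(dna + "$"):
            if ch == base:
                run += 1
            else:
                if run >= limit:
                    v.append(Violation("homopolymer", i - run, run, base))
                run = 0

    for k, npeat in c.kmer_repeat_rules:
        for i in range(len(dna) - k * npeat + 1):
            unit = dna[i:i + k]
            if all(dna[i + j * k:i + (j + 1) * k] == unit for j in range(1, npeat)):
                v.append(Violation("kmer_repeat", i, k * npeat, f"{unit}x{npeat}"))
    return v


def reverse_translate(
    peptide: str,
    constraints: DnaDesignConstraints = DnaDesignConstraints(),
    rng_seed: int = 0,
    codon_usage: dict[str, dict[str, float]] = DEFAULT_CODON_USAGE,
    n_repair_sweeps: int = 30,
) -> str:
    """Encode a peptide as DNA by usage-weighted codon sampling plus local repair.

    Translation fidelity is hard; the GC/repeat/homopolymer objectives are soft:
    codons at violation sites are resampled greedily for up to
    `n_repair_sweeps` sweeps, keeping the candidate with fewest violations.
    """
    _check_sequence(peptide)
    rng = random.Random(rng_seed)

    def sample(aa: str) -> str:
        table = codon_usage[aa]
        return rng.choices(list(table), weights=list(table.values()))[0]

    # homopolymer runs are hard synthesis failures; weight them above the
    # softer GC/repeat objectives, which low-complexity peptides cannot
    # always satisfy simultaneously
    weights = {"homopolymer": 10, "gc_global": 2, "gc_window": 1,
               "repeat": 1, "kmer_repeat": 1}

    def score(violations: list[Violation]) -> int:
        return sum(weights[v.kind] for v in violations)

    codons = [sample(aa) for aa in peptide]
    best = list(codons)
    best_score = score(validate_constraints("".join(best), constraints))
    for _ in range(n_repair_sweeps):
        if best_score == 0:
            break
        dna = "".join(codons)
        violations = validate_constraints(dna, constraints)
        if not violations:
            break
        top = max(weights[v.kind] for v in violations)
        viol = rng.choice([v for v in violations if weights[v.kind] == top])
        lo = max(0, viol.position // 3 - 1)
        hi = min(len(codons), (viol.position + max(viol.span, 1)) // 3 + 2)
        for ci in range(lo, hi):
            alts = CODONS_FOR[peptide[ci]]
            if len(alts) > 1:
                codons[ci] = rng.choice([c for c in alts if c != codons[ci]])
        new_score = score(validate_constraints("".join(codons), constraints))
        if new_score < best_score:
            best, best_score = list(codons), new_score
    out = "".join(best)
    assert translate(out) == peptide
    return out


def _window_distances(a: str, b: str, window: int) -> tuple[int, int]:
    return (
        levenshtein(a[:window], b[:window]),
        levenshtein(a[-window:], b[-window:]),
    )


@dataclass
class EditDistanceReport:
    dnas: list[str]
    converged: bool
    sweeps: int
    min_head: int
    min_tail: int


def enforce_edit_distance(
    dnas: Sequence[str],
    margin: int = 6,
    window: int = 48,
    rng_seed: int = 0,
    max_sweeps: int = 100,
    codon_usage: dict[str, dict[str, float]] = DEFAULT_CODON_USAGE,
) -> EditDistanceReport:
    """Repair a set of encodings until every pair differs by >= margin edits in
    both the first and last `window` bases, without changing the peptides.

    Randomized brute-force iteration: for each offending pair, two codons in
    the head window and two in the tail window of one member are resampled
    synonymously. Fails loudly (converged=False) after `max_sweeps` sweeps.
    """
    rng = random.Random(rng_seed)
    dnas = list(dnas)
    peptides = [translate(d) for d in dnas]
    if any(len(d) < window for d in dnas):
        raise ValueError(f"all sequences must be at least {window} bases")

    def resample_codons(idx: int, head: bool) -> None:
        d = dnas[idx]
        n_codons = len(d) // 3
        if head:
            candidates = range(0, min(window // 3, n_codons))
        else:
            candidates = range(max(0, n_codons - window // 3), n_codons)
        candidates = [ci for ci in candidates if len(CODONS_FOR[peptides[idx][ci]]) > 1]
        if not candidates:
            return
        for ci in rng.sample(candidates, min(2, len(candidates))):
            alts = [c for c in CODONS_FOR[peptides[idx][ci]] if c != d[ci * 3:ci * 3 + 3]]
            d = d[: ci * 3] + rng.choice(alts) + d[ci * 3 + 3:]
        dnas[idx] = d

    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        ok = True
        for i, j in itertools.combinations(range(len(dnas)), 2):
            dh, dt = _window_distances(dnas[i], dnas[j], window)
            if dh < margin or dt < margin:
                ok = False
                victim = rng.choice([i, j])
                if dh < margin:
                    resample_codons(victim, head=True)
                if dt < margin:
                    resample_codons(victim, head=False)
        if ok:
            break
    pairs = list(itertools.combinations(range(len(dnas)), 2))
    heads = [_window_distances(dnas[i], dnas[j], window)[0] for i, j in pairs]
    tails = [_window_distances(dnas[i], dnas[j], window)[1] for i, j in pairs]
    min_head = min(heads) if heads else window
    min_tail = min(tails) if tails else window
    converged = (min_head >= margin and min_tail >= margin)
    assert [translate(d) for d in dnas] == peptides
    return EditDistanceReport(dnas, converged, sweeps, min_head, min_tail)


def verify_paired_end_distance(
    dnas: Sequence[str], read_len: int = 50, threshold: int = 6
) -> tuple[int, list[tuple[int, int]]]:
    """Minimum summed paired-end edit distance (5' read + 3' read) over all pairs.

    Returns the minimum and the offending pairs below `threshold`; a
    single-element set passes vacuously.
    """
    if any(len(d) < read_len for d in dnas):
        raise ValueError(f"all sequences must be at least {read_len} bases")
    pairs = list(itertools.combinations(range(len(dnas)), 2))
    if not pairs:
        return 2 * read_len, []
    offenders = []
    minimum = 2 * read_len
    for i, j in pairs:
        d = levenshtein(dnas[i][:read_len], dnas[j][:read_len]) + levenshtein(
            dnas[i][-read_len:], dnas[j][-read_len:]
        )
        minimum = min(minimum, d)
        if d < threshold:
            offenders.append((i, j))
    return minimum, offenders


# ---------------------------------------------------------------------------
# Mutant panels

NEUTRAL_ALPHABET = "AGSTNQV"
SHORT_CONTEXT_UP = "ASAVGQQG"  # + A or N for 9-aa inserts
SHORT_CONTEXT_DOWN = "SATQSQSNT"  # preceded by N or S for 9-aa inserts
AROMATIC = "WFY"
HYDROPHOBIC_CLASS = "WFYILM"


@dataclass(frozen=True)
class DesignedPeptide:
    sequence: str
    panel: str
    provenance: str


def _neutral(rng: random.Random, n: int) -> str:
    return "".join(rng.choices(NEUTRAL_ALPHABET, k=n))


def design_mutant_panels(
    wild_type: str,
    panel: str,
    rng_seed: int = 0,
    n_scrambles: int = 8,
    n_aromatic_subsets: int = 8,
    n_matrix_regions: int = 32,
    second_cad: Optional[str] = None,
    cad_gap: int = 5,
) -> list[DesignedPeptide]:
    """Mutant panel generator for a wild-type region.

    Panels: ``scramble`` (random permutations of the residue multiset),
    ``aromatic_subsets`` (random subsets of W/F/Y mutated to Ala, one panel per
    subset size), ``acidic_subsets`` (random subsets of D/E mutated to N/Q),
    ``d2n_e2q`` (all Asp->Asn, Glu->Gln), ``d2e`` / ``e2d`` (acidic swaps),
    ``ala_scan`` and ``alapro_scan`` (non-hydrophobic positions 4-10, 1-based,
    individually to Ala or to Ala and Pro), ``tandem_cads`` (wild type and a
    second cAD embedded in AGSTNQV neutral sequence preserving their spacing),
    ``hydrophobic_matrix`` (random 20-aa variable regions with inflated FEKR and
    WFYLM frequencies placed 5 residues upstream of the cAD in neutral context),
    ``systematic_9mers`` (all binary Asp/Leu-Phe-Trp 9-mers in the fixed 30-aa
    assay context). Panels that do not apply return an empty list.
    """
    _check_sequence(wild_type)
    rng = random.Random(rng_seed)
    out: list[DesignedPeptide] = []

    if panel == "scramble":
        for i in range(n_scrambles):
            perm = list(wild_type)
            rng.shuffle(perm)
            out.append(DesignedPeptide("".join(perm), panel, f"scramble_{i}"))

    elif panel == "aromatic_subsets":
        positions = [i for i, aa in enumerate(wild_type) if aa in AROMATIC]
        if not positions:
            return []
        for size in range(1, len(positions) + 1):
            for i in range(n_aromatic_subsets):
                subset = sorted(rng.sample(positions, size))
                seq = list(wild_type)
                for p in subset:
                    seq[p] = "A"
                out.append(
                    DesignedPeptide("".join(seq), panel, f"n{size}_set{i}_pos{subset}")
                )

    elif panel == "acidic_subsets":
        positions = [i for i, aa in enumerate(wild_type) if aa in "DE"]
        if not positions:
            return []
        swap = {"D": "N", "E": "Q"}
        for size in range(1, len(positions) + 1):
            for i in range(n_aromatic_subsets):
                subset = sorted(rng.sample(positions, size))
                seq = list(wild_type)
                for p in subset:
                    seq[p] = swap[seq[p]]
                out.append(
                    DesignedPeptide("".join(seq), panel, f"n{size}_set{i}_pos{subset}")
                )

    elif panel == "d2n_e2q":
        seq = wild_type.replace("D", "N").replace("E", "Q")
        out.append(DesignedPeptide(seq, panel, "all_acidic_neutralized"))

    elif panel == "d2e":
        out.append(DesignedPeptide(wild_type.replace("D", "E"), panel, "asp_to_glu"))

    elif panel == "e2d":
        out.append(DesignedPeptide(wild_type.replace("E", "D"), panel, "glu_to_asp"))

    elif panel in ("ala_scan", "alapro_scan"):
        subs = "A" if panel == "ala_scan" else "AP"
        # positions 4-10 (1-based) of a 13-aa core AD, excluding hydrophobics
        for i in range(3, min(10, len(wild_type))):
            if wild_type[i] in HYDROPHOBIC_CLASS:
                continue
            for sub in subs:
                if wild_type[i] == sub:
                    continue
                seq = wild_type[:i] + sub + wild_type[i + 1:]
                out.append(DesignedPeptide(seq, panel, f"pos{i}_{wild_type[i]}>{sub}"))

    elif panel == "tandem_cads":
        if second_cad is None:
            return []
        gap = cad_gap
        both = wild_type + _neutral(rng, gap) + second_cad
        only_a = wild_type + _neutral(rng, gap + len(second_cad))
        only_b = _neutral(rng, len(wild_type) + gap) + second_cad
        out.append(DesignedPeptide(both, panel, "tandem"))
        out.append(DesignedPeptide(only_a, panel, "first_alone"))
        out.append(DesignedPeptide(only_b, panel, "second_alone"))

    elif panel == "hydrophobic_matrix":
        if len(wild_type) != 13:
            return []
        # TF-like frequencies with FEKR and WFYLM inflated to widen the
        # charge/hydrophobicity range spanned by the variable regions.
        alphabet = list(AMINO_ACIDS)
        weights = [3.0 if aa in "FEKRWYLM" else 1.0 for aa in alphabet]
        for i in range(n_matrix_regions):
            var = "".join(rng.choices(alphabet, weights=weights, k=20))
            seq = var + _neutral(rng, 5) + wild_type
            pad = 53 - len(seq)
            seq = seq + _neutral(rng, pad)
            out.append(DesignedPeptide(seq, panel, f"variable_{i}_{var}"))

    elif panel == "systematic_9mers":
        # 30-aa assay context: 13-aa inserts sit between ASAVGQQG and
        # SATQSQSNT; 9-aa inserts gain the extra AN / NS context residues.
        for mer in sorted(enumerate_binary_9mers()):
            seq = SHORT_CONTEXT_UP + "AN" + mer + "NS" + SHORT_CONTEXT_DOWN
            out.append(DesignedPeptide(seq, panel, mer))

    else:
        raise ValueError(f"unknown panel {panel!r}")
    return out
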