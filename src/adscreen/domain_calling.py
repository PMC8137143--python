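"""Call activation and coactivator-binding domains from tile-level Z-scores.

Tiles covering a residue are averaged into a mean positional Z (MPZ) profile;
domains are super-threshold peaks expanded to their full width at half maximum
(FWHM), with small shoulders of larger peaks excluded. Enrichment of called
sets against shuffled draws gives the coactivator shuffle null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

#: MPZ cutoff for activation-domain calls.
AD_CUTOFF = 3.5
#: MPZ cutoff for Med15/TFIID binding-domain calls.
BINDING_CUTOFF = 2.23
#: Minimum residue overlap for an AD to count as bound by a significant tile.
MIN_OVERLAP = 26


@dataclass
class PositionalProfile:
    protein_id: str
    mpz: np.ndarray  # length = protein length; NaN where no tile covers

    def __post_init__(self) -> None:
        self.mpz = np.asarray(self.mpz, dtype=float)


@dataclass
class DomainCall:
    protein_id: str
    start: int  # 0-based half-open
    stop: int
    peak_mpz: float
    kind: Literal["AD", "Med15-binding", "TFIID-binding"] = "AD"

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.stop)


def positional_mpz(tiles: Sequence[tuple[tuple[int, int], float]], length: int,
                   protein_id: str = "") -> PositionalProfile:
    """Mean positional Z: mpz[i] = mean z over tiles whose [start, stop) covers i."""
    if not tiles:
        raise ValueError("no tiles")
    zsum = np.zeros(length)
    cover = np.zeros(length)
    for (start, stop), z in tiles:
        if not (0 <= start < stop <= length):
            raise ValueError(f"tile [{start},{stop}) outside protein of length {length}")
        zsum[start:stop] += z
        cover[start:stop] += 1
    mpz = np.full(length, np.nan)
    covered = cover > 0
    mpz[covered] = zsum[covered] / cover[covered]
    return PositionalProfile(protein_id, mpz)


def _super_threshold_runs(mpz: np.ndarray, cutoff: float) -> list[tuple[int, int]]:
    above = np.nan_to_num(mpz, nan=-np.inf) > cutoff
    runs = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def call_domains(
    profile: PositionalProfile,
    cutoff: float = AD_CUTOFF,
    kind: Literal["AD", "Med15-binding", "TFIID-binding"] = "AD",
) -> list[DomainCall]:
    """FWHM domain calls on an MPZ profile.

    Maximal runs of positions above `cutoff` seed calls, processed in decreasing
    order of peak MPZ (argmax, leftmost on ties). Each call expands outward from
    its peak to the first positions strictly below peak/2 (uncovered positions
    terminate the scan; protein ends truncate it). A call whose FWHM interval
    contains a position outside the seeding run with MPZ above the seeding peak
    is discarded — the seed was a shoulder of a larger peak. Calls overlapping a
    previously accepted call are likewise dropped so calls never overlap.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    mpz = profile.mpz
    filled = np.nan_to_num(mpz, nan=-np.inf)
    seeds = _super_threshold_runs(mpz, cutoff)
    order = sorted(seeds, key=lambda run: -filled[run[0]:run[1]].max())
    calls: list[DomainCall] = []
    for run_start, run_stop in order:
        peak_idx = run_start + int(np.argmax(filled[run_start:run_stop]))
        peak = filled[peak_idx]
        half = peak / 2.0
        left = peak_idx
        while left - 1 >= 0 and filled[left - 1] >= half:
            left -= 1
        right = peak_idx
        while right + 1 < len(mpz) and filled[right + 1] >= half:
            right += 1
        start, stop = left, right + 1
        outside = np.ones(len(mpz), dtype=bool)
        outside[run_start:run_stop] = False
        region = filled[start:stop]
        if np.any(region[outside[start:stop]] > peak):
            continue
        if any(not (stop <= c.start or start >= c.stop) for c in calls):
            continue
        calls.append(DomainCall(profile.protein_id, start, stop, float(peak), kind))
    return sorted(calls, key=lambda c: c.start)


def call_binding_domains(
    profile: PositionalProfile,
    cutoff: float = BINDING_CUTOFF,
    kind: Literal["Med15-binding", "TFIID-binding"] = "Med15-binding",
) -> list[DomainCall]:
    """Binding-domain calls: same FWHM procedure at the binding cutoff (2.23)."""
    return call_domains(profile, cutoff=cutoff, kind=kind)


def overlap_classify(
    ads: Sequence[DomainCall],
    significant_tiles: Sequence[tuple[int, int]],
    min_overlap: int = MIN_OVERLAP,
) -> list[bool]:
    """Flag each AD that overlaps any significant binding tile by >= min_overlap aa."""
    flags = []
    for ad in ads:
        hit = any(
            min(ad.stop, t_stop) - max(ad.start, t_start) >= min_overlap
            for t_start, t_stop in significant_tiles
        )
        flags.append(hit)
    return flags


@dataclass
class ShuffleEnrichment:
    fold: float
    z: float
    p: float
    null_mean: float
    null_sd: float
    valid: bool


def shuffle_enrichment(
    observed_hits: int,
    group_labels: Sequence[str],
    target_group: str,
    n_draws: int,
    n_shuffles: int = 10_000,
    rng_seed: int = 0,
) -> ShuffleEnrichment:
    """Enrichment of observed in-target hits against random draws from a pool.

    Draws `n_draws` tiles without replacement from the pool `n_shuffles` times;
    the null is the count landing in `target_group`. Fold = observed/mean(null);
    Z and one-tailed p come from the null mean and sd.
    """
    labels = np.asarray(group_labels)
    if n_draws > labels.size:
        raise ValueError("draw count exceeds pool size")
    rng = np.random.default_rng(rng_seed)
    is_target = labels == target_group
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        idx = rng.choice(labels.size, size=n_draws, replace=False)
        null[i] = is_target[idx].sum()
    mean, sd = float(null.mean()), float(null.std())
    if sd == 0:
        return ShuffleEnrichment(
            observed_hits / mean if mean else np.nan, np.nan, np.nan, mean, sd, False
        )
    z = (observed_hits - mean) / sd
    return ShuffleEnrichment(observed_hits / mean, z, float(stats.norm.sf(z)), mean, sd, True)


def calls_to_bed(calls: Sequence[DomainCall]) -> str:
    """BED-format text (0-based half-open; score = peak MPZ)."""
    lines = [
        f"{c.protein_id}\t{c.start}\t{c.stop}\t{c.kind}\t{c.peak_mpz:.3f}" for c in calls
    ]
    return "\n".join(lines) + ("\n" if lines else "")
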