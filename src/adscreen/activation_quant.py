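"""Per-fragment activation estimates from pooled sort-seq bin counts.

Cells are FACS-sorted into 8 log-spaced GFP bins and sequenced per bin; the
per-fragment GFP geometric mean is recovered as the cell-weighted average of
the bin mean log-GFP values. Fold-activation, Z and one-tailed p are computed
against a negative-control model. All logarithms are base 10.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

N_BINS = 8

#: Cell-count filter: fragments represented by fewer cells are excluded.
MIN_CELLS = 10
#: Log-scale GFP standard-deviation filter (same log10 units as bin means).
MAX_SD_LOG_GFP = 4.5
#: Upper-tail normal quantile at p = 0.001, the significance cutoff used
#: throughout (reported to two decimals).
Z_CUTOFF_P001 = 3.09


@dataclass
class BinTable:
    """Dedup read counts per fragment across 8 GFP bins + input, with sort metadata."""

    counts: pd.DataFrame  # index: fragment id; columns bin1..bin8, input
    cells_sorted: np.ndarray  # (8,) total cells sorted per bin
    events_assayed: tuple[float, float]  # events in the bins1-4 sort, bins5-8 sort
    bin_mean_log_gfp: np.ndarray  # (8,) log10 GFP per bin

    BIN_COLUMNS = [f"bin{i}" for i in range(1, N_BINS + 1)]

    def __post_init__(self) -> None:
        self.cells_sorted = np.asarray(self.cells_sorted, dtype=float)
        self.bin_mean_log_gfp = np.asarray(self.bin_mean_log_gfp, dtype=float)
        if self.cells_sorted.shape != (N_BINS,):
            raise ValueError("cells_sorted must have 8 entries")
        if np.any(np.diff(self.bin_mean_log_gfp) <= 0):
            raise ValueError("bin mean log-GFP values must be increasing")
        if (self.counts[self.BIN_COLUMNS] < 0).any().any():
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class ControlModel:
    mu: float  # mean log10 GFP of negative controls
    sigma: float  # sd of log10 GFP of negative controls
    source: Literal["external-population", "internal-controls"] = "external-population"
    excluded_ids: tuple = ()

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class ActivationEstimate:
    fragment_id: str
    n_cells: float
    mean_log_gfp: float
    sd_log_gfp: float
    fold_activation: float
    z: float
    p: float
    passed_filters: bool


def normalize_bins(table: BinTable) -> BinTable:
    """Rescale bin 5-8 cell totals by events(1-4)/events(5-8).

    The two halves of the bins were sorted in separate passes; normalizing by
    events assayed makes cell counts comparable across passes. Returns a table
    with the ratio reset to 1 so the operation is idempotent.
    """
    lo, hi = table.events_assayed
    if lo <= 0 or hi <= 0:
        raise ValueError("events assayed must be positive")
    ratio = lo / hi
    cells = table.cells_sorted.copy()
    cells[4:] *= ratio
    return BinTable(table.counts, cells, (lo, lo), table.bin_mean_log_gfp)


def estimate_fragment_cells(table: BinTable) -> pd.DataFrame:
    """Estimated cells per fragment per bin: cells_b x reads_b(F)/reads_b(total)."""
    reads = table.counts[BinTable.BIN_COLUMNS].to_numpy(dtype=float)
    totals = reads.sum(axis=0)
    bad = (totals == 0) & (table.cells_sorted > 0)
    if bad.any():
        raise ValueError(f"bins with sorted cells but zero reads: {np.flatnonzero(bad)}")
    frac = np.divide(reads, totals, out=np.zeros_like(reads), where=totals > 0)
    return pd.DataFrame(
        frac * table.cells_sorted, index=table.counts.index, columns=BinTable.BIN_COLUMNS
    )


def activation_from_bins(
    cells: np.ndarray,
    bin_mean_log_gfp: np.ndarray,
    control: ControlModel,
    fragment_id: str = "",
    min_cells: float = MIN_CELLS,
    max_sd: float = MAX_SD_LOG_GFP,
) -> ActivationEstimate:
    """Activation estimate for one fragment from its per-bin estimated cells.

    mean log-GFP is the cell-weighted average of bin means (a geometric mean of
    GFP); sd is the cell-weighted population sd. Fold = 10^(mean - mu), Z is
    standardized against the control model and p is the upper-tail normal
    probability. Fragments with < min_cells cells or sd > max_sd fail filters
    but are still reported.
    """
    cells = np.asarray(cells, dtype=float)
    logg = np.asarray(bin_mean_log_gfp, dtype=float)
    n = float(cells.sum())
    if n <= 0:
        return ActivationEstimate(fragment_id, 0.0, np.nan, np.nan, np.nan, np.nan, np.nan, False)
    mean_log = float(np.average(logg, weights=cells))
    sd_log = float(np.sqrt(np.average((logg - mean_log) ** 2, weights=cells)))
    fold = 10.0 ** (mean_log - control.mu)
    z = (mean_log - control.mu) / control.sigma
    p = float(stats.norm.sf(z))
    passed = (n >= min_cells) and (sd_log <= max_sd)
    return ActivationEstimate(fragment_id, n, mean_log, sd_log, fold, z, p, passed)


def fit_control_model(
    control_means: Sequence[float],
    mode: Literal["external", "internal"] = "internal",
    control_ids: Optional[Sequence[str]] = None,
    control_sds: Optional[Sequence[float]] = None,
    control_cells: Optional[Sequence[float]] = None,
    external_mu: Optional[float] = None,
    external_sigma: Optional[float] = None,
) -> ControlModel:
    """Negative-control GFP model, from an external population or internal controls.

    Internal mode iterates outlier exclusion to a fixed point: any control whose
    mean log-GFP lies more than 3 sd from the mean of the surviving controls is
    dropped, then mean/sd are recomputed. Final mu/sigma are the moments of the
    pooled per-cell distribution of the survivors when per-control sds and cell
    counts are supplied (mixture moments), else the moments of the surviving
    means themselves.
    """
    if mode == "external":
        if external_mu is None or external_sigma is None:
            raise ValueError("external mode requires external_mu and external_sigma")
        return ControlModel(external_mu, external_sigma, source="external-population")

    means = np.asarray(control_means, dtype=float)
    if means.size < 3:
        raise ValueError("internal mode requires at least 3 controls")
    ids = list(control_ids) if control_ids is not None else [str(i) for i in range(means.size)]
    keep = np.ones(means.size, dtype=bool)
    while True:
        m, s = means[keep].mean(), means[keep].std()
        if s == 0:
            break
        out = keep & (np.abs(means - m) > 3 * s)
        if not out.any():
            break
        keep &= ~out
        if keep.sum() == 0:
            raise ValueError("all controls excluded")

    surv = means[keep]
    if control_sds is not None and control_cells is not None:
        sds = np.asarray(control_sds, dtype=float)[keep]
        ns = np.asarray(control_cells, dtype=float)[keep]
        w = ns / ns.sum()
        mu = float(np.sum(w * surv))
        var = float(np.sum(w * (sds**2 + (surv - mu) ** 2)))
        sigma = float(np.sqrt(var))
    else:
        mu = float(surv.mean())
        sigma = float(surv.std())
    if sigma <= 0:
        raise ValueError("degenerate control distribution (sigma = 0)")
    excluded = tuple(i for i, k in zip(ids, keep) if not k)
    return ControlModel(mu, sigma, source="internal-controls", excluded_ids=excluded)


def quantify_screen(
    table: BinTable,
    control: ControlModel,
    min_cells: float = MIN_CELLS,
    max_sd: float = MAX_SD_LOG_GFP,
) -> pd.DataFrame:
    """Full bin-count -> activation-table pipeline for every fragment."""
    table = normalize_bins(table)
    cells = estimate_fragment_cells(table)
    rows = []
    for fid in cells.index:
        est = activation_from_bins(
            cells.loc[fid].to_numpy(), table.bin_mean_log_gfp, control, fid, min_cells, max_sd
        )
        rows.append(vars(est))
    return pd.DataFrame(rows).set_index("fragment_id")


def corrected_multivector_rate(
    distinct_vector_colonies: int, colonies: int, n_plasmids: int
) -> float:
    """Multiple-vector transformation rate corrected for same-plasmid co-transformation.

    Colony genotyping only detects cells that received *distinct* plasmids; under
    two independent draws from n equiprobable plasmids that happens with
    probability (n-1)/n, so the observed fraction is divided by it.
    Returns a probability; values above 1 are flagged invalid.
    """
    if colonies <= 0:
        raise ValueError("colonies must be positive")
    if n_plasmids < 2:
        raise ValueError("need at least two plasmids")
    if distinct_vector_colonies < 0:
        raise ValueError("counts must be non-negative")
    rate = (distinct_vector_colonies / colonies) / ((n_plasmids - 1) / n_plasmids)
    if rate > 1:
        raise ValueError(f"corrected rate {rate:.3f} exceeds 1: counts inconsistent")
    return rate


def enhancement_factor(fold_tandem: float, fold_a: float, fold_b: float) -> float:
    """Tandem-cAD enhancement: activation in tandem over the product of singles."""
    if min(fold_tandem, fold_a, fold_b) <= 0:
        raise ValueError("fold-activations must be positive")
    return fold_tandem / (fold_a * fold_b)
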