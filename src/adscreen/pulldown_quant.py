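"""mRNA-display pull-down quantification.

Fractional pull-down per fragment (qPCR-anchored bound/input read-fraction
ratio), enrichment against random-sequence controls with iterative outlier
exclusion, Z/p on the control log-distribution, replicate combination by
geometric mean, and the sucrose-gradient discordance artifact filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Read-count filters: fragments below either are excluded.
MIN_INPUT_READS = 30
MIN_BOUND_READS = 5

#: Discordance filter: fragments with no-gradient Z inside this window whose
#: with-gradient Z is at least DISCORDANCE_MIN_DELTA higher are artifacts.
DISCORDANCE_WINDOW = (-2.5, 1.0)
DISCORDANCE_MIN_DELTA = 3.5


@dataclass
class PulldownTable:
    """Dedup read counts for input and bound samples plus the qPCR anchor."""

    input_reads: pd.Series  # index: fragment id
    bound_reads: pd.Series
    qpcr_bound_fraction: float  # fraction of the whole library bound to beads
    replicate: str = "rep1"

    def __post_init__(self) -> None:
        if not (0 < self.qpcr_bound_fraction <= 1) and self.qpcr_bound_fraction != 0:
            raise ValueError("qpcr_bound_fraction must be in (0, 1] (or exactly 0)")
        if (self.input_reads < 0).any() or (self.bound_reads < 0).any():
            raise ValueError("read counts must be non-negative")


def fractional_pulldown(
    input_reads: float,
    bound_reads: float,
    input_total: float,
    bound_total: float,
    qpcr_bound_fraction: float,
) -> float:
    """qpcr x (bound fraction of F) / (input fraction of F). NaN if no input reads."""
    if input_reads == 0 or input_total == 0:
        return float("nan")
    bound_frac = bound_reads / bound_total if bound_total > 0 else 0.0
    input_frac = input_reads / input_total
    return qpcr_bound_fraction * bound_frac / input_frac


def _iterative_exclusion(values: np.ndarray) -> np.ndarray:
    """Boolean keep-mask after iterating the 3-sd outlier rule to a fixed point."""
    keep = np.ones(values.size, dtype=bool)
    while True:
        m, s = values[keep].mean(), values[keep].std()
        if s == 0:
            break
        out = keep & (np.abs(values - m) > 3 * s)
        if not out.any():
            break
        keep &= ~out
        if keep.sum() == 0:
            break
    return keep


def enrichment_vs_controls(
    table: PulldownTable,
    control_ids: Sequence[str],
    min_input: int = MIN_INPUT_READS,
    min_bound: int = MIN_BOUND_READS,
    excluded_control_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Binding enrichment, Z and one-tailed p for every fragment.

    Enrichment is fractional pull-down over the geometric mean of the surviving
    random controls; Z standardizes log enrichment against the control
    log-distribution. Control outliers are dropped by the iterative 3-sd rule on
    log fractional pull-down unless an explicit exclusion list (e.g. derived
    from the activation assay) is supplied. Fragments failing the read filters
    are reported with passed_filters=False.
    """
    inp, bnd = table.input_reads, table.bound_reads
    it, bt = float(inp.sum()), float(bnd.sum())
    pulldown = pd.Series(
        {
            fid: fractional_pulldown(inp.get(fid, 0), bnd.get(fid, 0), it, bt,
                                     table.qpcr_bound_fraction)
            for fid in inp.index
        }
    )

    ctrl = [c for c in control_ids if c in pulldown.index]
    ctrl_vals = pulldown.loc[ctrl]
    ok = ctrl_vals.notna() & (ctrl_vals > 0)
    ctrl = list(ctrl_vals.index[ok])
    if excluded_control_ids is not None:
        ctrl = [c for c in ctrl if c not in set(excluded_control_ids)]
        excluded = tuple(set(control_ids) - set(ctrl))
    else:
        log_ctrl = np.log10(pulldown.loc[ctrl].to_numpy(dtype=float))
        keep = _iterative_exclusion(log_ctrl)
        excluded = tuple(c for c, k in zip(ctrl, keep) if not k)
        ctrl = [c for c, k in zip(ctrl, keep) if k]
    if len(ctrl) < 3:
        raise ValueError("fewer than 3 surviving controls")

    log_ctrl = np.log10(pulldown.loc[ctrl].to_numpy(dtype=float))
    ctrl_mean = log_ctrl.mean()  # log geometric mean
    log_enrich_ctrl = log_ctrl - ctrl_mean
    # identical controls leave enrichment defined but Z/p undefined
    ctrl_sd = log_enrich_ctrl.std()

    rows = []
    for fid in pulldown.index:
        pd_f = pulldown[fid]
        enrich = 10.0 ** (np.log10(pd_f) - ctrl_mean) if pd_f > 0 else np.nan
        z = (
            np.log10(enrich) / ctrl_sd
            if ctrl_sd > 0 and enrich == enrich and enrich > 0
            else np.nan
        )
        p = float(stats.norm.sf(z)) if z == z else np.nan
        passed = (
            inp.get(fid, 0) >= min_input
            and bnd.get(fid, 0) >= min_bound
            and pd_f == pd_f
        )
        rows.append(
            {
                "fragment_id": fid,
                "fractional_pulldown": pd_f,
                "enrichment": enrich,
                "z": z,
                "p": p,
                "passed_filters": bool(passed),
                "is_control": fid in set(ctrl),
            }
        )
    out = pd.DataFrame(rows).set_index("fragment_id")
    out.attrs["excluded_controls"] = excluded
    out.attrs["control_log_mean"] = float(ctrl_mean)
    out.attrs["control_log_sd"] = float(ctrl_sd)
    return out


def combine_replicates(results: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Combine replicate enrichment tables by per-fragment geometric mean.

    Z is recomputed from the combined control log-enrichment distribution.
    Fragments filtered out of some (not all) replicates are combined from the
    remainder and flagged partial.
    """
    if not results:
        raise ValueError("no replicates")
    all_ids = sorted(set().union(*[set(r.index) for r in results]))
    rows = []
    for fid in all_ids:
        vals = []
        passed = []
        is_ctrl = False
        for r in results:
            if fid in r.index and r.loc[fid, "enrichment"] == r.loc[fid, "enrichment"]:
                if r.loc[fid, "passed_filters"]:
                    vals.append(np.log10(r.loc[fid, "enrichment"]))
                    passed.append(True)
                else:
                    passed.append(False)
                is_ctrl = is_ctrl or bool(r.loc[fid, "is_control"])
        if not vals:
            continue
        rows.append(
            {
                "fragment_id": fid,
                "enrichment": 10.0 ** float(np.mean(vals)),
                "n_replicates": len(vals),
                "partial": len(vals) < len(results),
                "is_control": is_ctrl,
            }
        )
    out = pd.DataFrame(rows).set_index("fragment_id")
    ctrl_logs = np.log10(out.loc[out["is_control"], "enrichment"].to_numpy(dtype=float))
    if ctrl_logs.size >= 3 and ctrl_logs.std() > 0:
        m, s = ctrl_logs.mean(), ctrl_logs.std()
        out["z"] = (np.log10(out["enrichment"]) - m) / s
        out["p"] = stats.norm.sf(out["z"])
    else:
        out["z"] = np.nan
        out["p"] = np.nan
    return out


def discordance_filter(
    z_with_gradient: pd.Series,
    z_without_gradient: pd.Series,
    window: tuple[float, float] = DISCORDANCE_WINDOW,
    min_delta: float = DISCORDANCE_MIN_DELTA,
) -> list[str]:
    """Fragments whose binding appears only with the sucrose gradient (artifacts).

    Excludes fragments with no-gradient Z in [window] and with-gradient Z at
    least `min_delta` higher. Fragments present in only one condition are kept.
    """
    lo, hi = window
    shared = z_with_gradient.index.intersection(z_without_gradient.index)
    out = []
    for fid in shared:
        zb = z_without_gradient[fid]
        za = z_with_gradient[fid]
        if lo <= zb <= hi and (za - zb) >= min_delta:
            out.append(fid)
    return out
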