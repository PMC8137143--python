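"""1:1 Langmuir binding kinetics for SPR sensorgrams.

Closed-form association/dissociation curves and nonlinear least-squares
fitting of (kon, koff, Rmax) with multi-start initialization, reporting the
derived KD = koff/kon and interaction half-life ln2/koff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


@dataclass
class Sensorgram:
    time: np.ndarray  # seconds, strictly increasing
    response: np.ndarray  # arbitrary response units
    t_assoc_end: float  # association-phase end time (s)
    analyte_conc: float  # M

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def assoc_mask(self) -> np.ndarray:
        return self.time <= self.t_assoc_end


@dataclass
class LangmuirFit:
    kon: float  # 1/(M s)
    koff: float  # 1/s
    rmax: float  # response units
    kd: float  # M
    half_life: float  # s
    residual: float  # sum of squared residuals
    converged: bool
    message: str = ""


def langmuir_curve(
    t: np.ndarray,
    kon: float,
    koff: float,
    rmax: float,
    conc: float,
    phase: str = "association",
    r0: float | None = None,
) -> np.ndarray:
    """Closed-form 1:1 Langmuir response.

    Association: R(t) = Req (1 - exp(-(kon C + koff) t)) with
    Req = Rmax C / (C + koff/kon). Dissociation: R(t) = R0 exp(-koff t), with t
    measured from the start of dissociation.
    """
    t = np.asarray(t, dtype=float)
    if min(kon, rmax, conc) <= 0 or koff < 0:
        raise ValueError("parameters must be positive (koff may be zero)")
    if phase == "association":
        req = rmax * conc / (conc + koff / kon)
        return req * (1.0 - np.exp(-(kon * conc + koff) * t))
    if phase == "dissociation":
        if r0 is None:
            raise ValueError("dissociation needs the starting response r0")
        return r0 * np.exp(-koff * t)
    raise ValueError(f"unknown phase {phase!r}")


def _model(theta: np.ndarray, gram: Sensorgram) -> np.ndarray:
    kon, koff, rmax = np.exp(np.clip(theta, -50, 50))
    t = gram.time
    mask = gram.assoc_mask
    out = np.empty_like(t)
    out[mask] = langmuir_curve(t[mask], kon, koff, rmax, gram.analyte_conc, "association")
    r_end = langmuir_curve(
        np.array([gram.t_assoc_end]), kon, koff, rmax, gram.analyte_conc, "association"
    )[0]
    out[~mask] = langmuir_curve(
        t[~mask] - gram.t_assoc_end, kon, koff, rmax, gram.analyte_conc, "dissociation", r0=r_end
    )
    return out


def fit_langmuir(gram: Sensorgram, n_starts: int = 5) -> LangmuirFit:
    """Jointly fit (kon, koff, rmax) to both phases by least squares.

    Parameters are fit in log space from `n_starts` log-spaced initializations
    (kon spanning 1e4-1e8 per M s, koff seeded from the dissociation decay,
    rmax from the response maximum); the lowest-residual solution wins.
    """
    mask = gram.assoc_mask
    if mask.sum() < 10 or (~mask).sum() < 10:
        raise ValueError("need at least 10 points in each phase")
    resp_max = float(gram.response.max())
    if resp_max <= 0:
        raise ValueError("sensorgram has no positive response")

    # crude koff seed from the dissociation tail's log-linear slope
    td = gram.time[~mask] - gram.t_assoc_end
    rd = gram.response[~mask]
    pos = rd > 0.01 * resp_max
    if pos.sum() >= 2:
        slope = np.polyfit(td[pos], np.log(rd[pos]), 1)[0]
        koff_seed = max(-slope, 1e-6)
    else:
        koff_seed = 1e-2

    best = None
    for kon0 in np.logspace(4, 8, n_starts):
        theta0 = np.log([kon0, koff_seed, 1.5 * resp_max])
        try:
            sol = least_squares(
                lambda th: _model(th, gram) - gram.response, theta0, method="lm",
                max_nfev=5000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return LangmuirFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False,
                           "all starts failed")
    kon, koff, rmax = np.exp(best.x)
    return LangmuirFit(
        kon=float(kon),
        koff=float(koff),
        rmax=float(rmax),
        kd=float(koff / kon),
        half_life=float(np.log(2) / koff),
        residual=float(2 * best.cost),
        converged=bool(best.success),
        message=best.message,
    )
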