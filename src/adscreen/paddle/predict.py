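"""Prediction-time procedures: tile scanning, smoothing, AD calling,
short-sequence prediction in neutral contexts, core-AD localization and
in-silico mutagenesis."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ..seq_features import _check_sequence
from .encode import TILE_LEN, encode_sequences

NEUTRAL_ALPHABET = "AGSTNQV"
#: Z cutoffs for predicted AD calling.
HIGH_Z = 6.0
MEDIUM_Z = 4.0
MIN_CONSECUTIVE_TILES = 5
MERGE_OVERLAP = 26
#: p < 0.001 upper-tail cutoff used for core-AD qualification.
CORE_Z_CUTOFF = 3.09


@dataclass
class PredictionTrack:
    protein_id: str
    raw: np.ndarray  # per-start tile Z, length L - 52
    smoothed: np.ndarray  # 9-aa centered moving average, same length


def moving_average(x: np.ndarray, window: int = 9) -> np.ndarray:
    """Centered moving average with the window truncated at the track ends."""
    x = np.asarray(x, dtype=float)
    half = window // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def predict_protein(model, protein: str, protein_id: str = "",
                    smooth_window: int = 9) -> PredictionTrack:
    """Tile a protein at 1-aa steps, predict every 53-aa tile, and smooth."""
    _check_sequence(protein)
    if len(protein) < TILE_LEN:
        raise ValueError("protein shorter than one tile: use predict_short")
    tiles = [protein[i:i + TILE_LEN] for i in range(len(protein) - TILE_LEN + 1)]
    raw = model.predict(encode_sequences(tiles))
    return PredictionTrack(protein_id, raw, moving_average(raw, smooth_window))


@dataclass
class PredictedAD:
    start: int  # residue coordinates, 0-based half-open
    stop: int
    strength: str  # "high" | "medium"
    peak_z: float


def _runs_above(z: np.ndarray, cutoff: float, min_run: int) -> list[tuple[int, int]]:
    runs = []
    i = 0
    while i < z.size:
        if z[i] > cutoff:
            j = i
            while j < z.size and z[j] > cutoff:
                j += 1
            if j - i >= min_run:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _merge(intervals: list[tuple[int, int, float]], max_overlap: int
           ) -> list[tuple[int, int, float]]:
    merged: list[list] = []
    for s, e, p in sorted(intervals):
        if merged and min(merged[-1][1], e) - max(merged[-1][0], s) > max_overlap:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = max(merged[-1][2], p)
        else:
            merged.append([s, e, p])
    return [tuple(m) for m in merged]


def call_predicted_ads(
    track: PredictionTrack,
    high_cutoff: float = HIGH_Z,
    medium_cutoff: float = MEDIUM_Z,
    min_run: int = MIN_CONSECUTIVE_TILES,
    max_overlap: int = MERGE_OVERLAP,
    tile_len: int = TILE_LEN,
) -> list[PredictedAD]:
    """Predicted AD calls from a smoothed tile-Z track.

    High-strength ADs are unions of >= min_run consecutive tile starts with
    Z above `high_cutoff` (interval = first start to last start + 53); calls
    overlapping by more than `max_overlap` aa merge. Medium-strength calls
    repeat the procedure at `medium_cutoff` and are discarded if they overlap a
    high call by more than `max_overlap` aa.
    """
    z = track.smoothed
    high_iv = [
        (s, e - 1 + tile_len, float(z[s:e].max())) for s, e in _runs_above(z, high_cutoff, min_run)
    ]
    high_iv = _merge(high_iv, max_overlap)
    calls = [PredictedAD(s, e, "high", p) for s, e, p in high_iv]
    med_iv = [
        (s, e - 1 + tile_len, float(z[s:e].max()))
        for s, e in _runs_above(z, medium_cutoff, min_run)
    ]
    med_iv = _merge(med_iv, max_overlap)
    for s, e, p in med_iv:
        if any(min(e, h.stop) - max(s, h.start) > max_overlap for h in calls):
            continue
        calls.append(PredictedAD(s, e, "medium", p))
    return sorted(calls, key=lambda c: c.start)


def _neutral_contexts(n_pad_left: int, n_pad_right: int, n_contexts: int,
                      rng: np.random.Generator) -> list[tuple[str, str]]:
    alphabet = list(NEUTRAL_ALPHABET)
    return [
        (
            "".join(rng.choice(alphabet, size=n_pad_left)),
            "".join(rng.choice(alphabet, size=n_pad_right)),
        )
        for _ in range(n_contexts)
    ]


def predict_short(
    model,
    seq: str,
    n_contexts: int = 100,
    rng_seed: int = 0,
    contexts: Optional[list[tuple[str, str]]] = None,
) -> float:
    """Predicted Z of a 5-52 aa sequence, averaged over neutral embeddings.

    The region is centered in 53-aa sequences padded with random AGSTNQV
    context; the returned Z is the mean over `n_contexts` embeddings. A
    pre-drawn `contexts` list may be shared across calls (in-silico scans).
    """
    _check_sequence(seq)
    if len(seq) >= TILE_LEN:
        raise ValueError("sequence is a full tile or longer: predict directly")
    if len(seq) < 5:
        raise ValueError("sequence must be at least 5 aa")
    pad = TILE_LEN - len(seq)
    left, right = pad // 2, pad - pad // 2
    if contexts is None:
        rng = np.random.default_rng(rng_seed)
        contexts = _neutral_contexts(left, right, n_contexts, rng)
    embedded = [lc + seq + rc for lc, rc in contexts]
    return float(model.predict(encode_sequences(embedded)).mean())


@dataclass
class CoreAD:
    start: int  # relative to the parent protein
    stop: int
    z: float


def find_core_ads(
    model,
    protein: str,
    ad_interval: tuple[int, int],
    min_len: int = 5,
    max_len: int = 30,
    z_cutoff: float = CORE_Z_CUTOFF,
    n_contexts: int = 100,
    rng_seed: int = 0,
) -> list[CoreAD]:
    """Shortest qualifying sub-tiles of an AD (predicted Z > cutoff).

    Every sub-tile of length 5-30 within the AD is scored via neutral-context
    embedding; qualifying tiles are selected shortest-first (ties: higher Z),
    skipping tiles that overlap an already-selected shorter core.
    """
    start, stop = ad_interval
    if not (0 <= start < stop <= len(protein)):
        raise ValueError("AD interval outside protein")
    region = protein[start:stop]
    candidates = []
    for length in range(min_len, min(max_len, len(region)) + 1):
        rng = np.random.default_rng(rng_seed)
        contexts = _neutral_contexts(
            (TILE_LEN - length) // 2, (TILE_LEN - length) - (TILE_LEN - length) // 2,
            n_contexts, rng,
        )
        for s in range(len(region) - length + 1):
            z = predict_short(model, region[s:s + length], contexts=contexts)
            if z > z_cutoff:
                candidates.append(CoreAD(start + s, start + s + length, z))
    selected: list[CoreAD] = []
    for c in sorted(candidates, key=lambda c: (c.stop - c.start, -c.z, c.start)):
        if any(min(c.stop, s.stop) - max(c.start, s.start) > 0 for s in selected):
            continue
        selected.append(c)
    return sorted(selected, key=lambda c: c.start)


def insilico_scan(
    model,
    core: str,
    substitution: str = "A",
    n_contexts: int = 100,
    rng_seed: int = 0,
) -> np.ndarray:
    """Per-position predicted effect of mutating to `substitution`.

    dZ[i] = Z(mutant at i) - Z(wild type), with the same neutral contexts
    shared across all positions so differences reflect only the mutation.
    Positions already equal to the substitution have dZ exactly 0.
    """
    _check_sequence(core)
    if not (5 <= len(core) <= 52):
        raise ValueError("core must be 5-52 aa")
    pad = TILE_LEN - len(core)
    rng = np.random.default_rng(rng_seed)
    contexts = _neutral_contexts(pad // 2, pad - pad // 2, n_contexts, rng)
    wt = predict_short(model, core, contexts=contexts)
    out = np.zeros(len(core))
    for i, aa in enumerate(core):
        if aa == substitution:
            continue
        mut = core[:i] + substitution + core[i + 1:]
        out[i] = predict_short(model, mut, contexts=contexts) - wt
    return out
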