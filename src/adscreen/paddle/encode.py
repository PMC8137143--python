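"""Fragment encoding for the activation predictors.

A 53-aa fragment becomes a 53 x 24 matrix: 20 one-hot residue channels plus
two secondary-structure (helix, coil) and two disorder (short, long)
probability channels from external predictors. The noSS variant uses the
53 x 20 one-hot encoding alone.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from ..seq_features import AMINO_ACIDS, _check_sequence

TILE_LEN = 53
N_ONEHOT = 20
N_FULL = 24

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def encode_fragment(
    seq: str,
    ss_track: Optional[np.ndarray] = None,
    disorder_track: Optional[np.ndarray] = None,
    variant: str = "noSS",
) -> np.ndarray:
    """Encode one 53-aa fragment as (53, 20) or (53, 24)."""
    _check_sequence(seq)
    if len(seq) != TILE_LEN:
        raise ValueError(f"fragment must be exactly {TILE_LEN} aa, got {len(seq)}")
    onehot = np.zeros((TILE_LEN, N_ONEHOT), dtype=np.float32)
    for i, aa in enumerate(seq):
        onehot[i, _AA_INDEX[aa]] = 1.0
    if variant == "noSS":
        return onehot
    if variant != "full":
        raise ValueError(f"unknown variant {variant!r}")
    if ss_track is None or disorder_track is None:
        raise ValueError("full variant requires ss and disorder tracks")
    ss = np.asarray(ss_track, dtype=np.float32)
    dis = np.asarray(disorder_track, dtype=np.float32)
    if ss.shape != (TILE_LEN, 2) or dis.shape != (TILE_LEN, 2):
        raise ValueError("tracks must be (53, 2)")
    if (ss < 0).any() or (ss > 1).any() or (dis < 0).any() or (dis > 1).any():
        raise ValueError("track probabilities must lie in [0, 1]")
    return np.concatenate([onehot, ss, dis], axis=1)


def encode_sequences(seqs: Sequence[str], variant: str = "noSS",
                     ss_tracks: Optional[Sequence[np.ndarray]] = None,
                     disorder_tracks: Optional[Sequence[np.ndarray]] = None) -> np.ndarray:
    """Stack fragment encodings into (n, 53, channels)."""
    out = []
    for i, s in enumerate(seqs):
        ss = ss_tracks[i] if ss_tracks is not None else None
        dis = disorder_tracks[i] if disorder_tracks is not None else None
        out.append(encode_fragment(s, ss, dis, variant))
    return np.stack(out)


def composition_vector(seq: str) -> np.ndarray:
    """20-element residue-proportion vector."""
    _check_sequence(seq)
    v = np.zeros(N_ONEHOT, dtype=np.float32)
    for aa in seq:
        v[_AA_INDEX[aa]] += 1.0
    return v / len(seq)


def composition_matrix(seqs: Sequence[str]) -> np.ndarray:
    return np.stack([composition_vector(s) for s in seqs])
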