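"""Sequence-level analytics for activation-domain screens.

Hydrophobic content on the Wimley-White interfacial scale, net charge,
9aaTAD motif matching, the binary Asp/hydrophobic 9-mer design space, acidic
position skew, and gapped dyad-motif association testing.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Whole-residue water -> POPC-interface transfer free energies (kcal/mol),
# Wimley & White (1996). Negative = interface-favorable (hydrophobic).
WIMLEY_WHITE_INTERFACIAL: dict[str, float] = {
    "A": 0.17, "R": 0.81, "N": 0.42, "D": 1.23, "C": -0.24,
    "Q": 0.58, "E": 2.02, "G": 0.01, "H": 0.17, "I": -0.31,
    "L": -0.56, "K": 0.99, "M": -0.23, "F": -1.13, "P": 0.45,
    "S": 0.13, "T": 0.14, "W": -1.85, "Y": -0.94, "V": 0.07,
}


@dataclass(frozen=True)
class HydrophobicityScale:
    """Per-residue transfer free energies (kcal/mol) for the 20 residues."""

    delta_g: dict[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.delta_g)
        if missing:
            raise ValueError(f"scale missing residues: {sorted(missing)}")


WW_SCALE = HydrophobicityScale(WIMLEY_WHITE_INTERFACIAL, name="wimley-white-interfacial")


def _check_sequence(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-canonical residues: {sorted(bad)}")
    return seq


def hydrophobic_content(seq: str, scale: HydrophobicityScale = WW_SCALE) -> float:
    """Total hydrophobic content of a peptide, reported as a positive magnitude.

    Sums |dG| over the residues with negative transfer free energy only, so the
    value measures the total content of hydrophobic residues rather than net
    hydrophobicity. Additive over concatenation and invariant to residue order.
    """
    _check_sequence(seq)
    return float(sum(-scale.delta_g[aa] for aa in seq if scale.delta_g[aa] < 0))


def net_charge(seq: str) -> int:
    """#Arg + #Lys - #Asp - #Glu. His and termini are not counted."""
    _check_sequence(seq)
    return seq.count("R") + seq.count("K") - seq.count("D") - seq.count("E")


# The "most stringent" 9aaTAD pattern; {X} denotes any residue NOT in X.
_9AATAD_RE = re.compile(
    "[MDENQSTYG][^KRHCGP][ILVFWM][^KRHCGP][^CGP][^KRHCGP][ILVFWM][ILVFWMAY][^KRHC]"
)


def match_9aaTAD(seq: str) -> list[int]:
    """0-based start positions of all (possibly overlapping) 9aaTAD matches."""
    _check_sequence(seq)
    return [m.start() for m in re.finditer(f"(?={_9AATAD_RE.pattern})", seq)]


def enumerate_binary_9mers() -> set[str]:
    """All 9-mers over {D,L}, {D,F} and {D,W}, deduplicated (3 x 2^9 - 2 = 1534).

    The two-element overlap is the all-D string, shared by all three alphabets.
    """
    out: set[str] = set()
    for other in "LFW":
        for combo in itertools.product("D" + other, repeat=9):
            out.add("".join(combo))
    return out


def acidic_position_skew(seq: str) -> float:
    """Mean 0-based position of Asp/Glu residues; ValueError if none present."""
    _check_sequence(seq)
    positions = [i for i, aa in enumerate(seq) if aa in "DE"]
    if not positions:
        raise ValueError("no acidic residues: skew undefined")
    return float(np.mean(positions))


@dataclass
class MotifAssociation:
    pattern: str
    n_with: int
    n_without: int
    ks_statistic: float
    p_value: float
    testable: bool


def _dyad_patterns(residue: str, max_span: int) -> list[str]:
    """All gapped patterns of 2 or 3 copies of `residue` spanning <= max_span."""
    pats = []
    for g in range(max_span - 1):
        if 2 + g <= max_span:
            pats.append(residue + "." * g + residue)
    for g1 in range(max_span - 2):
        for g2 in range(max_span - 2):
            if 3 + g1 + g2 <= max_span:
                pats.append(residue + "." * g1 + residue + "." * g2 + residue)
    return pats


def dyad_motif_association(
    seqs: Sequence[str],
    activations: Sequence[float],
    residue: str = "L",
    max_span: int = 5,
) -> list[MotifAssociation]:
    """Two-sample KS association of every gapped 2-3 copy motif with activation.

    For each pattern (e.g. ``L..LL``), sequences are split into with/without-motif
    groups and the KS statistic/p is computed on log activation. Patterns leaving
    a group empty are flagged untestable.
    """
    if len(seqs) != len(activations):
        raise ValueError("seqs and activations must align")
    log_act = np.log10(np.asarray(activations, dtype=float))
    results = []
    for pat in _dyad_patterns(residue, max_span):
        rx = re.compile(f"(?={pat})")
        has = np.array([bool(rx.search(s)) for s in seqs])
        n_with, n_without = int(has.sum()), int((~has).sum())
        if n_with == 0 or n_without == 0:
            results.append(MotifAssociation(pat, n_with, n_without, np.nan, np.nan, False))
            continue
        ks = stats.ks_2samp(log_act[has], log_act[~has])
        results.append(
            MotifAssociation(pat, n_with, n_without, float(ks.statistic), float(ks.pvalue), True)
        )
    return results


def feature_table(seqs: dict[str, str], scale: HydrophobicityScale = WW_SCALE):
    """Per-sequence feature table (id, length, hydrophobic content, charge, ...)."""
    import pandas as pd

    rows = []
    for sid, seq in seqs.items():
        try:
            skew = acidic_position_skew(seq)
        except ValueError:
            skew = np.nan
        rows.append(
            {
                "id": sid,
                "length": len(seq),
                "hydrophobic_content": hydrophobic_content(seq, scale),
                "net_charge": net_charge(seq),
                "n_matches_9aaTAD": len(match_9aaTAD(seq)),
                "acidic_skew": skew,
            }
        )
    return pd.DataFrame(rows)
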