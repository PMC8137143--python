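"""The Tile record shared by tiling, simulation and quantification stages."""

from __future__ import annotations

from dataclasses import dataclass

from .seq_features import _check_sequence


@dataclass(frozen=True)
class Tile:
    """A protein fragment: 0-based half-open coordinates on its parent protein."""

    protein_id: str
    start: int
    stop: int
    sequence: str
    sublibrary: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.stop):
            raise ValueError("require 0 <= start < stop")
        if len(self.sequence) != self.stop - self.start:
            raise ValueError("sequence length must match coordinates")
        _check_sequence(self.sequence)

    @property
    def id(self) -> str:
        return f"{self.protein_id}|{self.start}-{self.stop}"

    def overlap(self, start: int, stop: int) -> int:
        """Residue overlap with another half-open interval (0 if disjoint)."""
        return max(0, min(self.stop, stop) - max(self.start, start))
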