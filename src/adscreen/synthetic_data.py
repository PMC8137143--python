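"""Synthetic proteomes, sort-seq screens, pull-downs, reads and sensorgrams.

Emulates the statistical structure of a pooled activation-domain screen: each
fragment's GFP population is log10-normal, cells are sorted into 8 log-spaced
bins, and per-bin reads are multinomial over fragments in proportion to cell
counts. Pull-down counts are multinomial with weights shaped by a supplied
affinity model, and sensorgrams follow the closed-form 1:1 Langmuir solution
plus Gaussian noise. All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .activation_quant import BinTable, N_BINS
from .kinetics import Sensorgram, langmuir_curve
from .library_design import tiles_for_protein
from .seq_features import AMINO_ACIDS
from .tiles import Tile

# Approximate background residue frequencies of yeast transcription factors:
# S/N/Q-rich, low in C and W, as is typical for TF-disordered regions.
TF_BACKGROUND_FREQS = {
    "A": 0.07, "C": 0.01, "D": 0.05, "E": 0.06, "F": 0.04, "G": 0.05,
    "H": 0.02, "I": 0.05, "K": 0.07, "L": 0.09, "M": 0.02, "N": 0.06,
    "P": 0.05, "Q": 0.05, "R": 0.05, "S": 0.10, "T": 0.06, "V": 0.06,
    "W": 0.01, "Y": 0.03,
}

# Planted activation-domain composition: high acidic (Asp-skewed) and high
# bulky-hydrophobic content, the two features that jointly drive activation.
AD_FREQS = {
    "D": 0.25, "E": 0.10, "L": 0.15, "F": 0.10, "W": 0.08,
    "A": 0.08, "S": 0.08, "N": 0.06, "Q": 0.05, "G": 0.05,
}

MIN_AD_OVERLAP = 26  # residues a tile must share with a planted AD to inherit signal


@dataclass
class SyntheticProteome:
    proteins: list[tuple[str, str]]
    planted_domains: list[tuple[str, int, int, float]]  # (protein, start, stop, fold)

    def sequence(self, protein_id: str) -> str:
        return dict(self.proteins)[protein_id]


@dataclass
class ScreenSimulationConfig:
    n_bins: int = N_BINS
    bin_edges: Optional[np.ndarray] = None  # 9 log10-GFP edges; default derived
    background_mean_log_gfp: float = 2.0
    population_sd_log_gfp: float = 0.35
    cells_per_fragment: int = 500
    read_depth_per_bin: int = 100_000
    input_depth: int = 100_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_edges is None:
            # 8 even log10 divisions spanning below background to ~600x above
            self.bin_edges = np.linspace(
                self.background_mean_log_gfp - 0.5,
                self.background_mean_log_gfp + 2.8,
                self.n_bins + 1,
            )
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.cells_per_fragment <= 0 or self.read_depth_per_bin <= 0:
            raise ValueError("counts must be positive")


@dataclass
class KineticTruth:
    kon: float  # 1/(M s)
    koff: float  # 1/s
    rmax: float  # response units
    analyte_conc: float  # M
    noise_sd: float = 0.0  # response units

    def __post_init__(self) -> None:
        if min(self.kon, self.koff, self.rmax, self.analyte_conc) <= 0:
            raise ValueError("rates, rmax and concentration must be positive")


def _random_seq(rng: np.random.Generator, n: int, freqs: dict[str, float]) -> str:
    letters = list(freqs)
    p = np.array([freqs[a] for a in letters])
    p = p / p.sum()
    return "".join(rng.choice(letters, size=n, p=p))


def generate_proteome(
    n_proteins: int = 20,
    length_range: tuple[int, int] = (150, 600),
    ad_frequency: float = 0.5,
    fold_range: tuple[float, float] = (5.0, 200.0),
    ad_length_range: tuple[int, int] = (30, 45),
    rng_seed: int = 0,
) -> SyntheticProteome:
    """TF-like random proteome with Asp/hydrophobic-enriched planted ADs.

    Each protein carries a planted activation domain with probability
    `ad_frequency`; its true fold-activation is log-uniform in `fold_range`.
    """
    if n_proteins < 1:
        raise ValueError("need at least one protein")
    if length_range[0] < 53:
        raise ValueError("proteins must be at least one tile (53 aa) long")
    rng = np.random.default_rng(rng_seed)
    proteins = []
    planted = []
    for i in range(n_proteins):
        pid = f"prot{i:03d}"
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _random_seq(rng, L, TF_BACKGROUND_FREQS)
        if rng.random() < ad_frequency:
            ad_len = int(rng.integers(ad_length_range[0], ad_length_range[1] + 1))
            ad_len = min(ad_len, L)
            start = int(rng.integers(0, L - ad_len + 1))
            ad_seq = _random_seq(rng, ad_len, AD_FREQS)
            seq = seq[:start] + ad_seq + seq[start + ad_len:]
            fold = float(
                10 ** rng.uniform(np.log10(fold_range[0]), np.log10(fold_range[1]))
            )
            planted.append((pid, start, start + ad_len, fold))
        proteins.append((pid, seq))
    return SyntheticProteome(proteins, planted)


def tile_proteome(proteome: SyntheticProteome, sublibrary: str = "A") -> list[Tile]:
    tiles: list[Tile] = []
    for pid, seq in proteome.proteins:
        tiles.extend(tiles_for_protein(pid, seq, sublibrary))
    return tiles


def true_fold_of_tile(tile: Tile, proteome: SyntheticProteome,
                      min_overlap: int = MIN_AD_OVERLAP) -> float:
    """Ground-truth fold of a tile under the overlap rule.

    A tile overlapping a planted AD by >= min_overlap residues inherits the
    planted log10 fold scaled by the fractional overlap (graded tiling
    profiles); otherwise its fold is 1.
    """
    fold = 1.0
    for pid, start, stop, planted_fold in proteome.planted_domains:
        if pid != tile.protein_id:
            continue
        ov = tile.overlap(start, stop)
        if ov >= min_overlap:
            frac = ov / (stop - start)
            fold = max(fold, 10 ** (np.log10(planted_fold) * min(frac, 1.0)))
    return fold


def simulate_screen(
    proteome: SyntheticProteome,
    tiles: Sequence[Tile],
    config: ScreenSimulationConfig,
    true_folds: Optional[Sequence[float]] = None,
) -> tuple[BinTable, pd.DataFrame]:
    """Simulate the pooled FACS sort and per-bin sequencing of a tile library.

    Each tile's cells draw log10 GFP ~ Normal(background + log10(true fold),
    population sd) and fall into bins by the configured edges (values beyond
    the range are clipped into the end bins, as a sorter gating the full GFP
    range would). Reads per bin are multinomial over tiles proportional to
    cell counts; the input sample is multinomial proportional to total cells.
    Returns the BinTable plus a truth table (tile id, true fold, true mean).
    """
    ids = [t.id for t in tiles]
    for t in tiles:
        seq = proteome.sequence(t.protein_id)
        if t.stop > len(seq) or seq[t.start:t.stop] != t.sequence:
            raise ValueError(f"tile {t.id} not within its proteome protein")
    if true_folds is None:
        true_folds = [true_fold_of_tile(t, proteome) for t in tiles]
    rng = np.random.default_rng(config.rng_seed)
    n_tiles = len(tiles)
    edges = config.bin_edges

    cell_counts = np.zeros((n_tiles, config.n_bins), dtype=float)
    logg_sum = np.zeros(config.n_bins)
    logg_n = np.zeros(config.n_bins)
    for i, fold in enumerate(true_folds):
        mu = config.background_mean_log_gfp + np.log10(fold)
        vals = rng.normal(mu, config.population_sd_log_gfp, size=config.cells_per_fragment)
        bins = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, config.n_bins - 1)
        counts = np.bincount(bins, minlength=config.n_bins)
        cell_counts[i] = counts
        for b in range(config.n_bins):
            sel = vals[bins == b]
            logg_sum[b] += sel.sum()
            logg_n[b] += sel.size

    mid = (edges[:-1] + edges[1:]) / 2
    bin_mean = np.where(logg_n > 0, logg_sum / np.maximum(logg_n, 1), mid)
    # enforce strict monotonicity where empty bins fell back to midpoints
    for b in range(1, config.n_bins):
        if bin_mean[b] <= bin_mean[b - 1]:
            bin_mean[b] = bin_mean[b - 1] + 1e-6

    cells_sorted = cell_counts.sum(axis=0)
    reads = np.zeros((n_tiles, config.n_bins), dtype=int)
    for b in range(config.n_bins):
        total = cell_counts[:, b].sum()
        if total > 0:
            reads[:, b] = rng.multinomial(config.read_depth_per_bin, cell_counts[:, b] / total)
    input_reads = rng.multinomial(
        config.input_depth, np.full(n_tiles, 1.0 / n_tiles)
    )

    counts = pd.DataFrame(reads, index=ids, columns=BinTable.BIN_COLUMNS)
    counts["input"] = input_reads
    events = float(cells_sorted.sum())
    table = BinTable(counts, cells_sorted, (events, events), bin_mean)
    truth = pd.DataFrame(
        {
            "tile_id": ids,
            "true_fold": true_folds,
            "true_mean_log_gfp": config.background_mean_log_gfp + np.log10(true_folds),
        }
    ).set_index("tile_id")
    return table, truth


def simulate_pulldown(
    tiles: Sequence[Tile],
    affinity_model: Callable[[str], float],
    depth_input: int = 1_000_000,
    depth_bound: int = 1_000_000,
    qpcr_bound_fraction: float = 0.02,
    umi_duplication: float = 0.0,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Simulate input/bound mRNA-display sequencing counts.

    Input reads are multinomial over tiles with mild log-normal abundance
    jitter; bound reads are multinomial with weights proportional to input
    weight x affinity(sequence). With `umi_duplication` p > 0, raw read counts
    gain geometric PCR duplicates (the dedup columns stay molecule counts).
    """
    if depth_input <= 0 or depth_bound <= 0:
        raise ValueError("depths must be positive")
    rng = np.random.default_rng(rng_seed)
    ids = [t.id for t in tiles]
    n = len(tiles)
    input_w = rng.lognormal(0.0, 0.25, size=n)
    input_w /= input_w.sum()
    affinity = np.array([affinity_model(t.sequence) for t in tiles], dtype=float)
    bound_w = input_w * affinity
    bound_w /= bound_w.sum()
    input_reads = rng.multinomial(depth_input, input_w)
    bound_reads = rng.multinomial(depth_bound, bound_w)
    out = pd.DataFrame(
        {
            "input_reads": input_reads,
            "bound_reads": bound_reads,
            "true_affinity": affinity,
        },
        index=pd.Index(ids, name="tile_id"),
    )
    if umi_duplication > 0:
        dup_in = rng.geometric(1 - umi_duplication, size=n)
        dup_out = rng.geometric(1 - umi_duplication, size=n)
        out["input_raw_reads"] = input_reads * dup_in
        out["bound_raw_reads"] = bound_reads * dup_out
    out.attrs["qpcr_bound_fraction"] = qpcr_bound_fraction
    return out


def simulate_sensorgram(
    truth: KineticTruth,
    t_assoc: float = 480.0,
    t_dissoc: float = 1200.0,
    dt: float = 1.0,
    rng_seed: int = 0,
) -> Sensorgram:
    """Noisy 1:1 Langmuir sensorgram: association to t_assoc, then dissociation."""
    if min(t_assoc, t_dissoc, dt) <= 0:
        raise ValueError("durations and dt must be positive")
    rng = np.random.default_rng(rng_seed)
    t = np.arange(0.0, t_assoc + t_dissoc, dt)
    assoc = t <= t_assoc
    resp = np.empty_like(t)
    resp[assoc] = langmuir_curve(
        t[assoc], truth.kon, truth.koff, truth.rmax, truth.analyte_conc, "association"
    )
    r0 = langmuir_curve(
        np.array([t_assoc]), truth.kon, truth.koff, truth.rmax, truth.analyte_conc,
        "association",
    )[0]
    resp[~assoc] = langmuir_curve(
        t[~assoc] - t_assoc, truth.kon, truth.koff, truth.rmax, truth.analyte_conc,
        "dissociation", r0=r0,
    )
    if truth.noise_sd > 0:
        resp = resp + rng.normal(0.0, truth.noise_sd, size=resp.size)
    return Sensorgram(t, resp, t_assoc, truth.analyte_conc)


def tiles_to_fasta(tiles: Sequence[Tile], path: str) -> None:
    """Write tiles as FASTA with `protein|start-stop` headers."""
    with open(path, "w") as fh:
        for t in tiles:
            fh.write(f">{t.id}\n{t.sequence}\n")


def simulate_read_pairs(
    elements: Sequence[tuple[str, str]],
    reads_per_element: int = 10,
    read_len: int = 50,
    umi_length: int = 8,
    error_rate: float = 0.0,
    duplication: float = 0.0,
    rng_seed: int = 0,
) -> list[tuple[str, str, str, str]]:
    """Paired reads (element id, umi, r1, r2) from DNA elements, with optional
    substitution errors and geometric PCR duplication, for read-mapping tests."""
    rng = np.random.default_rng(rng_seed)
    bases = np.array(list("ACGT"))
    out = []

    def mutate(s: str) -> str:
        arr = np.array(list(s))
        hits = rng.random(arr.size) < error_rate
        arr[hits] = rng.choice(bases, size=int(hits.sum()))
        return "".join(arr)

    for eid, dna in elements:
        for _ in range(reads_per_element):
            umi = "".join(rng.choice(bases, size=umi_length))
            r1 = mutate(dna[:read_len])
            r2 = mutate(dna[-read_len:])
            n_copies = 1 + (rng.geometric(1 - duplication) - 1 if duplication > 0 else 0)
            for _ in range(int(n_copies)):
                out.append((eid, umi, r1, r2))
    return out
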