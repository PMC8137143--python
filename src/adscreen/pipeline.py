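"""End-to-end demo pipeline on synthetic data, driven by a YAML config.

Stages: simulate (proteome + screen + pulldown) -> quantify -> call-domains ->
pulldown enrichment, each writing TSV/BED outputs into a run directory and a
provenance manifest of sha256 hashes. Identical config and seeds give
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import domain_calling, pulldown_quant, synthetic_data
from .activation_quant import (MAX_SD_LOG_GFP, MIN_CELLS, ControlModel,
                               quantify_screen)
from .seq_features import hydrophobic_content

log = logging.getLogger("adscreen")

_KNOWN_KEYS = {
    "seed", "n_proteins", "ad_frequency", "cells_per_fragment",
    "read_depth_per_bin", "ad_cutoff", "binding_cutoff", "min_cells", "max_sd",
    "min_input_reads", "min_bound_reads", "min_overlap", "qpcr_bound_fraction",
    "run_pulldown", "run_paddle", "pulldown_depth",
}


@dataclass
class PipelineConfig:
    seed: int = 0
    n_proteins: int = 12
    ad_frequency: float = 0.6
    cells_per_fragment: int = 500
    read_depth_per_bin: int = 100_000
    ad_cutoff: float = domain_calling.AD_CUTOFF
    binding_cutoff: float = domain_calling.BINDING_CUTOFF
    min_cells: float = MIN_CELLS
    max_sd: float = MAX_SD_LOG_GFP
    min_input_reads: int = pulldown_quant.MIN_INPUT_READS
    min_bound_reads: int = pulldown_quant.MIN_BOUND_READS
    min_overlap: int = domain_calling.MIN_OVERLAP
    qpcr_bound_fraction: float = 0.02
    pulldown_depth: int = 500_000
    run_pulldown: bool = True
    run_paddle: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the synthetic demo pipeline; returns the provenance manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "outputs": {}, "timings": {}}
    rng_seed = config.seed

    t0 = time.time()
    proteome = synthetic_data.generate_proteome(
        n_proteins=config.n_proteins, ad_frequency=config.ad_frequency,
        rng_seed=rng_seed,
    )
    tiles = synthetic_data.tile_proteome(proteome)
    synthetic_data.tiles_to_fasta(tiles, str(out / "tiles.fasta"))
    screen_cfg = synthetic_data.ScreenSimulationConfig(
        cells_per_fragment=config.cells_per_fragment,
        read_depth_per_bin=config.read_depth_per_bin,
        rng_seed=rng_seed + 1,
    )
    table, truth = synthetic_data.simulate_screen(proteome, tiles, screen_cfg)
    truth.to_csv(out / "truth.tsv", sep="\t")
    counts = table.counts.copy()
    counts.to_csv(out / "bin_counts.tsv", sep="\t")
    manifest["timings"]["simulate"] = time.time() - t0
    log.info("simulate: %d tiles from %d proteins", len(tiles), config.n_proteins)

    t0 = time.time()
    # Z standardizes against the control *cell* distribution, so sigma is the
    # cell-level log-GFP sd, not the standard error of a fragment mean.
    control = ControlModel(
        mu=screen_cfg.background_mean_log_gfp,
        sigma=screen_cfg.population_sd_log_gfp,
    )
    activation = quantify_screen(table, control, config.min_cells, config.max_sd)
    activation.to_csv(out / "activation.tsv", sep="\t")
    manifest["timings"]["quantify"] = time.time() - t0

    t0 = time.time()
    all_calls = []
    for pid, seq in proteome.proteins:
        prot_tiles = [
            ((t.start, t.stop), activation.loc[t.id, "z"])
            for t in tiles
            if t.protein_id == pid and activation.loc[t.id, "passed_filters"]
        ]
        if not prot_tiles:
            continue
        profile = domain_calling.positional_mpz(prot_tiles, len(seq), pid)
        all_calls.extend(domain_calling.call_domains(profile, config.ad_cutoff))
    (out / "domain_calls.bed").write_text(domain_calling.calls_to_bed(all_calls))
    manifest["timings"]["call_domains"] = time.time() - t0
    log.info("call-domains: %d calls", len(all_calls))

    if config.run_pulldown:
        t0 = time.time()
        affinity = lambda seq: float(np.exp(0.2 * hydrophobic_content(seq)))
        pull = synthetic_data.simulate_pulldown(
            tiles, affinity, depth_input=config.pulldown_depth,
            depth_bound=config.pulldown_depth,
            qpcr_bound_fraction=config.qpcr_bound_fraction, rng_seed=rng_seed + 2,
        )
        # random-control set: the 20 least hydrophobic tiles stand in for the
        # random-sequence controls of a designed library
        hydro = {t.id: hydrophobic_content(t.sequence) for t in tiles}
        controls = sorted(hydro, key=hydro.get)[:20]
        ptable = pulldown_quant.PulldownTable(
            pull["input_reads"], pull["bound_reads"], config.qpcr_bound_fraction
        )
        enrich = pulldown_quant.enrichment_vs_controls(
            ptable, controls, config.min_input_reads, config.min_bound_reads
        )
        enrich.to_csv(out / "enrichment.tsv", sep="\t")
        manifest["timings"]["pulldown"] = time.time() - t0

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
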