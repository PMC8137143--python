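# adscreen

Analysis machinery for pooled activation-domain (AD) screens in yeast, for
researchers quantifying transcriptional activation with sort-seq reporter
assays and mapping AD–coactivator interactions. The package covers the full
computational path of such a study:

- **Sort-seq quantification** — cells expressing each 53-aa protein fragment
  *F* are FACS-sorted into 8 log-spaced GFP bins and sequenced per bin. The
  per-fragment geometric-mean GFP is recovered as the cell-weighted average
  of bin means in log10 scale,
  `mean_log(F) = Σ_b cells_b(F)·log g_b / Σ_b cells_b(F)`, with
  `cells_b(F) = cells_b · reads_b(F)/reads_b(total)`. Fold-activation is
  `10^(mean_log − μ_ctrl)`, and `Z = (mean_log − μ_ctrl)/σ_ctrl` with a
  one-tailed normal p-value; fragments with < 10 cells or log-GFP SD > 4.5
  are filtered.
- **Domain calling** — the per-residue mean positional Z (MPZ) profile is the
  average Z of all tiles covering a position; ADs are MPZ > 3.5 peaks expanded
  to their full width at half maximum, with shoulder peaks of larger maxima
  excluded. Coactivator-binding domains use the same caller at MPZ > 2.23.
- **mRNA-display pull-downs** — fractional pull-down
  `qPCR × (bound fraction of F)/(input fraction of F)`, enrichment against
  random-sequence controls (iterative 3-SD outlier exclusion, geometric-mean
  baseline), replicate combination, and the sucrose-gradient discordance
  filter.
- **Read mapping** — paired-end reads assigned to library elements by minimal
  summed Levenshtein distance, UMI deduplication to molecule counts.
- **Library design** — 53-aa tiling with ≥ 40-aa overlap, mutant panels
  (scrambles, aromatic/acidic subsets, Ala/Pro scans, tandem core-ADs, the
  hydrophobic-inhibition matrix, binary Asp/Leu-Phe-Trp 9-mers), and DNA
  encoding under GC/repeat/homopolymer constraints with enforced pairwise
  edit distance ≥ 6 in both 48-base read windows.
- **Activation prediction** — a convolutional sequence-to-activity regressor
  (`PADDLERegressor`: 9 conv layers, kernel 10, 30 channels, global max-pool,
  Swish, batch norm) and an order-blind composition MLP baseline, both
  sklearn-style estimators, plus prediction-time procedures: 1-aa tile
  scanning with 9-aa smoothing, high/medium AD calling, neutral-context
  scoring of short sequences, core-AD localization and in-silico mutagenesis.
- **Kinetics** — closed-form 1:1 Langmuir association/dissociation and
  nonlinear least-squares fitting of (kon, koff, Rmax), reporting
  KD = koff/kon and half-life ln2/koff.
- **Synthetic data** — generators that emulate the statistical structure of
  every assay (log-normal per-fragment GFP, multinomial per-bin reads,
  affinity-weighted pull-down counts, noisy sensorgrams) so the whole
  pipeline runs and is tested without any external data.

## Worked example

```python
import numpy as np
from adscreen import synthetic_data as sd
from adscreen.activation_quant import ControlModel, quantify_screen
from adscreen.domain_calling import positional_mpz, call_domains

proteome = sd.generate_proteome(n_proteins=10, ad_frequency=0.6, rng_seed=4)
tiles = sd.tile_proteome(proteome)
cfg = sd.ScreenSimulationConfig(rng_seed=5)          # 500 cells/fragment, 8 bins
table, truth = sd.simulate_screen(proteome, tiles, cfg)
control = ControlModel(mu=cfg.background_mean_log_gfp,
                       sigma=cfg.population_sd_log_gfp)
act = quantify_screen(table, control)

est = np.log10(act.loc[act.passed_filters, "fold_activation"])
tru = np.log10(truth.loc[est.index, "true_fold"])
print(f"{len(tiles)} tiles, r = {np.corrcoef(est, tru)[0,1]:.3f}")

pid, start, stop, fold = max(proteome.planted_domains, key=lambda d: d[3])
prof = positional_mpz(
    [((t.start, t.stop), act.loc[t.id, "z"]) for t in tiles if t.protein_id == pid],
    len(proteome.sequence(pid)), pid)
print(f"planted AD in {pid}: [{start}, {stop}), fold {fold:.0f}")
for c in call_domains(prof):
    print(f"called  AD in {pid}: [{c.start}, {c.stop}) peak MPZ {c.peak_mpz:.1f}")
```

prints (seed-fixed):

```
319 tiles, r = 0.997
planted AD in prot008: [17, 49), fold 76
called  AD in prot008: [0, 51) peak MPZ 5.3
```

i.e. the estimated log10 fold-activation of the 319 tiles correlates with the
simulated truth at r = 0.997, and the tiling profile of the protein carrying
the strongest planted acidic/hydrophobic segment yields one called AD
covering it. The call is wider than the planted segment because every 53-aa
tile overlapping the segment activates, which is exactly the resolution limit
the FWHM caller has on real tiling data.

A command-line interface mirrors the library:
`adscreen simulate | quantify | call-domains | pulldown | design | kinetics | run`;
`adscreen run --out rundir` executes the synthetic demo pipeline end to end
and writes a sha256 provenance manifest.

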