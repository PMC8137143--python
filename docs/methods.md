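# Methods

This note documents the models and procedures implemented in `adscreen`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Sort-seq activation quantification

**Model.** Cells expressing a single protein fragment have log-normally
distributed GFP; all averaging is therefore done in log10 scale (a geometric
mean of GFP). A pooled library is sorted into 8 GFP bins, evenly spaced in
log scale, in two passes (bins 1–4, then bins 5–8); per-bin sequencing reads
are multinomial over fragments in proportion to sorted cell counts.

**Estimator.** Bin cell totals are first made comparable across the two sort
passes by rescaling bins 5–8 by the ratio of events assayed. The cells in bin
*b* expressing fragment *F* are estimated as
`cells_b · reads_b(F)/reads_b(total)`; the fragment mean and SD of log GFP
are the cell-weighted moments of the bin mean log-GFP values. The weighted SD
uses the population formula, since the weights are estimated cell counts
rather than draws from a sampled set. Fold-activation is
`10^(mean_log − μ)`, `Z = (mean_log − μ)/σ` against the negative-control
model, and p is the one-tailed upper normal probability. Fragments with
fewer than 10 estimated cells or log-GFP SD above 4.5 fail filters but are
retained in outputs with `passed_filters = False` for auditability. The SD
threshold is interpreted in the same log10 units as the bin means — the
units in which every other GFP quantity in the pipeline is expressed.

**Control model.** Either an externally measured population (μ, σ given), or
internal random-sequence controls: controls more than 3 SD from the mean of
the surviving controls are excluded iteratively to a fixed point, then μ/σ
are the moments of the pooled per-cell mixture of survivors when per-control
SDs and cell counts are available, else the moments of the surviving means.
Note the batch 3-SD rule cannot fire with fewer than ~11 controls (no point
of an n-sample can lie more than (n−1)/√n SDs from its mean).

**Transformation correction.** Colony genotyping detects only cells that
received *distinct* plasmids. With two independent draws from *n*
equiprobable plasmids the draws differ with probability (n−1)/n, so the
observed distinct-vector fraction is divided by that factor; with three
plasmids, 2/15 colonies corrects to 20% and 1/24 to 6%.

## Domain calling

The mean positional Z (MPZ) profile assigns each residue the mean Z of all
tiles covering it; uncovered positions are NaN and treated as below
threshold. Maximal runs above the cutoff (3.5 for ADs, 2.23 for
Med15/TFIID-binding domains) seed calls in decreasing order of peak MPZ.
Each call expands outward from its peak (argmax; leftmost on ties — the tie
rule was left open and a deterministic choice was needed) to the first
positions strictly below half the peak; NaN positions and protein ends
terminate the scan. FWHM is measured relative to zero baseline, since the Z
of background is zero by construction. A call whose interval contains a
position outside its seeding run higher than its own peak is a shoulder of a
larger peak and is discarded. The exclusion rule alone does not forbid two
near-equal peaks from producing overlapping calls, so calls overlapping an
already-accepted (higher) call are additionally dropped; accepted calls are
therefore always disjoint.

## mRNA-display pull-down quantification

Fractional pull-down of *F* is
`qPCR bound fraction × (bound read fraction of F)/(input read fraction of F)`,
with fragments under 30 input or 5 bound reads excluded. Binding enrichment
divides by the geometric mean of the random-sequence controls after the same
iterative 3-SD exclusion (applied on log fractional pull-down; an externally
derived exclusion list, e.g. from the activation assay, can be supplied
instead). Z standardizes log enrichment against the control
log-distribution; identical controls leave enrichment defined but Z
undefined. Replicates are combined by geometric mean of enrichment (the
log-scale average), with Z recomputed from the combined control
distribution; fragments filtered in some but not all replicates are combined
from the remainder and flagged partial. The discordance filter removes
fragments whose binding appears only with the sucrose-gradient protocol:
no-gradient Z within [−2.5, 1] (closed interval) and with-gradient Z at
least 3.5 higher.

## Read assignment and deduplication

Reads are assigned to the library element minimizing
`d(r1, element 5' prefix) + d(r2, element 3' suffix)` in Levenshtein
distance (via edlib). Minima above the threshold, ties between elements, or
any nonzero minimum in perfect-only mode leave the read unassigned — ties
are conservative, since a well-designed library makes them impossible within
a sub-library. UMI deduplication counts distinct (element, UMI) pairs;
reads without a UMI are dropped and tallied.

## Library design

Tiling uses `n = 1 + ceil((L−53)/13)` tiles at starts
`round(i·(L−53)/(n−1))`: steps never exceed 13 (i.e. overlaps are ≥ 40 aa)
and the tiling is as even as rounding allows. Proteins shorter than one tile
are rejected. DNA encoding samples codons by usage frequency (a bundled
mammalian-usage table; any table can be supplied) and greedily resamples
codons at violation sites. Translation fidelity is a hard constraint; GC
(45% target, ±10 points tolerance, global and 50-base windows), repeated
≥10-mers, homopolymer limits (A/T ≤ 7, C/G ≤ 4) and adjacent k-mer repeats
(3-mers ×3, 2-mers ×5) are soft objectives. Homopolymers are weighted
10× in the repair objective: they are hard synthesis failures, and
low-complexity peptides (e.g. polylysine) cannot satisfy the repeat rules at
all, so the repair must not trade a homopolymer fix for repeat violations.
Pairwise distinguishability is enforced by the randomized iterative repair:
while any pair of encodings is closer than 6 edits in the first or last 48
bases, two codons in each offending window of one member are resampled
synonymously; the loop fails loudly after 100 sweeps. The paired-end check
(sum of 5'-most and 3'-most 50-base distances ≥ 6) is verified explicitly
afterward — window containment does not make it a theorem for edit distance.

Mutant panels (scrambles, aromatic/acidic subsets, D↔E and D→N/E→Q swaps,
Ala and Ala/Pro scans of non-hydrophobic positions 4–10, tandem core-ADs in
AGSTNQV neutral context with native spacing preserved, the
hydrophobic-inhibition matrix, and the 1534 binary Asp/{Leu,Phe,Trp} 9-mers
in their fixed 30-aa assay context) each record provenance of what changed.

## Activation predictors

`PADDLERegressor` encodes a 53-aa fragment as a 53×24 matrix (20 one-hot
residue channels plus helix/coil and short/long disorder probabilities from
external predictors, consumed as inputs and never computed internally); the
noSS variant uses the 53×20 one-hot alone. The reference architecture is
nine same-padded conv layers (kernel 10, 30 channels), global max-pooling
over the sequence axis, and two dense layers of width 20, all with Swish,
batch normalization, dropout 0.1 and L2 penalty 1e-3; the composition
baseline (`CompositionMLP`) is three dense layers of width 40 (dropout 0.4,
L2 1e-2) on the 20-element residue-proportion vector. Same padding preserves
length before the max-pool; any valid padding satisfies the structural
contract. Both train with Adam and MSE on inputs and targets standardized to
mean 0/variance 1 over the training data, with learning-rate reduction by
5× after 20 stagnant training epochs and early stopping when the 10-epoch
moving average of validation loss fails to improve for 75 epochs (best
weights restored). Training splits are grouped by protein so overlapping
tiles never straddle train and validation; the fitted model is the mean of
the per-fold models (`n_folds=10` by default; `n_folds=1` trains a single
model with a held-back grouped validation split). The networks are built on
a small numpy core (strided im2col convolution, batch norm, Adam) written
for this package; gradients are verified against numeric differentiation in
the tests.

Prediction-time procedures: proteins are scanned at 1-aa tile steps and
smoothed with a 9-aa centered moving average (window truncated at track
ends — the edge behavior was unspecified and truncation keeps track length
equal to L−52). High-strength predicted ADs are runs of ≥5 consecutive
starts with smoothed Z > 6, reported as the union of the tiles' residue
spans and merged when overlapping by more than 26 aa; medium-strength calls
repeat at Z > 4 and are discarded if they overlap a high call by more than
26 aa. Sequences of 5–52 aa are scored by centering them in 100 random
AGSTNQV neutral contexts and averaging. Core ADs are the shortest 5–30 aa
sub-tiles with predicted Z > 3.09 (p < 0.001) that do not overlap an
already-selected shorter core (ties resolve to higher Z, then leftmost). The
in-silico alanine scan shares one context set across all positions so that
ΔZ reflects only the mutation.

## Langmuir kinetics

The 1:1 model: association
`R(t) = Req (1 − e^{−(kon·C + koff) t})` with `Req = Rmax·C/(C + koff/kon)`,
dissociation `R(t) = R0 e^{−koff t}`. Fitting is joint nonlinear least
squares over both phases in log-parameter space from 5 log-spaced kon
starts (1e4–1e8 /M/s), with koff seeded from the dissociation tail's
log-linear slope; the lowest-residual start wins. KD = koff/kon and
half-life = ln2/koff are derived identities, exact in every fit. Baseline
drift and bulk-shift terms are not modeled — a known limitation relative to
instrument software.

## Synthetic data

The generators define the package's study conditions. Proteomes draw
TF-like background residue frequencies (S/N/Q-rich, low C/W) with planted
activation domains of Asp-skewed acidic plus bulky-hydrophobic composition,
30–45 aa long, true folds log-uniform in [5, 200]. Screens draw each
fragment's cells (default 500/fragment) from a log10-normal GFP population
with SD 0.35 — a typical within-clone FACS spread — centered at background
(default 2.0 log10 AU) plus the fragment's true log fold; bins default to 8
even log10 divisions of [background − 0.5, background + 2.8]; reads (default
1e5/bin) are multinomial over fragments by cell count. A tile overlapping a
planted domain by ≥ 26 aa inherits the planted log10 fold scaled by its
fractional overlap, which produces the graded tiling profiles a real screen
shows; smaller overlaps contribute nothing. Sort metadata (per-bin cell
totals and mean log GFP) is recorded exactly as the simulated sorter saw it.
Pull-downs draw input reads multinomially with mild log-normal abundance
jitter and bound reads with weights ∝ input × affinity(sequence); geometric
UMI duplication is optional. Sensorgrams follow the closed-form Langmuir
solution plus Gaussian noise.

Not emulated: mCherry gating, growth competition, PCR bias, plasmid
copy-number drift, estrogen induction kinetics, bead chemistry, and in-vivo
mutation of fragments. Passing tests therefore demonstrate correctness of
the estimators under the assay's idealized statistical model, not robustness
to these real-data artifacts.

**Problem sizes in the test suite.** The quantitative checks run at sizes
chosen to exercise the statistics convincingly on a laptop-class machine:
estimator recovery on 200 single-tile fragments at 500 cells each; oracle
equivalences on 500 Levenshtein pairs, 200 random 150-mers and 100 random
tilings; edit-distance enforcement on 100 random 53-aa encodings; Langmuir
recovery over 20 noise seeds; and the predictor comparison on 2,000 tiles
with a reduced network (4 conv layers, 24 channels, single model, learning
rate 3e-3 for up to 300 epochs) against the composition MLP on an
LxxLL-motif target that composition cannot represent. The reduced predictor
configuration trains the same code path as the reference architecture; the
comparison asserts ranking and threshold, not exact losses, since training
is stochastic.
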