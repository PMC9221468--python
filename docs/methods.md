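# Methods

This note documents the models, statistics, parameter choices, and known
limitations behind `pnmine`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Expression preprocessing

The variability filter keeps genes whose raw MAD — the median of absolute
deviations from the gene's median, *without* the 1.4826 normal-consistency
constant — is strictly greater than the threshold (default 1000, on the
expression units of the deposited matrices). The constant is omitted
deliberately: the threshold is calibrated against raw expression units, and
scaling would silently change the survivor set. Whether the threshold should
apply to log or linear units is dataset-dependent, so the pipeline exposes a
`log_transform` toggle instead of guessing. The filter applies to the
cell-line matrix only; tumors are subset to the surviving genes. Each
dataset is then standardized per gene (mean 0, sd 1, ddof = 1) so that
network construction sees comparable scales and eigengenes are
scale-free.

## Consensus network and modules

Networks are unsigned: `a_ij = |r_ij|^β` with Pearson `r`. β defaults to 8;
when `pick_power` is enabled, the smallest candidate whose signed scale-free
fit R² (slope-signed R² of log10 p(k) against log10 k over ten equal-width
connectivity bins) reaches 0.8 in *both* datasets is chosen, with 8 as the
fallback. Zero-variance genes correlate 0 with a warning; degenerate
connectivity makes the fit undefined and skips the candidate.

The topological overlap transform uses the standard unsigned formula with
the diagonal forced to 1. The consensus of the two TOMs is taken after
multiplying the tumor TOM by the ratio of the two matrices' 0.95-quantile
off-diagonal entries — a single multiplicative quantile calibration that
stops systematic density differences from dominating the elementwise
minimum. The quantile is exposed in the configuration.

Module detection is average-linkage hierarchical clustering of `1 − TOM`
with a *static* cut (default height 0.995) followed by iterative eigengene
merging (modules whose cell-line eigengenes correlate above
`1 − merge_cut`, default r > 0.75, are merged, most-correlated pair first).
This replaces the hybrid dynamic tree cut used by WGCNA because it is fully
specified, deterministic, and testable; the exact module count of any
particular real dataset is parameter-sensitive either way. Clusters below
`min_module_size` (default 30) fall into `grey`. Modules are named from a
fixed color palette in descending size order — deterministic naming beats
fidelity to arbitrary labels. Networks are computed whole-matrix with the
expectation of desk-scale inputs (≤ ~5000 genes after filtering) rather
than block-wise.

## Eigengenes and preservation

A module eigengene is the first right singular vector of the module's
row-standardized gene × sample block, scaled to sd 1 and oriented so the
mean correlation with the module's genes is non-negative. Note a
consequence of that orientation rule: negating every gene in a module
negates the oriented eigengene. Variance explained is `s₁²/Σs²`.
Single-gene modules use the gene's standardized profile.

Preservation of a (cell-line-defined) module in the tumor set is a
permutation Z-summary built from two statistics:

* **density** — mean off-diagonal intramodular adjacency in the test set,
  at the network's β;
* **connectivity** — Pearson correlation between the intramodular
  connectivity vectors of the reference and test sets.

The null recomputes both statistics on seeded random gene sets of equal
size drawn from the filtered gene universe; `Z = (obs − mean)/sd` and
`Z_summary` is the mean of the two Z's. Modules with `Z_summary > 5` are
preserved; modules of fewer than 3 genes are reported missing. Two
composite statistics are used rather than the full seven-statistic
medianRank suite of WGCNA's `modulePreservation` because only the
`Z_summary > 5` call is consumed downstream.

**Limitation.** When the filtered universe is almost entirely modular (as
in strongly planted synthetic data), random null sets inherit substantial
shared connectivity structure, which makes the connectivity Z conservative
(often near or below zero even for genuinely preserved modules); the
density Z then carries the call. Z's are reproducible under a fixed seed and
stabilize by ~100–200 permutations.

## Drug screen summaries and filters

The per-(drug, line) summary response is the trapezoidal integral of
viability over log10 concentration divided by the log-span, which keeps the
AUC on the same 0–100 viability scale as the raw curves — this is what makes
a "< 55 % viability" cutoff dimensionally coherent for an AUC. If a
deposited screen already carries a summary column it is used verbatim. The
viability pre-filter keeps drugs whose *median* summary across lines is
strictly below the cutoff (default 55). The annotation filter keeps drugs
with pChEMBL strictly above 6 (missing pChEMBL kept by default, flagged —
screening libraries contain tool compounds without ChEMBL entries) and,
when requested, a clinical status within a closed vocabulary
(FDA-approved / Phase III / Phase II / Phase I / preclinical).

## Fingerprints, consensus clustering, candidates

A drug's fingerprint is the vector of Pearson correlations between its
per-line summary responses and each preserved module's eigengene over the
shared cell lines (≥ 3 required; zero variance on either side produces a
flagged missing entry, and rows with missing entries are dropped from
clustering rather than imputed — imputation would manufacture
fingerprints).

Drug clustering is Monti-style consensus clustering: `n_resample` (default
100) subsamples of ⌈`item_fraction`·n⌉ drugs (default 0.8, without
replacement), each clustered by average linkage on `1 − Pearson` between
fingerprint rows and cut at every k in `k_range`; the consensus matrix is
co-clustering counts over co-sampling counts. The final partition cuts an
average-linkage tree on `1 − consensus` at the chosen k. k is chosen by the
delta-area rule on the consensus CDF (area for the smallest k, proportional
gain thereafter), and can be pinned with `force_k` — on real data one may
prefer a fixed k. Correlation distance (pattern, not magnitude) is used
because the fingerprint's scientific content is *which* modules move and in
what direction, not the overall effect size. Fewer than 20 resamples is
refused as unstable.

Candidate List-1 ranks, within each cluster, the clinically advanced drugs
by `score = min over preserved modules of fingerprint r`, keeping only
`score < 0` (a negative correlation means the module's genes fall as the
drug takes effect — a treatable axis) and emitting the top 15 per cluster
with lexicographic tie-breaks. The module attaining the minimum is reported
explicitly rather than guessed. Fingerprint-similar drugs ("anchor-like")
are those whose fingerprint rows correlate with the anchor's at ≥ 0.8
(configurable); similarity is quantitative here, where a visual heatmap
reading would be subjective.

## Independent drug action (IDA)

The IDA model assumes non-interacting drugs: each cell line responds as if
given only the drug most effective for it, so the predicted combination
viability per line is the minimum of the two monotherapy viabilities at the
chosen concentrations. The IDAcombo score of a pair is

```
score(c_A, c_B) = min(mean_i V_A(i, c_A), mean_i V_B(i, c_B)) − mean_i min(V_A, V_B)
IDAcombo        = max over (c_A, c_B) of score
```

in viability percentage points, over the concentration grid with the two
extreme screen concentrations removed (positional trim). The
percentage-point scale is an explicit operationalization choice: a
reporting threshold of "score > 1" is meaningful for percentage points and
ill-posed for a 0–1 efficacy difference. The scoring hook is a single
function, documented in output provenance, and swappable. Because the mean
of minima never exceeds the minimum of means, the score is non-negative.
It is *not* monotone in partner potency: a partner that is lowered to near
total kill becomes the best monotherapy itself and the combination
advantage vanishes — the score rewards complementary line-by-line response
profiles, which is the population-heterogeneity insight of IDA.

Vertical combinations score all pairs within the anchor plus its
fingerprint-similar advanced-status set; horizontal combinations score the
anchor against all advanced-status members of a complementary cluster
(default: the cluster whose mean fingerprint is most anti-correlated with
the anchor's cluster mean). Shared cell lines are intersected per pair so
drugs with partial panels remain comparable.

## Enrichment

Over-representation of a module in user-supplied gene sets (GMT) is an
upper-tail hypergeometric test with Benjamini–Hochberg correction. The
universe is the filtered network gene space, not the genome — the only
defensible universe given the pipeline. Sets are intersected with the
universe before testing. No GO DAG handling or term-redundancy pruning is
attempted; gene-set collections are supplied by the user.

## Synthetic data generator

The generator defines the study conditions for every recovery test:

* **Expression** follows a latent-factor (spiked covariance) model: each
  module has one latent factor per dataset and positive gene loadings
  (uniform 0.6–1.0), so a single dominant eigenvector exists per module and
  eigengene recovery is well-defined. Preserved modules re-use their
  loading structure in the tumor set (with that set's own per-sample
  factor); non-preserved modules degrade to pure background noise there.
  Module genes are scaled (default 3000) so they clear the MAD > 1000
  filter while background genes (scale 300) mostly do not.
* **Drug responses**: summary viability per (drug, line) is
  `clip(base + amplitude·(Σ_m c_dm E_m + ε), 0, 100)` with couplings on the
  response scale (positive coupling = viability rises with the eigengene),
  eigengene sd 1, noise sd 0.1, amplitude 8, and base uniform in [32, 68] —
  numbers chosen so planted effects are strong but clipping at the
  viability bounds is rare. The default drug-class layout couples each
  class to a distinct pair of preserved modules at ±0.9 with per-drug
  jitter 0.05; explicit `drug_module_links` override it.
* **Dose–response**: 4-parameter Hill curves with top 100 %, slope 1, and a
  per-(drug, line) EC50 solved by bisection so the log-concentration
  trapezoidal AUC over the 11-point 3-fold dilution grid equals the planted
  summary exactly. Potency is therefore monotone in the planted response,
  and the screen module's AUC computation recovers the planted summary to
  numerical precision (away from the clip bounds).
* **Annotations**: statuses drawn with probabilities 0.20 / 0.10 / 0.15 /
  0.15 / 0.40 over FDA-approved / Phase III / Phase II / Phase I /
  preclinical (roughly one fifth approved, two fifths in trials, as in
  oncology screening libraries), pChEMBL uniform over [4, 9.5] spanning the
  6.0 cutoff, 15 % missing.
* Defaults of 5 cell lines and 13 tumors mirror the motivating datasets;
  recovery tests use 10–20 lines because correlations over n = 5 are
  statistically unstable — this separates implementation correctness from
  small-n noise.

What the generator does **not** emulate: real transcriptome marginal
distributions beyond second-order structure, compound-identity structure of
real libraries, batch effects, or assay artifacts. Passing recovery tests
demonstrates that the estimators invert the generator's model class at
realistic noise; it does not certify performance on any particular real
dataset.

`planted_fingerprints` additionally provides two complementary fingerprint
classes (alternating ±effect prototype and its negation) with per-entry
noise; the class separation per informative coordinate is
`2·effect/noise_sd`, and the consensus-clustering recovery condition uses
4× (effect 0.8, noise sd 0.4).

## Problem sizes and numerical choices

Recovery analyses run at 2000 genes (8 modules of 60–400 genes, 6
preserved), 20+20 samples, 100 permutations for preservation, and 100
consensus resamples — sizes at which every stage completes in seconds on
one CPU while leaving the statistics well-determined. Ties in candidate
ranking break lexicographically on drug name; module colors are assigned
deterministically by size; all permutation and resampling randomness is
seeded, with per-stage seeds derived from the global seed by a fixed
`SeedSequence` construction, so identical configurations reproduce
byte-identical outputs. Matrix symmetry is enforced to 1e-10 and network
entries are clipped to [0, 1] after each operation.

## Known limitations

* The static-cut + merge module detector can split or fuse modules whose
  eigengene correlation sits near the merge threshold; the exact module
  count is not a stable quantity and is not treated as one.
* The connectivity-preservation Z is conservative on heavily modular gene
  universes (see above).
* Consensus-TOM construction assumes two datasets; multi-set consensus,
  signed networks, and robust (bicor) correlation are out of scope.
* IDA ignores pharmacokinetic interaction, toxicity, and >2-drug
  combinations; its score depends on the cell-line panel's heterogeneity.
* The delta-area rule tends to favor small k when classes overlap; `force_k`
  exists for exactly that reason.
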