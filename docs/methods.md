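# Methods

## The problem

Methylation arrays report, for each of ~485k CpG probes, a methylation
fraction (beta-value in [0, 1]) computed from two channel intensities,
`beta = M / (M + U + offset)`. Differential-methylation workflows chain
quality control, normalization, batch correction and a DMP/DMR caller;
every link has competing options and the best chain depends on the
dataset's size, effect magnitude and number of truly altered probes.
Benchmarking those chains requires datasets whose differential probes
are known exactly, which only simulation provides. The simulator here
is *tissue-aware*: rather than injecting arbitrary shifts, it moves
probes in a source-tissue dataset toward the per-probe reference
profile of a real target tissue, so effect sizes and their spatial
structure are inherited from biology rather than chosen by hand.

## Quality control

Probes are removed when (1) the detection p-value exceeds 0.05, (2) any
intensity is negative, (3) the probe sits on a SNP with allele
frequency above 5%, or (4) it is flagged non-specific. Samples are
removed when dim in *both* channels: log2(median intensity) < 10 in M
and in U, with a strict inequality so a median of exactly 2^10 stays.
Choices the rules leave open, fixed here and exposed in `QcConfig`:

- the detection rule fires on *any* failing sample
  (`detection_fail_fraction = 0`); a per-fraction variant is available;
- a negative intensity in either channel in any sample removes the
  probe;
- the beta offset is the platform-conventional 100.

## Candidate co-methylated regions

Adjacent CpGs are co-methylated, so simulated DMRs should follow
co-methylation structure. Probes are sorted by (chromosome, position)
and scored by the mean Pearson correlation (across samples) between
their beta vector and each neighbour in a centred window of size 3 —
i.e. the two flanking probes; terminal probes use the neighbours they
have. The window pairing is our reading of "a window of size 3";
computing one joint correlation over three probes is the alternative
and gives very similar selections. Zero-variance probes score 0 and
never pass. Runs of probes with score strictly above the threshold
(0.1, 0.2 or 0.4) become regions after two HMM-island-derived filters:
split where adjacent probes are more than 702 bp apart (median island
length) and discard runs spanning under 12 bp (minimum island length).
A single probe spans 1 bp and therefore can never form a region.
Processing is per-chromosome and chromosome-generic.

Correlation must be computed within one homogeneous cohort: pooling
batches lets shared batch shifts masquerade as co-methylation, so the
scenario builder clusters on the largest single batch.

## Simulation approaches

For each region probe *p* and case sample *j*:
`beta'[p,j] = beta[p,j] − (mu_IR[p] − b[p,j])`, clamped to
`[eps, 1−eps]` with `eps = 1e-6`. `mu_IR` is the source-tissue
reference mean; `b` comes from the target-tissue reference
(`mu_SR`, `min_SR`, `max_SR`) and the source's per-probe standard
deviation `sigma_I`:

- **S1**: `b = mu_SR` — deterministic; equal references give an exact
  identity, and S1 is the `sigma_I → 0` limit of S3.
- **S2**: a per-probe average of n uniform draws on
  `[min_SR, max_SR]`, then per-sample uniforms centred on that average
  with half-width `sqrt(3)·sigma_I` (so the second stage's sd equals
  `sigma_I`, consistent with S3/S4), truncated to [0, 1]. The second
  stage's support is a design choice — only its uniformity is given.
- **S3**: `b ~ N(mu_SR, sigma_I)` per (probe, sample). A variant
  (`s3_mode="text"`) replaces `mu_SR` by the uniform first-stage
  average; the closed-form version is the default.
- **S4** (the recommended setting): `a_i ~ Beta(0.4, 0.5)` truncated to
  `[min_SR, max_SR]` (inverse-CDF sampling), `a_bar` their mean over n
  draws, then `b ~ N(a_bar, sigma_I)`. The truncated beta supplies
  between-CpG variation inside a region; the normal supplies
  inter-sample variation.

Numerical details: the first-stage draw count n defaults to the number
of simulated case samples; draws are per-probe (`a_bar` probe-specific,
`b` per probe × sample); a degenerate reference interval
(`min_SR = max_SR`) collapses the first stage to that value;
`min_SR > max_SR` is an error. Subtraction can leave [0, 1] — the rule
set is silent there — so results are clamped symmetrically at `eps`.
Control samples and out-of-region probes are returned bit-identical;
all randomness flows from one seeded generator.

## Benchmark grid

12 scenarios: {small, large} cohorts × {target A, target B} × threshold
{0.1, 0.2, 0.4}, each with a null twin (same case/control split, no
alteration). The five source batches contribute (204, 156, 31, 17, 24)
samples in the large contexts (432 total) and (14, 6, 4, 4, 4) in the
small (32 total); within each batch `floor(count/2)` samples become
cases (the floor goes to cases when counts are odd — the split rule is
otherwise unspecified). Target A models a distant tissue and target B a
close one; in the synthetic references this is a mean-beta shift of
0.40 vs 0.15 inside candidate regions — values chosen once so that the
0.3 fold-change threshold separates the two targets, mimicking the
breast-vs-CD8 contrast of real tissue references. One manifest and one
planted-region layout are shared by all scenarios.

## Synthetic fixtures

The generator emulates every external input from a seed: a manifest
with exponential inter-probe gaps (mean 500 bp, so a tail crosses the
702 bp splitting threshold), 70% type II probes, 5% SNP-flagged, 2%
non-specific; signal matrices built to invert exactly to a planted beta
with optional planted defects (failed detection, negative intensity,
dim samples); a multi-batch source matrix with bimodal baseline means,
logit-scale batch offsets (additive on logit keeps values in (0, 1) and
mimics multiplicative intensity bias) and a shared per-region
per-sample latent factor with weight 0.9 that produces the windowed
correlations clustering looks for; and a reference-profile pair whose
means differ by a configurable delta inside planted regions, with
min/max bracketing the mean at ±0.10. Region-probe baselines are drawn
mid-range so a ±delta shift stays inside (0, 1).

What the fixtures do **not** emulate: realistic 450k probe density or
chromosome lengths, probe-type intensity-distribution differences
(BAQN's strata behave identically up to labels), spatially varying
effect sizes within a region, cell-type mixture, and array
technical artefacts beyond the planted defect classes. Passing tests
therefore demonstrate correctness of the algorithms under controlled
conditions, not performance claims about any real cohort.

## Preprocessing

Quantile normalization replaces each sample's values (within a stratum)
by the mean-of-sorted-columns reference at the sample's ranks, with
ties averaged; this preserves within-sample rank order and is
idempotent. BAQN stratifies by Infinium design type; BetaQN is the
unstratified case. The four comparison metrics are the median per-probe
SD across samples (all / type I / type II probes) and dmrse — the SE
across samples of the mean beta over a fixed imprinted-DMR probe set,
`sd(per-sample mean) / sqrt(n)` — which should be small in data without
a biological reason for inter-individual iDMR variation. The iDMR list
is an input; fixtures plant a surrogate.

Batch correction is parametric empirical-Bayes location/scale
adjustment on beta-values directly (the pipeline is beta-based
throughout): per-probe standardization against an OLS fit containing
batch indicators and the group covariate, EB shrinkage of per-batch
location/scale toward across-probe priors (iterated to 1e-4 relative
change), back-transformation with batch terms removed, and clipping to
[0, 1]. No reference batch; confounded designs (a batch containing a
single group level) are rejected. The implementation is cross-checked
in the test suite against the Bioconductor reference implementation on
a shared fixture.

## Detection and evaluation

The internal caller is intentionally minimal — per-probe Welch t,
Benjamini–Hochberg, significance at q ≤ 0.05, significant probes merged
into regions when within 702 bp with at least 2 probes — because the
benchmark's subject is the surrounding workflow, and external callers
attach through a BED/TSV file contract instead of being reimplemented.

DMP calls are scored as set confusion counts over the probe universe;
0/0 rates are reported as undefined, never as 0. DMR calls use the
20%-overlap rule with these disambiguations: the TP test pools the
total detected overlap of a truth region and compares it strictly
(`>`) against 20% of the *truth* length; the FP test compares each
detection's best single-truth overlap against 20% of the *detection's
own* length with `≤`, so an exactly-20% graze remains an FP. A
detection can therefore simultaneously make a truth region TP and
count as an FP. Region-level TN is undefined (there is no region
universe), so specificity is only reported for DMPs.

Truth regions are stratified by effect size — the mean over member
probes of |mean(case) − mean(control)|, threshold 0.3 — so large- and
small-effect DMRs can be scored separately. The guideline-improvement
statistic is `100 · (F1_selected − mean(F1_all)) / mean(F1_all)` over
the pipeline grid for one scenario.

Simulator validation: the dispersion score between two sample groups is
defined here as the Euclidean distance between group centroids in the
first k principal components (k = 2 default) of the pooled samples —
the underlying score was named but not defined, and centroid distance
is monotone in the separations it is used to rank; it is computed
simulated-vs-target (lower is better), simulated-vs-source and
grouped (higher is better). The SVM protocol trains PCA (10 components)
on a random 80% of real tissue samples, fits a linear one-vs-rest SVM
with 10-fold cross-validation (kernel unspecified upstream; linear
chosen), projects held-out and simulated samples into the trained PC
space, and reports accuracies plus the mean absolute decision value
over simulated samples.

## Problem sizes and determinism

Tests and the acceptance script run on 400–2,000-probe fixtures with
cohorts up to the full 432-sample large scenario; brute-force oracles
(windowed-correlation double loop, exhaustive interval intersection,
quadrature of the truncated beta density) are used at sizes where they
are exact and fast. Every stochastic component takes a seed;
`numpy.random.default_rng` substreams keyed by (seed, generator id)
make each fixture generator independently reproducible.

## Known limitations

- Simulated intensity-level (M/U) data are not produced for simulated
  tissues; simulation operates on beta-values only.
- The S2/S3 first-stage conventions follow one reading of an ambiguous
  description (per-probe averaging of first-stage draws); both S3
  readings are implemented.
- BMIQ normalization and cell-type deconvolution scoring are out of
  scope; report structures accommodate externally computed values.
- The benchmark's internal caller understates what specialized DMR
  callers can do; it exists so the grid runs end to end without R.
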