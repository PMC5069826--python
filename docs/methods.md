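# Methods

## Overview

`ffpesig` asks whether a composite expression-signature score computed
from degraded FFPE material ranks samples the same way as the score from
matched fresh-frozen tissue, and which samples and probes are responsible
when it does not. Because no matched FF/FFPE multi-platform cohort is
bundled with the package, all analyses run against a synthetic cohort
whose generative model encodes the data structure the workflow assumes.
This note documents that model, the statistical procedures, the defaults,
and what the synthetic setting does and does not demonstrate.

## Synthetic cohort model

Latent truth. Each gene *g* in sample *s* has a true log2 expression

    x_gs = mu_g + a_s + beta * 1[g in signature and label_s = MUT] + eps_gs

with gene baselines `mu_g ~ N(8, 1.2)` (housekeeping genes `N(10, 0.5)`:
housekeepers are high-expressed and tight), per-sample RNA-amount offsets
`a_s ~ N(0, 0.2)`, biological noise `eps_gs ~ N(0, 0.5²)`, and a class
effect `beta` (default 1.0 log2 units) on the 18 signature genes in MUT
samples. Housekeeping genes never receive a class effect. The default
cohort has 54 samples, a balanced MUT/WT split, and 1000 background genes.

FF microarray. Probe *p* of gene *g* (1–4 probes per gene, per-probe
brightness offsets `N(0, 0.3)`) reports
`x_gs + offset_p + N(0, 0.3²)`.

FFPE degradation. Every FFPE measurement of a log2 signal `v` reports

    floor + r_g * q_s^gamma_p * (v - floor) + N(0, 0.3² * (2 - q_s))

* `floor = 2.0` log2 units: the background level degraded signal
  collapses toward.
* `q_s ∈ (0, 1]`: per-sample RNA quality. Good samples draw
  `q ~ U(0.85, 1.0)`; a planted subset of 15 "bad" samples draws
  `q ~ U(0.2, 0.5)`. Degradation is therefore multiplicative attenuation
  toward the floor plus heteroscedastic noise — the two observable
  signatures of poor-quality samples (depressed means, low
  signal-to-noise) with two parameters.
* `gamma_p ≥ 1`: per-probe fragility on the microarray platform only,
  `gamma_p = 1 + 3·Phi(−offset_p / 0.3)`. Dim probes degrade faster than
  bright ones, encoding the differing sensitivity of gene-specific probes
  to fixation damage. Gene-level platforms (hybridization counts, FPKM)
  have no probe structure and use `gamma = 1`, which is why the
  NanoString-like platform comes out more forgiving of degraded samples —
  an emergent property of the model, not a hard-coded one. At `q = 1`
  every exponent collapses and FFPE equals FF exactly, so disabling
  degradation reproduces the FF data (a conservation property the tests
  check).
* `r_g`: per-gene FFPE sensitivity, 1.0 for ordinary genes and 0.1 for a
  planted set of 2 "problematic" signature genes whose FFPE response is
  nearly flat. These emulate signature genes that measure essentially
  nothing on FFPE: their probes fail the variance filter, and removing
  them improves FF↔FFPE concordance.

Count platforms exponentiate the degraded log2 signal, apply per-sample
size factors `exp(N(0, 0.15²))` and round to non-negative integers; the
FPKM platform exponentiates and rescales. Sample IDs are barcode-style
zero-padded integers (S101…S154).

What the generator does **not** emulate: raw array intensities or
sequencing reads, fixation chemistry, gene–gene correlation structure
beyond the shared sample factors, batch effects, and realistic mutation
frequencies beyond a configurable class fraction. Passing tests therefore
show that the pipeline's logic behaves correctly under its assumed data
structure — not that any particular correlation or error rate will be
attained on real tissue.

## Normalization

* **Housekeeping scaling** (count platforms with a reference panel): the
  factor for sample *s* is the grand mean of per-sample housekeeping
  geometric means divided by sample *s*'s geometric mean; all counts in
  *s* are multiplied by it. The defining fixed point — equal housekeeping
  geometric means across samples — is asserted to 1e-9 relative
  tolerance. Zero or negative housekeeping counts are an error naming the
  sample and gene: guessing a pseudocount here would silently change the
  factors. Normalized counts are left unrounded.
* **Median centering** (targeted counts): subtract each sample's median
  (even-count medians are the mean of the middle order statistics);
  missing values are excluded from the median and propagated. Idempotent.
* **log2 + z-score** (FPKM): `log2(fpkm + 1)` (pseudocount configurable),
  then each gene standardized across samples to mean 0 and sd 1 with the
  n−1 denominator. Standardization is per gene, not per sample, because
  downstream scores average across genes within a sample; zero-variance
  genes are excluded with a logged warning rather than silently dropped.

## Probe processing

A probe is retained iff (a) at least a `fold_change` (default 1.5-fold,
i.e. |x − median| ≥ log2 1.5 on log2 data) deviation from its own median
occurs in at least `min_fraction` (default 20 %) of its non-missing
samples, and (b) at most `max_missing_fraction` (default 50 %) of its
values are missing. The fold-change denominator is the non-missing count,
so a mostly-missing probe cannot pass on a handful of observations;
comparisons are ≥ / ≤ exactly. Filtration runs on the FFPE microarray
restricted to QC-passed samples (configurable), and the result is applied
to all datasets.

Before filtration, gene values are the mean of all probes of the gene;
after filtration, the single retained probe with the highest across-sample
mean represents the gene (ties broken to the lexicographically smallest
probe ID for determinism). Genes left with no retained probe drop out of
the signature via ordered intersection.

## Scoring and QC

The signature score of a sample is the unweighted arithmetic mean of its
gene-level values over the signature genes — no per-gene standardization
or weighting, applied identically on every platform; cross-platform
comparisons are rank-based, so scale differences between platforms are
immaterial.

QC computes the top-two unit eigenvectors of the sample × sample
covariance matrix (features centered, divisor `n_features − 1`) over the
full feature set, not the signature subset. Eigenvector signs are
arbitrary, so each component is oriented to correlate positively with
per-sample mean expression (ties: non-negative entry sum); degraded,
signal-attenuated samples then land at low PC1. Samples with PC1 strictly
below −0.10 are flagged. The threshold applies to unit-norm entries — for
a 54-sample cohort a uniform vector has entries ≈ 0.136, and a cleanly
separated 15-sample degraded block sits near −0.22 — and is a CLI flag,
not a fitted quantity.

## Concordance

Spearman correlation uses average ranks for ties and the two-sided
t-approximation `t = rho·sqrt((n−2)/(1−rho²))` on n−2 df, the convention
of mainstream statistical software at n in the tens; an exact permutation
mode exists for n ≤ 10 and |rho| = 1 reports p = 0. The pairwise table is
computed on the per-pair intersection of sample IDs minus any exclusion
set; pairs with fewer than 3 usable samples are reported unavailable
rather than fabricated. The Fisher exact test enumerates all 2×2 tables
with the observed margins and sums the probabilities not exceeding the
observed table's (1e-7 relative tolerance guards against float ties).

## Nearest shrunken centroids

For gene *j*, class *k* (`n_k` of *n* samples, `K` classes):
`s_j` is the pooled within-class sd (denominator `n − K`), `s0` the median
of the `s_j`, `m_k = sqrt(1/n_k − 1/n)` (the variance of the
centroid-minus-overall contrast; the `+` variant common in parts of the
literature is available behind `m_variant="plus"`),
`d_kj = (x̄_kj − x̄_j)/(m_k(s_j + s0))`, soft-thresholded
`d'_kj = sign(d_kj)·max(|d_kj| − Δ, 0)`, and shrunken centroid
`x̄'_kj = x̄_j + m_k(s_j + s0)·d'_kj`. Classification minimizes
`Σ_j (x_j − x̄'_kj)²/(s_j+s0)² − 2 log π_k`; exact ties go to the first
class in sorted label order. Priors default to observed class
proportions.

Model selection: LOOCV over a Δ grid (default 30 points from 0 to
max|d_kj| on the full data), with pooled variances, centroids and hence
gene selection recomputed inside every fold; the chosen Δ minimizes the
LOOCV error with ties broken toward the largest Δ (most parsimonious
model). Sensitivity = predicted mutants / true mutants and specificity =
predicted WT / true WT come from the chosen-Δ LOOCV predictions with MUT
as the positive class, and the summary prints them as quotients
(e.g. `0.815 = 22/27`). A class with fewer than 3 samples is rejected for
LOOCV because some fold would leave it with fewer than 2 training
samples. Note that under label permutation, fold-wise observed-proportion
priors bias heavily-shrunk folds against the held-out sample's class; the
chance-level behaviour checks therefore fix balanced priors, matching the
balanced design.

An independent naive-loop implementation of the same formulas lives in
the test suite and is compared against the vectorized implementation on
random instances (offsets, shrunken offsets, surviving genes, and
predictions across the grid), alongside a standalone standardized
nearest-centroid rule that Δ = 0 must reproduce.

## Pipeline

`run_pipeline` materializes the before/after comparison as four
concordance tables — {all samples, QC-passed} × {full signature, reduced
signature} — plus per-dataset LOOCV reports on the reduced signature, a
filter report, QC report, score tables, and a manifest recording seed,
parameters and library versions (no timestamps or absolute paths, so
identical config + seed reproduces every output byte-for-byte). Stage
logging records samples/probes in and out so the filtration and QC
reductions are auditable.

## Problem sizes and defaults

The default conditions are 54 samples, 1000 background genes (~2600
probes), 15 planted bad samples, 2 problematic genes, class effect 1.0,
biological/technical noise 0.5/0.3 log2 units. Repeated-seed checks in
the test suite use 20 seeds for outlier recovery and concordance
improvement and 10–25 random instances for classifier oracles; these
sizes give stable pass/fail behaviour for the properties under test while
keeping the whole suite fast to run routinely.

## Known limitations

* All degradation parameters are free design knobs, not estimates from
  real FFPE series; none of the reported correlations or error rates
  should be read as predictions for clinical material.
* The token `SLCO4A` in the shipped signature panel is kept exactly as
  published; it most likely denotes the HGNC symbol SLCO4A1.
* The Fisher-test utility implements the sum-of-small-probabilities
  convention only; mid-p and conditional-MLE variants are out of scope.
* Multi-class (K > 2) NSC works at the level of the core math, but
  reporting is designed for the two-class MUT/WT setting.
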