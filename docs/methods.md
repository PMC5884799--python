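# Methods

## Scope and model

`consensusde` implements a cross-study meta-analysis of case/control
expression comparisons in which the unit of evidence is a *dataset
comparison* — one contrast (e.g. healthy vs relapsing-remitting MS) within
one study — and the summary statistic is a direction-aware significance
frequency rather than a pooled effect size. Vote counting is deliberate:
the intended data are small, heterogeneous microarray/miRNA studies across
platforms, phenotypes (RRMS/SPMS/PPMS, treatment regimens) and labs, where
a common effect-size scale cannot be assumed. The cost is well known —
vote counting discards magnitude information and has low power for small
per-study effects — and is accepted as the method's defining trade-off;
fixed-/random-effects pooling and p-value combination are explicit
non-goals.

## Differential stage

Per comparison, each molecule gets a two-sided two-sample t-test on log2
expression. The default is Welch's unequal-variance test; the pooled
(equal-variance, df = n1+n2−2) Student variant is available by flag. The
original pipeline this emulates ran a generic "Student t-test" inside a web
tool whose exact engine is unspecified; Welch is the safer default for
heterogeneous real data and the choice is surfaced rather than hidden. Two
constant, equal groups return (t = 0, p = 1) instead of NaN.

P-values are Benjamini–Hochberg adjusted within the comparison (statsmodels
`fdr_bh`, verified in the tests against a brute-force step-up oracle).
A *statistically poor* comparison — min adjusted p > 0.05, i.e. nothing
survives adjustment — falls back to raw p-values; the decision is logged
and recorded per comparison. Significance is `p < 0.05` **and**
`log2FC > 1 or < −1`, both strict, matching the stated cut-offs read
literally; boundary values are excluded.

## Harmonization and merging

Platform identifiers are mapped to a canonical namespace through a single
user-supplied two-column table; unmapped records are dropped or kept by
policy, with counts reported. No live database access is performed — the
original multi-database chain is collapsed into that one mapping input.
Within a comparison, records sharing a canonical id are collapsed exactly
once, at the merge stage: same-sign fold changes are arithmetic-mean
averaged, strict sign conflicts (some > 0, some < 0; zeros neutral) remove
the molecule. The merged record keeps the minimum p-value of its members —
the source procedure specifies averaging only for fold changes, so the
best-evidence p is kept as a stated convention. Collapse precedes
thresholding by default (the order is switchable), so an averaged molecule
is judged once on its merged fold change. The long table keys on
(canonical_id, comparison_id); a gene absent from a comparison has no row —
absence is never imputed as zero effect.

## Stratification

PCA runs on the comparisons × genes log2FC matrix (post-threshold rows by
default, switchable), missing entries filled with 0 — absence-of-evidence
treated as no-change, a convention, since nothing better is derivable from
DE tables alone. Columns are mean-centered by the PCA itself
(scikit-learn, full SVD; validated against an explicit covariance
eigendecomposition at 1e-8). The historical outlier removal this replaces
was visual; here a comparison is flagged when its score on any of the first
`n_components` (default 2) components deviates from the component median by
more than `k · 1.4826 · MAD` (default k = 3). Components with zero MAD are
skipped with a warning; a manual removal list is honoured. The rule is
deterministic and order-invariant, which is the point: the same compendium
always yields the same retained set. On noisy null-like data it will
occasionally flag a legitimate comparison (≈ the tail mass at 3 robust
SDs); that conservatism is preferred over a subjective plot.

## Consensus scoring

Per group and molecule: up- and down-significant occurrences are counted;
the majority direction wins; `occurrences` counts majority-direction
comparisons only; frequency = occurrences / group size. The denominator is
the **full group size** (13 untreated / 22 treated in the default
geometry), not the number of comparisons measuring the molecule — this
reproduces the printed arithmetic (4/13 → 31%, 11/22 → 50%) and penalises
molecules absent from platforms, a conservative bias that is intentional.
Direction ties break toward the side with larger mean |log2FC| and are
logged. `mean_log2fc` averages majority-direction significant occurrences
only; opposite-direction hits set a conflict flag with a count. Tier
thresholds are strict (`>`); at exactly 20% a molecule is excluded, with
the comparison operator exposed for sensitivity checks. Default tiers
(general 20/17/14/11%, non-treated 23/15%, treated 23/18/14%) are shipped
as given by the source threshold table, not recomputed.

## Concordance

A reference panel gene is classified against a comparator group's consensus
records by log2FC sign: `ns` (not significant there), `concordant`,
`discordant`, or `ambiguous` when the comparator's direction vote is an
exact tie (occurrences = opposite_count), in which case no sign comparison
is meaningful. "Overlap" counts all non-`ns` statuses, including ambiguous
— mirroring the dual usage of overlap-regardless-of-direction vs
similar-trend in the source analysis, with the ambiguous case surfaced
explicitly instead of silently resolved.

## Enrichment

Over-representation uses the exact hypergeometric upper tail P(X ≥ k) with
BH adjustment across terms (the same adjuster as the differential stage,
bit-for-bit). The pathway z-score standardises k by its hypergeometric
mean and variance, including the finite-population factor
`1 − (n−1)/(N−1)`; zero variance (term set empty or equal to the universe)
yields z = 0 with a warning. The permutation p-value is
`(1 + #{z_perm ≥ z_obs}) / (n_perm + 1)` — add-one to avoid p = 0 — over
uniform random panels of the observed size. Because z is monotone in k for
fixed (N, K, n), the null panels are drawn as hypergeometric counts
directly, which is distributionally identical to sampling panels and
intersecting, and orders of magnitude faster; the tests confirm agreement
with the analytic tail within Monte-Carlo error. Term clustering, network
layout and GO-graph operations are out of scope.

## Synthetic compendia

The generator emulates the statistical structure the pipeline assumes, not
microarray physics: expression is Gaussian on the log2 scale around
per-gene baselines (sd 1 around a baseline mean of 8, typical of normalised
log2 array intensities), so log2FC is exactly a difference of means.
Planted genes carry a mean shift (`effect_log2fc`) in their target groups
with per-comparison probability `penetrance` — the generator's analogue of
cross-study consistency — sign-flipped with `sign_flip_rate` (default 0.05)
and subject to per-comparison platform dropout (default 0.10). Defaults:
noise_sd 1.0, effects ~2–2.5, 10 case + 10 control samples; group geometry
13/22/2/3/14 comparisons, mirroring the study conditions. Where the
emulated study states no value, defaults are stated conventions chosen once
(effect sizes in the 1.5–3 range are ordinary microarray DE magnitudes),
not estimates. One root seed drives everything through per-comparison
substreams keyed by a stable CRC of (group, index), so generation is
bit-reproducible and order-independent.

What the generator does **not** model: probe-level artifacts, batch
effects beyond sign flips/dropout, correlated genes, miRNA-specific
structure, non-Gaussian heavy tails. Passing recovery tests therefore
demonstrates correctness of the pipeline's logic under its own model
assumptions — not robustness to everything real compendia contain.

## Validation experiments and problem sizes

* **Zero-noise limit**: penetrance 1, noise_sd 1e-6 (the config requires
  strictly positive noise; 1e-6 makes every realized effect certain to be
  detected without degenerate t-tests), 13 comparisons, 60 genes, 6 planted
  both directions → the consensus panel equals the planted set exactly at
  every tier.
* **Frequency recovery**: 500 replicates × 13 comparisons, 40 genes, 3
  planted (effect 2, penetrance 0.3, noise_sd 1, dropout and sign-flip 0),
  20 samples per arm so per-occurrence detection power is ≈ 1 and the
  detected frequency estimates penetrance cleanly; the replicate-averaged
  frequency must fall in the 95% binomial CI of the penetrance given the
  19,500 realization draws. These sizes keep the experiment at desk scale
  while leaving the binomial comparison sharp.
* **Null calibration**: 100 null compendia × 200 genes; the rate of genes
  crossing the 20% tier must stay below P(Binom(13, 0.05) ≥ 3) ≈ 0.0245,
  the bound implied by per-comparison α = 0.05 alone (the additional
  |log2FC| > 1 requirement makes the observed rate far smaller).

## Numerical conventions and degenerate inputs

BH on an empty vector returns empty; `choose_pvalue_column` on empty input
reports `used_adjusted=True` vacuously. Constant equal groups → (0, 1);
constant shifted groups → (±inf, 0). PCA refuses all-zero (degenerate)
matrices and matrices with fewer than 2 rows. Tier thresholds must be
strictly decreasing in (0, 1]. Fixture panels validate on load (16 rows,
sign/direction consistency, positive occurrence counts). Frequencies are
reported at full precision internally and rounded to integer percent only
in human-readable output.

## Known limitations

The poor-dataset fallback makes a comparison-level (not gene-level)
decision; a single strong gene keeps adjusted p-values for the whole
comparison. The group-size denominator under-scores genes missing from
platforms by construction. The ambiguous concordance status has no
published analogue count to validate against. The enrichment stage assumes
an unstructured universe (no gene–gene correlation), as hypergeometric ORA
always does.
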