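# Methods

## Model and parameterisation

Counts are modelled gene-wise as negative binomial with log link,
`y_gi ~ NB(mu_gi, phi_g)`, `log mu_gi = x_i' beta_g + o_i`. The design is
parameterised by cell means — one coefficient per strain:salinity cell
(24 for the default 8 × 3 layout) — rather than reference coding. Every
comparison of interest is then a zero-sum weight vector over cells, the
"average" and interaction identities hold exactly, and no coding
convention can leak into contrast definitions. Coefficients are reported
in log2 (the fold-change convention of the output tables); fitting is in
natural log internally.

Offsets are natural-log effective library sizes: total counts times TMM
scaling factors (trimmed mean of M-values; trim fractions 0.30 on M and
0.05 on A, inverse-asymptotic-variance weights, reference sample chosen by
upper-quartile closeness to the mean; factors normalised to geometric
mean 1). Genes are pre-filtered to CPM ≥ 1 in ≥ 3 samples (one replicate
group) by default; both thresholds are configurable.

## Fitting

All genes share one design matrix, so IRLS is vectorised: each iteration
updates every gene's coefficient vector with a batched solve of the
weighted normal equations (weights `mu/(1 + phi·mu)`), with per-gene
step-halving whenever a proposed step would increase the deviance.
Convergence is declared at a relative deviance change below 1e-8, with a
cap of 100 iterations; non-converged genes are flagged but reported.
Linear predictors are clipped to ±40 so cells observed at zero remain
finite.

## Dispersion estimation

Gene-wise dispersions maximise the Cox–Reid adjusted profile likelihood
(APL; the profile log-likelihood penalised by half the log-determinant of
the weighted information), evaluated on a fixed 19-point geometric grid of
phi from 1e-4 to 16. To borrow strength across genes, the per-gene APL
curves are smoothed by a moving average over genes ordered by average
log2 CPM (window 25% of genes), and each gene maximises

    APL_g(phi) + (prior_df / residual_df) · APL_trend(phi)

with prior_df = 10 by default — an empirical-Bayes compromise between the
gene's own likelihood and the abundance trend. The grid maximum is
refined by quadratic interpolation in log phi; genes maximised at the
lower grid boundary report phi = 0 (e.g. replicates identical within
every group). The weight `prior_df / residual_df` makes shrinkage fade as
replication grows.

## Contrast testing and the two-stage procedure

The default per-contrast statistic is the likelihood-ratio test: the
model is refit under the single constraint `w' beta = 0` (the constrained
design is the full design projected onto the null space of `w`, warm
started from the unconstrained fit) and the deviance difference is
referred to chi-squared with 1 df. A quasi-likelihood F variant
(deviance-based QL dispersion, F(1, residual df)) is available by flag
for data with residual overdispersion the NB model misses.

Stage I (screening) tests each gene's global null over the whole family —
the LRT against the model constrained by the family's span (rank 16 for
the 27-contrast salinity set, 14 for the 84-contrast interaction set;
linearly dependent contrasts are absorbed into the span). Screening
p-values are BH-adjusted (Padjscreen); genes at Padjscreen ≤ α proceed.

Stage II (confirmation) tests individual contrasts only for the R
screened genes (of m tested). Within each gene the family of raw
p-values undergoes a step-down familywise correction — Holm by default; a
Shaffer variant exploits the constraint that of three pairwise
differences among three salinity means, at most one can be null once any
is false (multipliers shrink to 1 per strain-triple after its first
rejection). Decisions are taken at the stage-II level α·R/m; reported
Padj values are the within-gene adjusted p-values rescaled by m/R and
clipped at 1, so "call iff Padj ≤ α" reproduces the procedure and the
whole two-stage pipeline controls the gene-level FDR at α. Raw
confirmation p-values are computed only for screened genes (others are
NaN): unscreened genes receive no stage-II decisions, and skipping their
84-contrast refits keeps full runs fast.

The two families are always tested separately and never pooled.

## Set logic

Interaction-DE genes are classified from the *per-strain salinity-set
calls*: a gene is "direction" if some salinity pair has at least one
strain with a confirmed positive and another with a confirmed negative
call — the same pair, which is the strictest unambiguous reading of
"up in some strains, down in others" — and "magnitude" otherwise.
Interaction-DE genes lacking per-strain salinity information default to
magnitude and are flagged.

The core response intersects, over strains, the genes with ≥ 1 confirmed
per-strain contrast; average-response calls do not count. As an
intersection of marginally FDR-controlled sets it carries no joint 5%
guarantee; the module reports the plain intersection and leaves
descriptive evidence (e.g. max-over-strains Padj) to the caller. The
uniquely-DE partition (one strain only / one strain + average / average
only / multi-strain) pools the salinity pairs of each block by default.

The "confect" ranking is a simplified confident-effect ordering: per
gene, the largest-|logFC| contrast contributes a Wald-style lower
confidence bound on |logFC| (its SE implied by the LRT p-value) at a
step-down FDR-adjusted level, with monotonicity enforced down the
ranking. It is an approximation to the published confident-effect-size
procedure, adequate for ranking; the bounds themselves should not be
quoted as calibrated intervals.

## Enrichment

ORA uses the one-sided hypergeometric upper tail. The elim variant
processes terms children-before-parents; a term with p below the elim
cutoff (default 0.01, the conventional choice) has its annotated genes
removed from all ancestors before they are tested. Terms fully depleted
by their children score the trivial p = 1. Only `is_a` edges are
traversed; annotations are propagated to ancestors before testing. The
default universe is the filtered (expressed) gene set.

The competitive test compares a set's mean per-gene statistic to the
rest, inflating the set variance by `1 + (m−1)·rho_bar`; `rho_bar` is the
mean within-set residual correlation (estimated from log-CPM residuals
about the cell means; floored at 0 to avoid deflation). The pipeline
feeds signed z-scores derived from each contrast's raw p-values.

## Ordination and growth

The leading-logFC distance between two samples is the RMS of the top-n
(default 500) largest absolute per-gene log2-CPM differences, the top
genes re-selected for every pair; the prior count is 2, scaled by
relative depth. Classical (Torgerson) MDS embeds the distances;
non-positive eigenvalue axes are dropped with a warning, and the sign of
each axis is fixed by making its largest-magnitude loading positive. The
Poisson distance is the square root of the summed per-gene Poisson
deviance of two depth-normalised profiles (median-of-ratios size factors,
total-count fallback) against their pooled mean, with 0·log 0 = 0 — a
closed-form, testable member of the family of Poisson-model
dissimilarities. Cluster concordance is the mean silhouette width
computed once with strain and once with salinity labels; it is a
quantified surrogate for "which factor do samples cluster by", not a
significance test. The robustness recipe recomputes distance + silhouette
after dropping a supplied gene blocklist.

Growth rates are per-transfer OLS slopes of ln(relative fluorescence)
against time in days; condition summaries are the mean and SD over
replicates × transfers. Transfers with fewer than two points are skipped
with a warning.

## Synthetic data

The generator draws NB counts under exactly the fitted model class:
gamma–Poisson with gene-wise dispersion (lognormal, median 0.1, log-SD
0.5), baseline log2 means N(6, 2), per-sample depth multipliers lognormal
with log-SD 0.2, and the default 8 × 3 × 3 design. Effect classes
partition the genes: a configurable fraction carries a shared salinity
response (default 10%, |log2FC| = 2 between the extreme salinities,
linear ramp across levels); 30% carry strain main effects (N(0, 2) per
strain — four times the salinity-effect spread, so strain structure
dominates sample ordination); 5% each carry the two interaction
subtypes. Magnitude-type genes respond in a random proper subset of
strains with one sign; direction-type genes split the strains into two
disjoint subsets with opposite-sign responses, which guarantees the
class-defining opposite-sign property at every split. Identical seeds
give bit-identical output.

What the generator does *not* emulate: GC/length biases, batch or
harvest-level effects (the motivating experiment pooled two harvests per
RNA sample; no harvest-level variance component is reported to
calibrate one), read-level artefacts, or single-cell zero inflation.
Passing tests therefore demonstrate correctness of the statistical
machinery under the assumed model, not robustness to the full messiness
of real libraries.

## Problem sizes and numerical choices

Validation simulations use 25 seeds of 2,000-gene experiments for FDR
checks (the full default design) and 600-gene experiments with enriched
interaction fractions (15% + 15%) for classification recovery, where
recovery rates are scale-free in gene count but require enough planted
genes per seed. The dispersion grid, IRLS tolerances (1e-8 full fits,
1e-6 inside the dispersion grid), eta clipping at ±40, and the 1e-10
ridge on the normal equations are fixed constants chosen for stability;
all user-facing thresholds (α, filters, prior df, elim cutoff, top-n
values) are exposed in `PipelineConfig`.

## Known limitations

- The LRT with plug-in shrunk dispersions is slightly liberal in theory;
  empirically the two-stage procedure's FDR stays below nominal in the
  validation suite. The QL-F flag is the conservative alternative.
- The confect ranking is approximate (above).
- The Shaffer variant applies only to families whose names parse into
  blocks of three pairwise salinity comparisons; other families fall
  back to Holm.
- Average contrasts weight strains equally; with unbalanced replication
  a sample-weighted average would differ (not provided).
- The elim implementation handles `is_a` edges only; `part_of` and other
  relations are ignored.
- Direction classification is conservative by construction: a gene's
  between-strain interaction contrast carries roughly the sum of the two
  opposite per-strain effects, so interaction detection is easier than
  confirming *both* sides of the split in the per-strain salinity calls.
  Genes whose weaker side misses stage-II confirmation land in
  "magnitude" even when the planted effect reverses sign, so the
  direction category has high precision but imperfect sensitivity among
  interaction-DE genes.
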