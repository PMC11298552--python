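# Methods

This note documents the statistical models implemented in `methylvar`,
their assumptions, the defaults that matter, and what the synthetic-data
generator does and does not emulate.

## Data model and coordinates

Internal coordinates are 0-based half-open (BED convention); Bismark
coverage and CX reports (1-based) are converted on read and the stated
percent-methylation column is always recomputed from the counts. A
(CpG, sample) cell with `total_reads = 0` is *missing*, never 0 %
methylation. Symmetric CpG pairs on opposite strands are not merged by
default (`merge_symmetric_strands` is available); the coverage filter is
applied to whichever representation the caller chose. Upstream features
span exactly 1,000 bases 5' of each gene, truncated at contig boundaries;
genes split across contigs are dropped.

## Gene-body methylation

CpGs need ≥ 10 reads in a sample to count there (`min_cov`, inclusive).
The gene-level summary is the weighted methylation level
`W_gs = Σ_c meth_{cgs} / Σ_c total_{cgs}` over the gene's passing CpGs —
a coverage-weighted mean, invariant to splitting a site's reads across
pseudo-sites and bounded by the per-CpG fraction range. Per-CpG
methylation calls use a one-sided binomial test against the bisulfite
non-conversion rate (default 1 %, a conservative ceiling for conversion
efficiencies in the 99.1–99.5 % range), BH-corrected within sample; these
calls are descriptive and do not feed the gene-level analyses.

## Methylated-gene classification

**Mixture route.** Gene × sample `W` values are pooled, transformed by
`logit((W + ε)/(1 + 2ε))` with ε = 1e-3 (defined at both boundaries;
a raw-scale mode exists via `use_logit=False`), and fitted with a
two-component Gaussian mixture (EM, 5 restarts, tolerance 1e-8, ≤ 500
iterations). The higher-mean component is "methylated". A degenerate fit
(component weight < 1e-3 or coincident means) falls back to a
midpoint-threshold rule with a warning. A gene is called methylated when
its posterior exceeds 0.5 in at least ⌈0.85 × n_samples_with_data⌉
samples; the consistency rule means population-specific methylated genes
are intentionally *not* called by this pooled route.

**Random-intercept route.** Per-CpG, per-sample methylation fractions of
one population's samples are binarized by 2-state kmeans (10 restarts,
seed 42; the higher-centre cluster is state 1), and the binary states are
modelled as `state ~ 1 + (1|gene)`, a logistic random-intercept model.
Because the likelihood factorizes over genes given the global intercept
β₀ and random-effect SD σ, the marginal likelihood is a product of 1-D
integrals; we evaluate them with 25-node Gauss–Hermite quadrature and
maximize over (β₀, log σ) with L-BFGS-B. Conditional modes `u_g` come
from damped per-gene Newton steps. With perfectly separated data
(all-0 vs all-1 genes) the likelihood is unbounded in (β₀, σ) without
affecting the ordering of the modes, so the optimizer is bounded
(β₀ ∈ [−15, 15], σ ∈ [0.05, 8]). On non-separated data the conditional
modes agree with lme4's `ranef` to r > 0.9999. A gene is methylated when
`u_g > 2.5` (log-odds scale, strict), applied per population to produce
the FC/NC sets and their shared / FC-only / NC-only / neither partition.

## Differential methylation and empirical FDR

Gene-level aggregated counts (M, T) per sample enter a binomial GLM with
logistic link and prior weights T; the design is intercept + condition
(+ block dummies when ≥ 2 blocks are present — on by default, matching
the expression analysis). The fit is IRLS vectorized across genes (all
genes share the design matrix), which makes the 1000-shuffle permutation
runs cheap; coefficients match statsmodels' GLM to < 1e-6. A condition
whose cells are all 0 % or all 100 % (complete separation) receives a
0.5-read continuity correction and is flagged. The family is pure
binomial: extra-binomial variation inflates significance, exactly the
behaviour of a base weighted GLM; a quasi-binomial mode (`quasi=True`)
rescales by the Pearson dispersion with t-based p-values. Genes with
BH-adjusted p < 0.01 (strict) are DMGs.

The empirical FDR shuffles the sample labels of the contrast uniformly
over assignments with the observed group sizes (the identity assignment
is allowed), re-runs GLM + BH + threshold each time, and reports the
plug-in estimator `#{null ≥ observed}/n_shuffles` (which can be exactly
0) alongside the add-one estimator. Note the plug-in p has a resolution
floor of `2/C(n, k)` per shuffle from exact or complement re-draws: with
a 4v4 contrast (70 assignments) a 100-shuffle run ties with probability
≈ 0.03 per shuffle, so study designs intended to *demonstrate* p = 0 need
a permutation space much larger than the shuffle count (the calibration
study in the acceptance tests uses a 12v12 contrast for this reason, with
a planted log-odds effect of 0.45 so that full-strength effects are
detected while half-diluted permutation leaks fall below the BH
threshold).

## CpG coordination

For a gene set, each repeat samples 100 genes (without replacement),
enumerates all unordered CpG pairs within each gene, and computes
pairwise-complete Pearson correlations of methylation fractions across
samples (pairs need ≥ 4 joint observations; zero-variance profiles are
skipped). The null repeats the procedure after uniformly permuting the
CpG → gene assignment within the drawn set. Correlations pool all samples
across conditions (maximising n at 14 WGBS samples; a per-population run
is a matter of passing a sample subset). The coordinated-vs-null contrast
is the difference of pooled means plus a two-sided rank-sum test on
per-repeat means.

For small population- or environment-specific sets the rank-sum over
repeats is inappropriate: repeats of a small fixed set share almost all
pairs, so the test treats any fixed offset — however tiny — as
significant (pseudo-replication). Overlay sets are therefore compared by
`overlay_vs_null`: the single whole-set within-gene mean against the
Monte-Carlo null distribution, with an add-one empirical two-sided p.

## Expression variability

Counts are normalized by median-of-ratios size factors (computed over
genes expressed in every sample, rescaled to geometric mean 1). Genes
with < 15 counts in > 90 % of samples are removed first. Per population
(environments pooled), `CV² = s²/μ²` (unbiased variance) is computed per
gene and `log CV²` is regressed on `log μ` with a local-quadratic,
tricube-weighted smoother (span 0.75, no robustness iterations; written
here because no installed package provides degree-2 loess). The residual
is the variability statistic: a gene at twice the trend sits ≈ log 2
above zero, and residual *ordering* is invariant to rescaling all counts.
The log–log fit is a deliberate choice over a raw-scale fit (numerically
robust over ~5 decades of expression; raw mode via `log_scale=False`).
Set comparisons use two-sided rank-sum tests; the cross-population
comparison of population-specific methylated genes uses the per-gene
difference of residuals (FC − NC), tested by signed-rank (against a
reference set by rank-sum when one is given).

The differential-expression stage is declared plumbing: log₂ fold change
of normalized group means (0.5 pseudocount), a negative-binomial Wald
test with method-of-moments gene-wise dispersion, BH correction, and the
strict call `q < 0.05 AND |log₂FC| ≥ 1`. Its outputs only feed overlap
statistics; it is not a shrinkage-based DE method and planted 2-fold
changes straddle the |log₂FC| ≥ 1 gate by construction.

## Set statistics

Fisher's exact overlap tests report the sample (unconditional) odds ratio
with a Haldane–Anscombe 0.5 correction iff a cell is zero (flagged), and
the exact conditional two-sided p. The universe is always an explicit
argument — overlap statistics are meaningless without one. The slope test
fits OLS `y ~ x` and tests slope ≠ 1 by refitting `(y − x) ~ x`, so
`y = x` yields statistic 0 and p = 1. The SNP divergence rule is strict
and symmetric: some SNP with frequency > 0.8 in one population and < 0.2
in the other.

## Synthetic-data generator

The generator emulates the assayed design: two populations (FC/NC) × two
care environments × 2 blocks, WGBS 3–4 libraries per condition (14
total), RNA-seq 11–12 per condition (46 total). Defaults (a `SimConfig`
with 2,000 genes; `SimConfig.scaled(n)` shrinks planted-set sizes
proportionally):

- **Methylomes.** 39 % of genes methylated in both populations, plus 32
  FC-only and 40 NC-only genes (~1.6 %/2 % of genes, the proportions of
  population-specific methylation in this kind of design). Methylated
  CpGs draw latent fractions from Beta(9, 1); unmethylated CpGs from a
  Beta with mean = the 1 % non-conversion rate (Beta(1, 99)). Coverage is
  negative-binomial, mean 18×, size 10 (SD ≈ 7.5 per CpG, emulating
  real coverage spread); methylated reads are binomial in the latent
  fraction.
- **Planted methylation changes.** 60 coordinated genes: one log-odds
  shift (default 2.0) applied to every CpG, random sign per gene, in the
  NC population. 60 sparse genes: 20 % of CpGs shifted with independent
  random signs per CpG — scattered perturbations with no net gene-level
  change, so they are detectable as coordination *non*-signal but not as
  gene-level DMGs (DMG sensitivity is defined over the coordinated set).
- **Expression.** Log-normal gene means (log-mean log 60, log-SD 1.3);
  genes methylated in a population get 2× mean and 0.5× NB dispersion
  (base 0.2) in that population's samples — the causal link behind the
  variability analyses. 60 planted DEGs at 2-fold in the NC population;
  log-normal size factors (log-SD 0.15).
- **SNPs.** 20 divergent genes with a (0.9, 0.1) SNP; background SNP
  frequencies ~ N(0.5, 0.05) in both populations.

One global seed fans out to per-stage child seeds (genome / methylome /
expression / SNP), so outputs are byte-identical under a seed and stages
can be regenerated independently.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: background genes carry no per-sample biological
variation in methylation (the binomial GLM is therefore exactly
calibrated on nulls here, whereas real WGBS has extra-binomial variation
that inflates its significance — use `quasi=True` there); there is no
environmental responsiveness of methylation (planted changes are
population-level, so the environmental and reversal contrasts are true
nulls); no sequence context, read-level errors, mapping biases, TEs, or
non-CpG methylation; and expression effects of methylation are imposed,
not mechanistic.

## Numerical choices

- GLM IRLS: η clipped to ±30, ridge 1e-10 on the normal equations,
  convergence at max |Δβ| < 1e-10, ≤ 60 iterations.
- Mixture EM: scikit-learn backend, spherical covariance, reg_covar
  1e-10.
- kmeans binarization: fixed seed 42; constant input returns all-0 with a
  warning.
- Loess: k = ⌈span·n⌉ nearest neighbours (contiguous window on sorted x),
  tricube weights, exact zero-distance windows get uniform weights.
- Paired variability comparison with all-zero differences reports p = 1
  with a warning (degenerate signed-rank).
- Empirical-p estimators: plug-in and add-one both reported.

## Problem sizes

The test suite and `scripts/acceptance.py` run simulations at 500–2,000
genes, 5–25 CpGs per gene, and the design's sample counts; permutation
runs use 100 shuffles per replicate and 10–20 seeded replicates per
claim. These sizes give each statistical check comfortable power while
keeping a full run in minutes on one CPU.

## Known limitations

- The pure-binomial DMG test is anticonservative under real biological
  overdispersion; the quasi-binomial mode is the honest default for real
  data but is not what a base weighted GLM reports.
- The random-intercept classifier's 2.5 threshold is interpreted on the
  conditional-mode log-odds scale; fits on perfectly bimodal data sit at
  the optimizer's σ bound by construction.
- The plug-in empirical FDR cannot distinguish p = 0 from
  p < 1/n_shuffles, and has the combinatorial tie floor described above.
- `simple_de` is intentionally minimal and should not be used as a DE
  method in its own right.
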