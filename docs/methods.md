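# Methods

## Generative model

One replication is a balanced two-group experiment with `n_per_group = 50`
(N = 100). The condition code X is effect-coded (−1 block, then +1 block;
all downstream statistics are permutation invariant, and a fixed order
simplifies golden tests). The latent attribute is

    T = r_TX · X + sqrt(1 − r_TX²) · e_r,   e_r ~ N(0, 1) iid,

i.e. a two-component normal mixture with group means ±r_TX, within-group SD
sqrt(1 − r_TX²), population mean 0 and variance 1, and corr(T, X) = r_TX
*exactly*. We use the exact parameters rather than three-digit roundings of
them (e.g. SD 0.866... not 0.865 at r_TX = 0.5); at r_TX = 1 the mixture
degenerates and T ≡ X. The manipulation check is the attenuated copy
M = r_TM·T + sqrt(1 − r_TM²)·e_m.

The outcome is a linear combination of T and M plus independent noise,
Y = w₁T + w₂M + σ_res·e_y, with the weights solving

    w₁ + w₂·r_TM = r_TY
    w₁·r_TM + w₂ = r_MY

so the population correlations of Y with T and M equal their targets
exactly, and σ_res² = 1 − (w₁² + w₂² + 2w₁w₂·r_TM) so Y has unit variance.
Standardization is therefore *by construction at the population level*; we
never re-standardize samples, which would distort bootstrap behavior.

### Feasibility

A grid cell is generable only if σ_res² ≥ 0 (tolerance −1e−12 against
floating-point sign flips at exact-zero boundaries) and the implied 4×4
correlation matrix of (X, T, M, Y) is positive semi-definite. On the
canonical grid this excludes exactly the four cells with
(r_TM, r_MY, r_TY) = (0.95, 0, 0.5): demanding an outcome uncorrelated with
a nearly errorless check yet strongly driven by the attribute forces
offsetting loadings whose joint variance exceeds one. Note the rule depends
only on (r_TM, r_MY, r_TY), never on r_TX. A second mode, `paper_list`,
excludes a fixed published list of four cells that swaps two of these for
two r_TX = 0.95 cells; that list cannot arise from any outcome construction
that depends only on (r_TM, r_MY, r_TY), so we expose both modes rather
than guess at the unpublished generation details. Both leave 68 cells. All
headline results use r_TX = 1 cells, where the observable (X, M, Y) joint
law is fully determined by (r_TM, r_MY, r_TY) and the two modes agree.

## Analysis of one replication

* **t-test**: pooled-variance Student t of Y between condition levels
  (groups are balanced with equal population variances by construction;
  for a balanced design its p-value equals the slope test of Y ~ X, which
  the suite asserts). Welch is deliberately not the default.
* **Paths**: OLS with intercepts — a from M ~ X, c from Y ~ X, (c′, b)
  from Y ~ X + M; classical t-based standard errors and two-sided
  p-values. Coefficients are solved from the normal equations (numerically
  identical to standard routines, cross-checked against statsmodels to
  1e−10, and fast enough for ~7×10⁷ bootstrap re-fits). The nested-model
  identity c = ab + c′ holds to 1e−10 on every dataset.
* **VIF**: 1/(1 − r̂²_XM) from the *sample* X–M correlation, averaged over
  replications. At population r_XM = 0.95 the population VIF is 10.256;
  small-sample variation inflates the mean of the sample VIF to ≈ 10.65 at
  N = 100, which is what a reported mean sample VIF reflects.
* **Bootstrap**: nonparametric case resampling of whole (x, m, y) rows,
  size N, `n_boot = 1000`; a and b are re-estimated on each resample from
  its second moments. The CI is the central 95% interval using
  linear-interpolation empirical quantiles (numpy's default convention,
  documented so runs are bit-reproducible); "significant" means the CI
  excludes zero. Degenerate resamples (constant x, or collinear design,
  detected by a relative determinant tolerance of 1e−12) are redrawn so
  exactly n_boot valid values enter the interval — a measure-zero event at
  N = 100 with continuous M, but the contract keeps the count fixed.
* **Detection rules**: `baron_kenny` = t-test, a and b all significant at
  α = 0.05; `bootstrap` = t-test significant and CI excluding zero. Both
  conjunctions require the overall X→Y effect. We additionally record the
  **CI-only rate** (interval excludes zero, regardless of the t-test):
  published summary tables of this design report rates of 1.000 in cells
  where the t-test alone has power ≈ 0.87, which is only consistent with
  the indirect-effect test alone, so the runner reports all three rather
  than silently choosing an interpretation. In cells with r_XY = 0.5 the
  t-test has power ≈ 1 and the conjunction and CI-only rates coincide.

Detection rates, ab moments and mean VIF are computed over *all* completed
replications (no conditioning on a significant t-test as a gate, and no
selection on detection for the moments — the latter is what makes the mean
ab match the closed-form population value).

## Population oracle

With standardized variables, a = r_XM, c = r_XY,
b = (r_MY − r_XY·r_XM)/(1 − r_XM²), c′ = (r_XY − r_MY·r_XM)/(1 − r_XM²),
ab = a·b, VIF = 1/(1 − r_XM²), and the observables follow from the latent
design as r_XM = r_TX·r_TM, r_XY = r_TX·r_TY. The oracle doubles as a
design advisory (`whatif_report` / `tmc-sim oracle`): given planned
correlations it reports the paths a mediation analysis would estimate in
expectation, the VIF, and a mediation class — `consistent` (ab and c share
sign), `inconsistent` (suppression: opposite signs), or `null`
(|ab| < 1e−10; population quantities are analytic, so an exact-zero
tolerance suffices).

The r-to-d conversion uses the balanced-groups formula d = 2r/√(1 − r²)
(r = 0.95 → d ≈ 6.085). Alternative conversions based on rounded mixture
parameters give slightly different values at r = 0.5 and 0.7 (Δμ/σ_within
yields 1.155 → sometimes printed 1.16, and 2.00); no single formula
reproduces all three conventional prints, so we standardize on the cited
conversion and note the mismatch here.

## Randomness and reproducibility

A single study seed spawns child streams through `numpy.random.SeedSequence`
keyed by `(study_seed, condition_index, replication_index, purpose)` with
purpose ∈ {latent, check, outcome, bootstrap}. The condition index refers
to the *full* lexicographic grid before feasibility filtering, so streams
are independent of which cells run and in what order: serial and parallel
(`joblib`) execution give identical results, and any replication can be
regenerated bit-for-bit in isolation.

## Problem sizes

The canonical configuration is the full factorial study: 68 feasible
conditions × 1000 replications × 1000 bootstrap resamples at N = 100
(≈ 4–5 minutes on one CPU with the vectorized bootstrap). The test suite
runs this once and reuses it across checks; unit tests use large-n
(5×10⁵–10⁶ draw) Monte Carlo checks for generator moments and small
(25-replication) studies for orchestration contracts.

## What the simulation does and does not show

The generator reproduces the idealized study conditions: normal,
homoscedastic, linear relationships, balanced groups, a single mediator,
no missing data, population-level standardization. Passing tests therefore
validate the *procedure's behavior under its own assumptions* — e.g. that
high X–M collinearity produces huge, sign-flipped indirect effects
(suppression) and erratic detection, while low manipulation intensity with
a reliable check makes the detection rate track r_MY. They say nothing
about non-normal outcomes, unbalanced designs, heteroscedastic treatment
effects, or multiple/sequential mediators, all of which are out of scope.

Known limitations: the percentile bootstrap's null rejection rate is only
asymptotically α (observed ≈ 0.05–0.07 at N = 100); the `paper_list`
feasibility mode reproduces a published exclusion list whose generating
rule is not recoverable; and detection-rate comparisons across seeds carry
binomial Monte Carlo error of up to ≈ ±0.03 at 1000 replications, which is
why qualitative pattern assertions use slack margins of that order.
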