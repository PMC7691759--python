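# Methods

This note documents the statistical models, the estimation machinery,
the synthetic-data generator's assumptions, and the design choices made
where more than one defensible option existed.

## Single-trial model and repeatability

Each trial is an alpha-lattice with `r` replicates (default 2) and
equal-size sub-blocks nested in replicates.  The plot model is

    y_ijk = mu + R_j + SB_k(R_j) + G_i + e_ijk,

replicates fixed, sub-blocks iid `N(0, sigma2_sb)`, residuals iid
`N(0, sigma2_e)`.  Two companion REML fits are run:

* genotypes **fixed** — GLS-adjusted entry means at the REML estimates
  of `(sigma2_sb, sigma2_e)`;
* genotypes **random** — `sigma2_g` for the repeatability.

Repeatability is reported on the **entry-mean basis**,
`H2 = sigma2_g / (sigma2_g + sigma2_e / r)`; the basis is recorded in
the output so results are auditable.  A trial with no genetic and no
residual variance (0/0) is assigned `H2 = 0` and discarded rather than
raising.  The filter keeps trials with `H2 >= threshold` (default
0.05, strict `<` on the discard side).

Null behavior worth knowing: with two replicates, `H2 >= 0.05` is
equivalent to a genotype/residual mean-square ratio of about 1.05, and
the null distribution of that F-ratio puts roughly 40–45% of its mass
above 1.05 at any realistic entry count.  A pure-noise trial therefore
has a ~55–60% chance of being discarded — not more.  The filter is a
coarse screen against uninformative sites, not a significance test.

REML in this module maximizes the profiled restricted likelihood over
log variance ratios (`gamma_u = sigma2_u / sigma2_e`), with `sigma2_e`
profiled out in closed form and the Woodbury identity keeping each
evaluation at the cost of a q×q Cholesky (q = random-effect levels).
The reported value is the exact log-density of an orthonormal basis of
error contrasts, so different but equivalent factorizations of the same
model produce identical numbers.  Variance components are kept
non-negative by the log parameterization; the lower bound `exp(-18)`
acts as the zero floor.

## Yield-environment classification

Retained trials are pooled across series (class labels must be
comparable across years) and clustered on mean yield with 1-D k-means,
k = 3.  The solver is the exact dynamic program over contiguous
partitions of the sorted means — optimal 1-D k-means partitions are
contiguous — so the stage is deterministic and the seeded Lloyd
multi-start exists only as a cross-check.  Classes are labeled
LYE < MYE < HYE by ascending center; HYE trials are excluded from the
gain analysis (they are generated by the simulator precisely so this
exclusion path is exercised).

## Factor-analytic multi-environment model

Per analysis unit (one series × one class, or the series' LYE+MYE sites
pooled for the "Across" analysis):

    y = X b + Z_r r + Z_g g + Z_ge ge + e

* `b`: fixed site effects;
* `r`: replicate-within-site effects, `Var = diag(sigma2_rj)` per site;
* `g ~ N(0, sigma2_g I)` — lines assumed unrelated;
* `ge`: `Cov = Sigma_ge (x) I`, `Sigma_ge = Lambda Lambda' + D` with an
  s×k loading matrix and site-specific variances `D` (FA(k), default
  k = 1 — the smallest nontrivial structure; k is a config knob);
* `e ~ N(0, sigma2_e I)`.

Sub-block effects are deliberately absent at this stage; the
single-trial model absorbs them locally.

Identifiability: entries above the diagonal of the leading k×k block of
`Lambda` are fixed at zero, and each column's first nonzero entry is
made nonnegative after convergence.  At a single site the interaction
is confounded with the genotype main effect and is dropped.

**Estimation.**  For complete balanced units (every genotype once per
replicate at every site — what the generator produces) the restricted
likelihood factorizes exactly into three independent strata:

1. pure-residual within-cell contrasts — `SS_B / sigma2_e` with
   `s(g-1)(r-1)` df;
2. replicate-mean contrasts per site — variance
   `sigma2_rj + sigma2_e/g`;
3. genotype-centered cell means — their cross-site sample covariance is
   Wishart with `g-1` df and scale
   `sigma2_g J + Lambda Lambda' + D + (sigma2_e/r) I`.

This turns an O(n^3) likelihood into O(s^3) and is the workhorse path;
it is maximized by L-BFGS-B with analytic gradients from data-driven
starts plus one seeded jittered restart.  Unbalanced (or explicitly
requested) fits use a dense marginal-covariance REML over all plots,
feasible at small scale.  Both paths report the same orthonormal-
contrast log-density, verified against an independently built oracle in
the tests.  Convergence uses the optimizer's relative function
tolerance (1e-11); a specific variance at the floor is recorded as a
Heywood warning in the fit metadata.

**BLUPs** are solved at the estimates through the marginal covariance,
`u = G Z' V^{-1} (y - X b_hat)` — numerically stable for any estimate,
including Heywood-collapsed `D` where the Henderson normal equations
would need the inverse of a near-singular G.  The test suite checks the
result against an independently coded dense mixed-model-equation solve
(in the G-scaled form that tolerates singular G) to 1e-8.

**Line predictions.**  The tabulated prediction per genotype is

    mean fixed site effect + u_g + mean over unit sites of u_ge.

Including the mean interaction BLUP matters: the FA likelihood leaves
the split between `sigma2_g` and a fully correlated loading component
weakly identified (exactly flat when all sites' interaction effects are
perfectly correlated), so `u_g` alone can leak genotype signal into the
interaction BLUPs.  The combined predictor is invariant to that split
and collapses to plain genotype means in the noise-free limit.

**Model comparison** reports AIC = −2·loglik + 2·(variance-parameter
count) for FA(k) against the diagonal baseline (k = 0).

## Check-relative yield and gain

Within each analysis unit, `GYC = (BLUP − MeanGY)/MeanGY × 100` with
`MeanGY` the mean predicted yield of the checks present in that series
(check rosters may vary by series; only present checks enter the mean).
The checks' own mean GYC is algebraically zero, and GYC is invariant to
rescaling all yields.

The top `ceil(0.10 × n_noncheck)` non-check entries per series-by-class
unit are flagged as highest-yielding lines (ties broken by genotype id
for determinism).  Pooled across series, per-line GYC values are
regressed on the series index by unweighted OLS (a per-series-mean mode
exists but is off by default; the per-line mode is what produces R²
values in the 0.3–0.7 range seen on realistic data).  The %/yr slope is
converted to kg/ha/yr by multiplying with the class's mean check
predicted yield — so `slope_kg / slope_pct = mean check yield (kg/ha) /
100` holds exactly by construction.

Selecting the top decile on estimated GYC induces a constant upward
shift of the selected points (selection on noise) but no slope bias to
first order, since the selection intensity is the same in every series.
BLUP shrinkage attenuates the recovered slope slightly when the number
of sites per unit is small; at the default 10 sites per class the
attenuation is a few hundredths of a point.

A caution on the slope's standard error: HYL points from the same
series share part of their error (the unit's check-mean estimate and
its shrinkage level), so the per-line OLS standard error is somewhat
optimistic and the nominal 95% CI of the slope covers the truth at
roughly 85–90% in the shipped zero-trend calibration runs.  The null
slope itself is unbiased.  The per-series-mean regression mode
collapses each series to one point and is correctly calibrated, at the
cost of discarding the within-series spread that the default mode (and
its R² values) reflects.

## Coancestry and grouping

`f(i,i) = (1 + f(p1, p2))/2` and `f(i,j) = (f(p1(i), j) + f(p2(i),
j))/2` expanding the individual with the greater generation depth
(which is never an ancestor of the other); unknown parents are unique
unrelated non-inbred founders; a selfed ancestor is written as
`parent1 = parent2`.  The full matrix uses the tabular method in
topological order; the pairwise entry point uses memoized recursion,
and the two are cross-checked.  Twice the COP matrix is a numerator
relationship matrix, hence positive semidefinite — asserted against
eigenvalues in the tests.

Grouping: the COP matrix rows are column-centered (a `raw` mode
exists), decomposed by SVD, and lines are clustered by seeded
multi-start k-means on the leading `max(2, n_groups − 1)` component
scores; reported coordinates are PC1/PC2.  Clustering in exactly two
dimensions is not enough in general: G well-separated ancestor groups
span G−1 dimensions of the centered COP matrix with near-equal
variances (measured 0.47/0.38/0.31 for four balanced families), and a
2-D projection can superimpose two groups.  Group labels are renumbered
1..G by decreasing size so output is reproducible.  This automated rule
stands in for grouping by visual inspection of pedigrees; it recovers
generated ancestor groups with adjusted Rand ≥ 0.9 under strong
within-group mating, but real pedigrees curated by hand may split
differently.

## Synthetic-data generator

The generator emulates an annual international semi-arid nursery:

* 12 annual series; 50 entries per trial of which 3 are long-term
  checks with frozen merit (the premise that makes the check mean a
  valid cross-year yardstick); an optional presence table lets checks
  enter or leave specific series.
* Alpha-lattice layout: 2 replicates, 5 equal sub-blocks per replicate,
  assignment by seeded random partition — the analysis needs only the
  nesting structure, not an optimal alpha design.
* Sites per series: 10 low- + 10 medium- + 2 high-yielding, class mean
  yields 2.4 / 4.6 / 6.5 t/ha, site means jittered by
  `sigma2_site = 0.09` — without between-site spread the classification
  stage is degenerate.  The high class exists to exercise the
  classify-and-drop path.
* Genetic merit: checks `N(0, sigma2_g)`; new lines in series t are
  drawn around `trend_pct/100 × t × (reference check yield)`, i.e. the
  trend is expressed per year as a percentage of the check yield
  (default 1.8 %/yr).  Genotype effects scale proportionally with the
  class yield level, so the same percentage trend is recovered in every
  class — consistent with per-hectare gains growing with the yield
  level.
* G×E: one latent factor per site by default (loading variance 0.04)
  plus site-specific noise (0.02); `sigma2_rep = sigma2_subblock =
  0.01`, `sigma2_e = 0.05`, `sigma2_g = 0.0625` (all (t/ha)²) — yields
  plot-level CVs near 9% at low-yield sites and single-trial
  repeatabilities around 0.7–0.85, typical of managed drought trials.
* The truth channel (per-genotype merit and true check-relative yield,
  per-site class and loadings) is emitted beside the data and never
  consumed by estimation.

What the generator does **not** emulate: spatial field trend within
trials, weather covariates, unbalanced data return (every simulated
trial reports complete data), genotype-specific check interactions, or
realistic pedigree string notation.  Passing tests demonstrate that the
estimation machinery recovers the parameters of this generative model
at these sizes; they do not certify behavior under field
irregularities the generator omits.

The pedigree generator assigns founders evenly to ancestor groups and
mates each new line within its group with probability 0.95 per parent,
parents always strictly earlier — acyclic by construction.

## Pipeline

Stage order: single-trial fits → repeatability filter → pooled k-means
classification (drop HYE) → per-series FA-MET fits (LYE, MYE, Across) →
GYC → HYL selection → gain regression per class → COP/PCA grouping of
the pooled HYLs.  One seed drives everything through named
`SeedSequence` substreams per stage, so no stage's draw count can
perturb another; identical config + seed reproduces the report
bit-identically (the output directory is not part of the config hash).
Every stage writes its table to the output directory; the report
serializes to JSON losslessly.  In simulate mode the pipeline generates
a pedigree whose non-founder lines are exactly the simulated entries.

Problem sizes used by the shipped checks: the end-to-end trend
ensembles run the default 12-series configuration above;
oracle-equivalence checks use 2–4 sites × 6–12 genotypes; the
zero-trend calibration ensemble uses 8-series runs with 10 sites per
analysis class, 3 checks and 20 entries — the sites-per-class and
check count drive the CI calibration (they set the shared check-mean
error within a series), while series and entry counts only trim
runtime.

## Known limitations

* The FA surface has a weakly identified direction (`sigma2_g` vs. a
  common loading component); likelihoods and predictions are stable but
  the individual components `sigma2_g`, `Lambda`, `D` should not be
  over-interpreted at small site counts.
* The repeatability filter's null discard rate is bounded near 55–60%
  (see above); treat it as a screen, not a test.
* Entry-mean repeatability has a small negative finite-sample bias
  (~0.02 at 20 entries with equal variance components).
* The dense REML path scales cubically in plots and is intended for
  small or unbalanced units only.
* `validate_inputs` checks schema and referential integrity, not
  statistical plausibility.
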