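# Methods

## The question

A p-curve is the distribution of statistically significant p-values
(p < 0.05) across a collection of estimates. Right-skew — mass piling
up near zero — is widely read as evidence that the underlying studies
measure true effects, while a peak just below 0.05 is read as evidence
of p-hacking. Both readings presume that a null effect can only produce
a uniform p-value distribution. In observational regression that
premise fails: omitting a confounder biases the coefficient of interest
*systematically*, so its p-value marches to zero as the sample grows
exactly as it would under a true effect. This package implements the
two demonstrations of that failure — a calibrated Monte Carlo
simulator, and a cross-country growth specification search with an
exactly-null constructed outcome — plus the p-curve toolkit used to
summarize both.

## Simulation arm

### Data-generating process

Each iteration draws `(x, z, ε)` from a multivariate standard normal
with `Cov(x, z) = c` (default 0.2), `ε` independent of both, and sets

    y = β* x + γ z + ε,      β* = 0 by default.

The analyst's regression omits `z`, regressing `y` on `x` (with an
intercept). The omitted-variable bias of the short-regression slope is

    E[bias] = γ · Cov(x, z) / Var(x) = c γ    (unit variances).

`γ` is redrawn each iteration from Uniform[0, γ_max], and the sample
size from a discrete uniform on [n_min, n_max] (n_min = 50). All
variables are resampled every iteration — a conservative design: no
dataset is reused while searching over biases.

### Calibrating γ_max from a target correlation

Bias strength is parameterized by the maximum expected Pearson
correlation between `y` and `x` under the null. With β* = 0 and unit
variances, `Var(y) = γ² + 1` and `Cov(y, x) = cγ`, so

    ρ_yx(γ) = c γ / sqrt(γ² + 1),

which is increasing in γ and bounded by |c|. Inverting at the target
ρ_max gives the closed form

    γ_max = ρ_max / sqrt(c² − ρ_max²),

e.g. γ_max = 1/√3 ≈ 0.577 for ρ_max = 0.1 at c = 0.2, and ≈ 0.0501 for
ρ_max = 0.01. The test suite cross-checks this closed form against a
numerical root (scipy `brentq`) and against the realized correlation of
a 10⁶-point simulated sample. Targets at or beyond |c| are rejected as
unsolvable.

### Inference and numerical choices

* The short regression includes an intercept (all variables are
  mean-zero, so this is asymptotically immaterial; it matches standard
  finite-sample practice). A flag drops it.
* Two-sided p-values use the Student t distribution with the residual
  degrees of freedom (`scipy.special.stdtr`), which matters at n near
  50; significance is strict (`p < α`), two-sided, sign-unrestricted in
  this arm.
* Randomness: one `SeedSequence` child per iteration, so iteration i's
  draws are a pure function of (seed, i). Within an iteration the
  sample size and γ come from uniform deviates drawn *before* the
  normal block; grid cells run with the same seed therefore share
  their underlying randomness (common random numbers), which makes
  between-cell comparisons — e.g. monotonicity of the significant
  share in ρ_max and n_max — far less noisy than independent cells
  would be.
* Default problem size is 20,000 iterations per condition (the
  package's desk scale; `--full` in the analysis driver runs 500,000).

### What the simulation shows — and the resolution limit

Under the exact null (γ_max = 0) the p-value distribution is uniform
and ~5% of iterations are significant; this calibration is tested with
a KS test and a 3-binomial-SE band. With γ_max > 0 the significant
share grows in both bias strength and sample size, and the p-curve
becomes right-skewed — strongly so at ρ_max = 0.1, n_max = 10⁴, where
the (0, 0.01] bin holds dozens of times the (0.04, 0.05] mass. One
caveat is inherent: in near-null cells (ρ_max = 0.01 with small n_max)
the *true* first-versus-last bin tilt is of order 0.1 percentage
points, far below the per-bin sampling noise of a 20,000-iteration run
(~1.3 pp with ≈1,000 significant draws). Fine-grained bin-shape
statements about those cells are noise-dominated at desk scale — and
only marginally resolvable even at 500,000 iterations. The module's
property tests therefore assert bin-shape claims only on cells where
the bias signal is resolvable.

## p-curve toolkit

Bins are left-open, right-closed intervals partitioning (0, α] — five
bins of width 0.01 by default. p ≥ α is excluded from the bins but
counted in the total (so the significant share is still reported);
p = α exactly is not significant. The skew summary is descriptive:
direction compares first and last bin shares (margin configurable,
default 0 — qualitative, since "right-skewed" has no canonical
numerical definition), and a monotone-decreasing flag checks
non-increasing shares left to right. No inferential skew test is
provided. Conservation, permutation invariance and bin-refinement
consistency (a 10-bin curve merged pairwise equals the 5-bin curve) are
property-tested.

## Growth specification-search arm

The table layout is one outcome (`GR6096`, annualized real GDP
per-capita growth), one variable of interest (`MALARIA`, prevalence in
1966) and 15 named adjusters, for 99 complete-case countries. The
reader applies complete-case filtering and matches headers
case-insensitively with `.`/`_` equivalence.

1. **Null outcome.** Fit the full model (interest + all 15 adjusters +
   intercept); set `y_new = y − β̂* · interest`. This equals rebuilding
   `y` from the fitted intercept, adjuster terms and residuals with the
   interest term dropped: refitting on `y_new` returns an interest
   coefficient of zero to rounding, identical adjuster estimates and
   identical residuals, and the operation is idempotent. Rank-deficient
   designs are rejected with the offending columns named (QR with
   column pivoting).
2. **Model space.** All C(15, 6) = 5,005 six-adjuster subsets (six
   matches the typical model size of the growth-regression literature),
   enumerated in lexicographic index order; the random browse permutes
   this canonical list.
3. **Vibration analysis.** For each of 100 country samples (drawn
   without replacement, size ~ discrete Uniform[50, 99]) fit all 5,005
   models and classify each interest estimate by sign × significance.
   p-values are displayed as −log10(p) with the significance line at
   −log10(α), and 1/50/99% quantiles of both axes are reported.
4. **p-hacking search.** Per country sample, browse models in a fresh
   uniformly random order and keep the *first* negative, significant
   estimate; samples with no hit contribute nothing; repeat until the
   target number of hits (default desk scale 10,000; the full-scale
   target is 100,000). A `full_sample` variant always uses all 99 rows,
   so only model order varies. A `max_attempts` bound (default
   100 × n_hacked) guards against degenerate inputs, raising an error
   that carries the partial harvest.

Collinearity on a subsample is skipped-and-counted in the vibration
analysis and treated as a non-hit in the search. All fits go through
the normal equations on a per-sample Gram matrix of the full design;
per-model submatrices are solved in one stacked LAPACK call (with a
per-model fallback if any submatrix is exactly singular). This is
algebraically identical to refitting from raw columns — the test suite
checks equality with `statsmodels` OLS at 1e−10 — and is what makes
500,500-fit analyses run in seconds.

## Synthetic growth table

The generator emulates the *statistical structure* the pipeline needs,
not any real country data: 99 rows; 16 regressors from a multivariate
normal with exchangeable correlations (0.2 between adjusters, 0.3
between the interest variable and each adjuster); outcome = 1.8 +
0·interest + Σ δ_j·adjuster_j + N(0, 1) noise. The interest variable's
true coefficient is exactly zero; the full correlation matrix can be
overridden from config.

The δ calibration is frozen: the first 8 adjusters carry negative
coefficients decaying geometrically from 1.25 by factor 0.75.
Rationale: omitting positively-correlated adjusters with negative
effects biases the interest estimate downward (the multiple-regression
analogue of the bias formula above), mimicking a disease-prevalence
variable entangled with growth-depressing conditions; and the *size*
matters — at 50–99 rows the bias must dominate the coefficient's
standard error, otherwise significant estimates cluster just under
0.05 and the harvested p-curve comes out left-skewed rather than
right-skewed. At the frozen values, ≈56% of (sample, model) fits are
negative-significant (inside the generator's intended 5–60% band) and
the harvested p-curve is monotone decreasing. A mirror-image
`no-negative-hit` flavor (all δ positive) makes negative-significant
hits vanishingly rare and serves as the guaranteed-failure fixture.

What the generator does **not** emulate: real marginal distributions
(colonial-indicator variables are generated continuous), units, country
identities, or the real data's covariance matrix. Passing tests on
synthetic tables therefore validate the *pipeline* — exact null
construction, enumeration, selection logic, bookkeeping — and the
qualitative selection-distortion phenomenon, not any numerical claim
about the actual malaria–growth literature; with a real table in the
expected layout, the same commands reproduce the empirical analysis
as-is.

## Known limitations

* Omitted-variable bias is the only bias source modelled; simultaneity,
  measurement error and functional-form misspecification are out of
  scope, as are experimental p-hacking mechanisms (optional stopping,
  outcome switching).
* The skew summary is descriptive; no mixture-model or FDR estimation
  is provided.
* Near-null bin-shape statements are noise-limited at desk scale (see
  above).
* Seeded runs are reproducible on a fixed BLAS/LAPACK stack; bitwise
  reproducibility across different linear-algebra backends is not
  guaranteed.
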