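# Methods

## Model and metric

All computations assume Samejima's graded response model for ordered
categories 1..K.  The boundary probability of responding above category k is
logistic in a(θ − b_k) with scaling constant **D = 1** — the pure logistic
metric, not the normal-ogive-approximating 1.7 scaling.  The packaged bank's
published information table identifies this convention: an isolated logistic
boundary peaks at a²/4, and the strongest item's printed maximum (7.49)
matches 5.47²/4 = 7.48 only under D = 1.  The bank file carries an explicit
`"metric": "logistic, D=1"` tag so recalibrated banks remain self-describing.

The latent trait is identified by fixing the calibration prior at N(0, 1);
no post-hoc rescaling is applied.  Responses live on the instrument scale
(codes 1..K); missing entries are NaN and are handled by likelihood omission,
never imputation.

## Calibration (MML-EM)

`GradedResponseModel.fit` maximizes the marginal likelihood over a
rectangular quadrature grid: **61 equally spaced nodes on [−6, 6]** with
renormalized N(0,1) masses.  A dense rectangular grid is robust to the very
narrow posteriors this bank produces (posterior SD ≈ 0.13 at the center) and
the same grid is reused for EAP scoring and residual diagnostics.  Each EM
cycle computes per-person posterior node weights (E-step) and then maximizes
each item's expected complete-data log-likelihood in slope/intercept form
(a·θ + d_k, d_k = −a·b_k) by Newton ascent with a finite-difference Hessian
of the analytic gradient and step-halving, at most 25 inner iterations
(M-step).  Line searches are capped at 0.9 of the largest step that keeps
a > 0 and the intercepts strictly ordered, so iterates never cross the
boundary of the parameter cone.

Numerical note: category probabilities are **never** formed by naive
subtraction of boundary probabilities inside likelihood code.  In float64,
expit saturates to 1.0 once a(θ − b) exceeds ≈ 37 and the difference cancels
to exactly zero, which silently freezes estimation for highly discriminating
items.  All likelihood internals use the exact identity
σ(x) − σ(y) = σ(x)·σ(−y)·(1 − e^{y−x}) in log space, keeping every log
probability finite for strictly ordered thresholds.

Defaults: stop when the largest absolute parameter change in a cycle falls
below **1e−4**, cap at **500 cycles** (non-convergence returns a result with
`converged = False` plus a warning, never an exception).  Starting values:
a = 1 and d_k from the inverse logistic of the marginal cumulative category
proportions, which are ordered by construction.  Categories a sample never
uses are collapsed into their neighbor toward the scale middle before
fitting, with the remap recorded in the result (thresholds of empty
categories are unidentified).  Discriminations diverging past 50 are capped
and flagged.  Calibration refuses samples under 100 persons by default.
Optional standard errors come from the empirical cross-product of per-person
score vectors (scores by central differences of the per-person marginal
log-likelihood).

EM guarantees a non-decreasing marginal log-likelihood trace; the suite
asserts this on every fitted model.

## Information functions

Item information is I(θ) = Σ_k (P′_k)²/P_k with P′_k differenced from the
boundary derivatives a·P*(1−P*).  `max_information` evaluates the curve on a
**0.1-step grid over [−4, 4]** — matching the one-decimal reporting
convention — rather than by gradient search, because high-discrimination
graded items have one local information peak near each threshold and the
curves are genuinely multimodal.  Exact grid ties break toward the smaller θ
(a `tie_tol` parameter widens the tie window if desired; default 0).  For
items whose per-threshold peaks are nearly equal the *location* of the
argmax can flip under two-decimal rounding of the stored parameters even
though the peak *value* is stable to < 0.02; one bank item (EDANX53) sits in
this regime, with peaks 6.6458 at θ = −1.1 and 6.635 at θ = −2.3.

Test information is the plain sum of item informations with **no prior
term**: the packaged bank's per-item column then sums to 63.48 at θ = 0,
matching the published curve maximum of 63.427 to parameter-rounding
accuracy, which is what identifies the prior-free convention.  The "highly
informative range" reported by the pipeline is the θ interval where
T(θ) ≥ 10 (conditional SE ≤ 0.316) — an explicit numeric stand-in for what
is usually judged visually from the curve.

EAP scores are posterior means over the quadrature grid; persons with no
answered items get NaN.  For persons near the bank's center the posterior SD
agrees with 1/√T(θ̂) to ~15% (asserted in the suite).

## Classical statistics

Cronbach's α uses the raw covariance form with listwise deletion and n−1
variance denominators throughout (α is invariant to the denominator choice
if applied consistently — consistency is the contract).  "Item-scale
correlation" is implemented as the **corrected item-rest correlation**
(item vs total-minus-item): the uncorrected item-total variant is inflated
by the item's self-correlation and is available behind a flag for
comparison.  Dropped-row counts are always reported.

## Assumption checks

* **Unidimensionality** — PCA on the Pearson correlation matrix of the raw
  ordinal codes (the arithmetic general-purpose statistics packages
  perform), not polychoric PCA; verdict: first/second eigenvalue ratio > 3.
  KMO and Bartlett's sphericity are computed from their textbook
  definitions (anti-image partial correlations from the inverse correlation
  matrix; χ² = −(n−1−(2J+5)/6)·ln|R| with J(J−1)/2 df) since no installed
  package exposes them.
* **Local independence** — Yen's Q3: correlations of per-person residuals
  (observed minus model-expected score at the person's EAP θ); verdict:
  max |Q3| < 0.70, applied to absolute values.  Q3 carries a small negative
  bias (≈ −1/(J−1)) under local independence, visible in the suite.
* **Monotonicity** — mean item score by quantile-binned rest score (bins
  merged below 30 persons); an item is flagged when adjacent bin means drop
  by more than **0.05** score units, a tolerance sized to absorb binomial
  noise at the minimum bin size where a visual criterion is the tradition.

## Model fit (M2)

Limited-information fit compares observed and model-implied univariate and
bivariate category margins (categories 2..K per item).  The statistic is the
standard quadratic form with the model-implied covariance of the sample
margins and the margin/parameter Jacobian; the covariance is assembled from
the local-independence factorization over the quadrature grid with exact
delta-rule corrections for moment pairs sharing an item (the construction is
verified against a brute-force empirical covariance in development).  RMSEA
= √(max(M2 − df, 0)/(df(n−1))); CFI and TLI are computed against an
independence baseline holding the observed univariate margins (TLI may
exceed 1 and is reported unclipped with a note).  For the 23-item bank this
is a 4140-moment problem (~10 s); tests exercise 5-item sub-banks.

## DIF analysis

For each item three proportional-odds models of the response are fitted —
matching only; + group; + group × matching — by Newton ascent with
step-halving (convergence: log-likelihood change < 1e−8), a fitter validated
against statsmodels' `OrderedModel` to 1e−4 in maximized log-likelihood and
fast enough for replicate simulations.  Uniform and non-uniform DIF are the
df = 1 likelihood-ratio tests between adjacent models (flag at p < 0.05, no
multiplicity correction), and practical salience is the change in McFadden's
pseudo-R² with gate **0.02** — the two-tier logic that lets a bank show
statistically detectable but practically negligible DIF.  The default
matching variable is the **standardized rest score**, which avoids
circularity from the studied item and needs no calibration; EAP matching is
a flag.  Purification of the matching variable is off by default (single
pass) — the simplest auditable choice.  Under null simulations at n = 1000
the empirical ΔR² stays two orders of magnitude below the 0.02 gate and LR
p-values are uniform (both asserted at 200 replicates).

## Synthetic data

`simulate_study(seed)` emulates the calibration study's shape: n = 1075
respondents, the packaged 23-item bank, θ ~ N(0,1), and covariate splits
matching the study population (age 64.5/35.5, gender 38.0/62.0, education
47.0/53.0).  Covariates are independent of θ by default ("no impact"); a
group-mean θ shift is a separate knob so DIF studies can distinguish impact
from DIF, and `inject_dif` builds focal-group banks (uniform: all thresholds
shifted by the magnitude; non-uniform: discrimination scaled by 1 +
magnitude).  One seed drives one named generator; true θ values are returned
through a separate channel and never written into response files.

What the generator deliberately does **not** emulate: missing-data
mechanisms, response styles (e.g. extreme responding), minor secondary
dimensions, or item-level misfit.  Passing tests on this data therefore
demonstrate that the *procedures* behave correctly under their own
assumptions — not that real questionnaire data will be as clean.  Two
visible consequences: simulated eigenvalue ratios run ~2–3× higher than
real-data values (exact unidimensionality), and fit indices are near their
ideals.

## Problem sizes used by the test suite

Chosen as the package's own balance of statistical resolution and suite
turnaround: one full study-scale calibration (n = 1075, 23 items) shared
across tests; consistency checks on 5-item sub-banks at n = 800 and 8000;
DIF operating characteristics at 200 null replicates (n = 1000) and 50 power
replicates (n = 1000 per group, 0.75 θ-unit shift); Monte-Carlo/quadrature
agreement at n = 100 000 for three items.

## Known limitations

Unidimensional GRM only (no generalized partial credit, nominal, or
multidimensional models); no Bayesian estimation; no linking/equating to the
US T-score metric; no CAT item-selection engine; no iterative DIF
purification by default; plotting is left to the exported curve tables.
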