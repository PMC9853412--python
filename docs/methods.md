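# Methods

## Model

The survival function of a period life table, s(x) = lx/l0, is modelled as a
modified stretched exponential (extended Weibull) law

    s(x) = exp[ −(x/α)^β(x) ],

with two structural ingredients:

- **Characteristic age α** — the unique age with s(α) = e⁻¹ ≈ 0.368. It is a
  pure scale parameter: (α/α)^β = 1 for any exponent, so s(α) = e⁻¹ holds
  *identically*, which the test suite uses as an analytic anchor.
- **Age-dependent exponent β(x)** — β = 1 gives the simple exponential
  (constant hazard 1/α), a constant β ≠ 1 the classical Weibull; letting β
  grow with age captures the rectangularization of modern human survival.
  At extreme ages (here: 100–109) β(x) is taken quadratic,
  β(x) = b0 + b1·x + b2·x².

Mortality connects through μ(x) = −d ln s/dx; for the fitted law
μ(x) = (x/α)^β(x)·[β′(x)·ln(x/α) + β(x)/x] (exact), and on a grid curve the
forward difference −Δln s is used.

**The limit ω.** Since −ln s(x) = β(x)·ln(x/α), monotonic decrease of s is
equivalent to β(x) > γ(x) with γ(x) = −x·ln(x/α)·β′(x). The smallest root of
β(x) = γ(x) above α is the maximum mathematical lifespan ω: past it the
fitted curve would increase, which a survival function cannot. ω is a
*model-consistency* bound, not a prediction of any individual's death age.

## Estimation procedure and numerical choices

1. **α** — linear interpolation of s against age between the first grid pair
   bracketing e⁻¹. (Interpolating in log s instead moves α by < 0.01 y on
   realistically shaped curves.) First crossing wins; non-monotone curves
   are rejected upstream at tolerance 1e−12.
2. **β extraction** — pointwise inversion β = ln(−ln s)/ln(x/α), masked
   (never NaN) where it is undefined or ill-conditioned: s ≤ 1e−12,
   s ≥ 1 − 1e−6, or |ln(x/α)| ≤ 1e−6. The asymmetric clip is deliberate:
   near s = 1 the float64 rounding of s destroys −ln s below ~1e−7, so such
   ages carry no recoverable exponent information, while small s is
   well-conditioned for the logarithm.
3. **Quadratic fit** — unweighted ordinary least squares on the valid ages
   in the half-open window [100, 110): "extreme ages" excluding the 110+
   open-interval row, whose exposure convention differs. Inverse-variance
   weighting by death counts is available (`weights=`) but off by default.
   The three coefficients are strongly collinear over a 10-year window far
   from the origin; individual coefficients are reported but ω is the
   stable functional of the fit.
4. **ω solve** — h(x) = β(x) − γ(x) is scanned on a 0.1-y grid from α to the
   search bound (default 200 y); the first sign change is refined by Brent
   bisection to 1e−6 y. The smallest root is the physically meaningful one
   (monotonicity is violated from the first crossing onward). No sign change
   up to the bound is an explicit "no finite ω" outcome, not an error —
   constant-exponent laws (γ ≡ 0) and Gompertz-shaped tables typically land
   there.
5. **Gompertz baseline** — diagnostic only. On a grid with spacing dx the
   forward difference estimates the *integrated* hazard
   H(x) = (a/b)·e^{bx}(e^{b·dx} − 1), whose log is exactly linear in x; OLS
   gives b as the slope and a is recovered from the intercept through the
   (e^{b·dx} − 1)/b factor. This discretization correction is what makes
   parameter recovery on exact Gompertz data accurate to machine precision;
   without it, a carries a ~b/2 relative bias.
6. **Aggregation** — mean ± SD of the finite per-year ω. The SD divisor
   convention is configurable (population/n by default; sample/n−1 also
   always reported — with ~11 years the two differ by ~5%). Years without a
   finite ω are excluded and counted, never imputed at the search bound,
   which would bias the mean toward an arbitrary parameter.

A rectangularity heuristic β(x) ≈ 7/ln(x) is exposed as a labelled
diagnostic (`rectangular_beta_approx`) but never used in fitting: with x in
plain years it yields β ≈ 1.5 near age 90, far below empirical extreme-age
exponents, so its normalization is evidently tied to a convention not
adopted here.

## Synthetic data: what it emulates, and what it does not

`GeneratorSpec` states a complete world: a law (stretched exponential with
quadratic exponent, or Gompertz(–Makeham)), a radix (default 100 000, the
life-table convention), a noise model, a seed, and year labels. Tables are
emitted in the HMD period-1x1 text dialect, including the 110+ closing row
(qx = 1) and "." for columns not generated, so they exercise the real
reader.

- **Presets.** "sweden-like" (α = 88) and "japan-like" (α = 91) use
  quadratic exponents anchored at β(0) = 3 and β(100) = 8.5 / 8.8, with the
  remaining freedom used to place the law's own limit at ω = 123.8 / 125.4 y
  — characteristic ages and limits in the empirically reported range for
  recent Swedish/Japanese female tables. β(0) = 3 (rather than 2) keeps the
  survival strictly decreasing over the whole 0–110 grid; a single quadratic
  over all ages is otherwise prone to a non-monotone artifact near childhood
  ages. The quadratic-over-all-ages shape is a modelling convenience: real
  β(x) profiles are only quadratic at extreme ages, which is also the only
  region the pipeline uses.
- **Noise.** Deaths are a binomial chain, l(x+1) | l(x) ~
  Binomial(l(x), s(x+1)/s(x)), keeping lx integer, monotone and
  radix-conserving; one root seed per table (spec seed × year) makes every
  table independently reproducible. An extinct cohort carries lx = 0,
  qx = 1 to age 110.
- **Oracle.** `generator_omega` evaluates the *law's* limit by dense-grid
  (0.001 y) argmin of the exact survival — independent of the whole fitting
  path — and is what recovery tests compare against.

What a green synthetic test does **not** establish: real HMD tables are not
binomial draws from a quadratic-exponent law — they carry smoothing from
the HMD estimation protocol, cohort-size-driven heteroscedasticity,
age-heaping corrections, and a β(x) whose extreme-age shape is only
approximately quadratic. Synthetic recovery validates the estimator
machinery, not the model's adequacy for any real population; the optional
real-data acceptance check (HMD files under `data/hmd/`) is the only test
of the latter.

## Sampling behaviour and known limitations

- **Variance of ω.** The quadratic is fitted on ages 100–109 and evaluated
  near 124: an extrapolation of ~1.5 window-widths that amplifies noise in
  the smallest survivor counts by roughly an order of magnitude. At radix
  10⁶ under binomial noise the ω estimator's sampling SD is ≈ 1.9 y
  (measured over 300 replicates; bias ≈ +0.15 y); at the conventional radix
  10⁵ the SD is ≈ 6 y. Across-year SDs on real tables are smaller than the
  radix-10⁵ binomial figure because national female populations contribute
  far more exposure than one radix cohort.
- **ω is window-sensitive.** Moving the fit window or weighting the fit
  shifts ω by O(1 y); the defaults are fixed (100–110, unweighted) and the
  CLI exposes both knobs for sensitivity reporting.
- **No confidence interval on a single year's ω** is attempted; the only
  spread reported is the across-year SD, matching how multi-year limits are
  usually quoted.
- **Period, 1-year tables only.** Cohort tables, abridged (5-year) tables
  and HMD authentication are out of scope; the reader accepts the period
  1x1 text dialect and a CSV mirror.
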