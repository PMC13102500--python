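# Methods

## The problem

Wildlife managers controlling invasive birds (the motivating system is the
monk parakeet) need to compare the physiological strain imposed by
different control methods. The standard acute-stress readout is plasma
corticosterone (CORT, ng/ml), the primary avian glucocorticoid: it rises
within minutes of a stressor's onset via the HPA axis and stays elevated
while the stressor persists. The study design behind this package samples
each bird exactly once, in one of three groups: *shot* (blood taken at the
instant of death; the HPA axis has had no time to respond), *baseline*
(live-trapped, bled within 3 minutes of net activation, before the
handling-induced rise), and *trapped–confined* (live-trapped, held in a
bag, bled between 10 and 210 minutes after capture).

## Models

**Treatment comparison.** CORT for bird *i* is gamma with mean μ_i and
shape k (Var = μ²/k), with g(μ_i) = Xβ and treatment as the sole
categorical predictor. The default link g is the log: concentrations are
positive and treatment effects are naturally multiplicative; inverse and
identity links are available and recorded in the fit. The overall effect
is a likelihood ratio test of the three-group model against the
intercept-only model on 2 df; the three pairwise contrasts are Wald z
tests on the link scale with Bonferroni adjustment (multiplier = 3 pairs,
capped at 1).

**Time course.** With all 63 birds pooled and time since capture t the
sole predictor, three gamma mean models are compared:

* null: μ(t) = μ
* logistic: μ(t) = a / (1 + exp(−b (t − x₀)))
* quadratic: μ(t) = a + b t + c t²

Fits are joint maximum likelihood over mean parameters and shape. Models
are ranked by AICc = −2 logL + 2k + 2k(k+1)/(n−k−1) with k counting the
shape once; Akaike weights use unrounded AICc. Selection is parsimonious:
within ΔAICc < 2 of the best, the fewest-parameter model wins (ties by
name). Explanatory power is a deviance-based pseudo-R²,
1 − D_model/D_null with D = 2 Σ[−log(y/μ) + (y−μ)/μ]; a likelihood-ratio
variant 1 − exp((2/n)(logL_null − logL_model)) is reported alongside
because the literature does not standardize on one formula.

**Sex differences.** The sex family holds the logistic form and lets
subsets of {a, b, x₀} take separate female/male values: the shared-curve
null plus all 7 non-empty subsets, k ∈ {4, 5, 5, 5, 6, 6, 6, 7}. The
gamma shape is always shared across sexes — per-sex shapes would change
the parameter bookkeeping that the comparison tables rely on.

## Numerical choices

* **Profile-shape trick.** The gamma score for the mean parameters factors
  through the shape, so the mean MLE minimizes the shape-free kernel
  Σ(log μ_i + y_i/μ_i); the shape MLE then solves
  log k − ψ(k) = D/(2n) (unique root; solved by Brent to 1e-13). This is
  exactly the joint MLE but reduces the logistic fit from a 4-parameter to
  a 3-parameter search. A numerically exact fit (D = 0) maps to a capped
  shape of 1e12, with the covariance marked unavailable.
* **Optimization.** Logistic fits run Nelder–Mead from a scale-free grid of
  8 starts (a₀ ∈ {max y, 1.5 max y}; x₀ ∈ {median t, mean t};
  b₀ ∈ {4/range(t), 0.1}) on (log a, b, x₀), then re-polish the best start
  at tighter tolerance. Quadratic fits start from the least-squares
  parabola and the flat-mean point, on the natural (a, b, c) scale with an
  infinite objective wherever any fitted mean is non-positive (the
  quadratic form itself stays unconstrained). The null mean is closed-form
  (the sample mean). Ties between equal-objective starts go to the earlier
  start. Sex-family fits start from the pooled fit (duplicated where
  varying) plus one perturbed start, which also guarantees the fitted
  family log-likelihood never falls below the shared-curve member's.
* **Covariance and bands.** Parameter covariance is the inverse of a
  central-difference observed-information matrix at the optimum, on the
  natural scale (mean parameters, then shape). 95% prediction bands use
  the delta method on the mean-parameter block with normal quantiles,
  floored at 0; a parametric bootstrap band (resimulate at the fitted
  model, refit warm-started, pointwise percentiles) is available as a
  cross-check — the two agree to well within 25% at interior times in the
  test suite.
* **LRT.** Both models carry their own profiled shape, so the statistic
  2(logL_full − logL_null) compares genuine maxima; the χ²₂ reference is
  asymptotic. At n = 63 with gamma dispersion the simulated type-I rate at
  α = 0.05 is ≈ 0.05–0.06 (the acceptance suite bounds it in [0.03, 0.08]).

## The synthetic-data generator

The generator is the analysis model run forwards, reproducing the study's
sampling design by default: 63 birds split 7 shot / 6 baseline /
50 trapped–confined; baseline times uniform on (1, 3) minutes; confinement
times uniform on (10, 210) minutes; shot birds at t = 0 by convention.
CORT is gamma with mean from the logistic curve at the bird's sampling
time (trapped and, by default, baseline birds) or a fixed shot mean.

Default parameter values are calibrated to the study's reported summaries
rather than to fitted coefficients (which were not deposited):
(a, b, x₀) = (45 ng/ml, 0.12 /min, 25 min) puts the half-maximum
(~20 ng/ml) at 25 minutes and ~45 ng/ml by 50 minutes; reading the
trapped group's 41.00 ± 17.20 ng/ml as mean ± SD gives CV ≈ 0.42, i.e.
shape ≈ 5.68, and the shot group's 2.38 ± 0.58 gives shot mean
2.38 ng/ml with shape ≈ 16.8. Two consequences of these choices are worth
stating plainly. First, the baseline-from-curve mean at 1–3 minutes is
≈ 2.4–2.8 ng/ml — slightly below the reported baseline mean of
3.99 ng/ml but consistent with the qualitative finding that baseline and
shot birds are statistically indistinguishable; a fixed-mean baseline
mode is available instead. Second, the reported sex counts (30 females,
34 males) sum to 64 against 63 birds overall — an inconsistency in the
source summaries — so the generator keeps 30 females and assigns the
remaining 33 birds as males.

Sexes are assigned by a seeded permutation, independent of treatment and
CORT (no sex effect by default); an optional sex-effect mode scales the
male asymptote and/or shifts the male inflection for power studies.
Randomness is a single master seed driving a `SeedSequence`; replicate r
of a Monte-Carlo run uses the master seed itself for r = 0 (so one
replicate reproduces a single draw exactly) and a seed hashed from
(seed, r) otherwise.

What the generator does **not** emulate: assay measurement error beyond
the gamma dispersion (the EIA's intra-/inter-assay CVs are folded into
the shape, not modelled separately), any decline of CORT after the
stressor ends, non-uniform sampling-time distributions, repeated measures,
or social/seasonal structure. Passing tests therefore demonstrate that
the estimators recover the generative model and that the bookkeeping
matches the study design — not that the defaults are the true parameters
of any wild population.

## Problem sizes in the validation suites

The test and acceptance suites use: 200 replicates at n = 200 for
parameter recovery and selection consistency (median relative bias of a,
b, x₀ within ±10%; logistic ranked first in ≥ 90%); 500 replicates at
n = 63 for the LRT type-I rate; 100 replicates for sex-family null
retention (≥ 80% within ΔAICc < 2). `scripts/acceptance.py` reruns the
same studies at 100 / 300 / 60 replicates, which it records in each
quantity's `n` field.

## Known limitations

* Wald (normal) contrasts are used rather than t-type contrasts with
  estimated denominator df; at n = 7/6 per small group the adjusted
  p-values for small-group contrasts are mildly liberal.
* The quadratic model's positivity is checked on the observed time range
  only; extrapolated predictions can go negative (bands are floored at 0,
  the mean is not).
* The delta-method band is first-order; near the boundary of the observed
  time range or at small n the bootstrap band is the better reference.
* AICc's k counts the shared shape once by design; comparisons against
  software that drops the shape from k (or uses quasi-likelihood) will
  differ by a constant in k.
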