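"""Gamma-likelihood nonlinear models of CORT versus time since capture.

Three mean functions are entertained for the time course of plasma
corticosterone after an acute capture stressor:

* ``null`` — a constant mean (no time effect);
* ``logistic`` — a sigmoidal surge ``a / (1 + exp(-b (t - x0)))`` with
  asymptote ``a`` (ng/ml), rate ``b`` (per minute) and inflection time
  ``x0`` (minutes), reflecting a hormonal rise that stabilizes while the
  stressor persists;
* ``quadratic`` — ``a + b t + c t^2``, whose negative curvature can encode
  a transient peak-and-decline response.

All models assume gamma-distributed observations with the modelled mean
and a common shape ``k`` (coefficient of variation ``1/sqrt(k)``).  Fits
are full maximum likelihood: the mean parameters minimize the shape-free
gamma kernel (the gamma mean score does not involve the shape), and the
shape is then profiled from the deviance, which together give the joint
MLE.  A family of logistic fits with sex-specific parameters is provided
for testing whether females and males differ in their response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from . import _gamma
from .core_io import Dataset, DataValidationError, Sex

ModelName = Literal["null", "logistic", "quadratic"]

_REL_TOL = 1e-9


class CurveFitError(RuntimeError):
    """Raised when no optimizer start converges; carries the best trace."""

    def __init__(self, message: str, traces=None):
        super().__init__(message)
        self.traces = traces or []


@dataclass(frozen=True)
class LogisticParams:
    """Logistic growth curve: asymptote ``a`` > 0, rate ``b``, inflection ``x0``.

    At ``t = x0`` the mean equals ``a/2`` and the rate of increase is
    greatest.
    """

    a: float
    b: float
    x0: float

    def __post_init__(self):
        if not np.isfinite(self.a) or self.a <= 0:
            raise ValueError(f"asymptote a must be positive, got {self.a!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.x0], dtype=float)


@dataclass(frozen=True)
class QuadraticParams:
    """Quadratic curve: intercept ``a`` (baseline CORT at time zero),
    linear term ``b``, curvature ``c`` (negative = peak then decline)."""

    a: float
    b: float
    c: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)


def logistic_mean(t, p: LogisticParams):
    """Logistic mean ``a / (1 + exp(-b (t - x0)))``; overflow-safe."""
    return p.a * expit(p.b * (np.asarray(t, dtype=float) - p.x0))


def quadratic_mean(t, p: QuadraticParams):
    """Quadratic mean ``a + b t + c t^2``; vertex at ``-b/(2c)`` for c != 0."""
    t = np.asarray(t, dtype=float)
    return p.a + p.b * t + p.c * t * t


def _mean_for(model: str, t: np.ndarray, mean_params) -> np.ndarray:
    if model == "null":
        mu = float(mean_params if np.isscalar(mean_params) else np.asarray(mean_params).item())
        return np.full(t.shape, mu)
    if model == "logistic":
        if not isinstance(mean_params, LogisticParams):
            mean_params = LogisticParams(*np.asarray(mean_params, dtype=float))
        return logistic_mean(t, mean_params)
    if model == "quadratic":
        if not isinstance(mean_params, QuadraticParams):
            mean_params = QuadraticParams(*np.asarray(mean_params, dtype=float))
        return quadratic_mean(t, mean_params)
    raise ValueError(f"unknown model {model!r}")


def gamma_negloglik(ds: Dataset, model: ModelName, mean_params, shape: float) -> float:
    """Negative gamma log-likelihood of ``ds`` under the given mean model.

    Mean configurations that put any predicted mean at or below zero are
    infeasible for a gamma model and return ``+inf``.
    """
    y = ds.cort_array()
    t = ds.time_array()
    mu = np.asarray(_mean_for(model, t, mean_params), dtype=float)
    if not np.all(np.isfinite(mu)) or np.any(mu <= 0.0):
        return np.inf
    return -_gamma.loglik(y, mu, shape)


@dataclass
class CurveFit:
    """A fitted gamma-likelihood curve.

    ``k`` counts every estimated parameter including the gamma shape;
    ``resid_df = n - (k - 1)`` counts only mean parameters against n,
    matching the residual-df bookkeeping of model-comparison tables.
    ``cov`` is the observed-information covariance of the natural-scale
    parameters, ordered as ``param_names`` (mean parameters then shape);
    None when the information matrix is singular.
    """

    model: str
    params: object
    shape: float
    log_lik: float
    deviance: float
    n: int
    k: int
    resid_df: int
    cov: np.ndarray | None
    converged: bool
    n_starts_used: int
    param_names: tuple[str, ...]
    data: Dataset = field(repr=False, compare=False, default=None)

    def mean_params_array(self) -> np.ndarray:
        if self.model == "null":
            return np.array([float(self.params)])
        if isinstance(self.params, dict):  # sex-family fit
            return np.concatenate([np.atleast_1d(v) for v in self.params.values()])
        return self.params.as_array()

    def mean_at(self, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        if isinstance(self.params, dict):
            raise ValueError(
                "sex-specific fits need a sex: use mean_at_sex(times, sex)"
            )
        return np.asarray(_mean_for(self.model, times, self.params), dtype=float)

    def mean_at_sex(self, times, sex: Sex) -> np.ndarray:
        p = _sex_params_for(self.params, sex)
        return logistic_mean(np.asarray(times, dtype=float), p)


def _polish(obj, x0, maxiter=2000):
    res = minimize(
        obj, x0, method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-10, "fatol": _REL_TOL},
    )
    return res


def _multistart(obj, starts, polish=True):
    """Run Nelder-Mead from every start; best objective wins, ties going to
    the earlier start.  Returns (best_result, n_starts, any_success)."""
    best = None
    traces = []
    for x0 in starts:
        res = minimize(
            obj, np.asarray(x0, dtype=float), method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-8},
        )
        traces.append(res)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 0.0):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise CurveFitError(
            "curve fit failed to converge from every start", traces=traces
        )
    if polish:
        polished = _polish(obj, best.x)
        if np.isfinite(polished.fun) and polished.fun <= best.fun:
            best = polished
    return best, len(traces), any(t.success for t in traces)


def _finalize_fit(model, ds, mean_params, param_names, natural, mean_fn,
                  converged, n_starts) -> CurveFit:
    """Profile the shape, assemble the likelihood, and invert the observed
    information at the optimum (natural parameter scale)."""
    y = ds.cort_array()
    t = ds.time_array()
    mu = mean_fn(t, natural[:-1] if natural is not None else None)
    shape = _gamma.profile_shape(y, mu)
    ll = _gamma.loglik(y, mu, shape)
    dev = _gamma.deviance(y, mu)
    n = y.size
    n_mean = len(param_names) - 1
    full = np.append(np.asarray(natural[:-1], dtype=float), shape)

    def nll_natural(x):
        mu_x = mean_fn(t, x[:-1])
        if not np.all(np.isfinite(mu_x)) or np.any(mu_x <= 0) or x[-1] <= 0:
            return np.inf
        return -_gamma.loglik(y, mu_x, x[-1])

    cov = None
    if shape < _gamma.MAX_SHAPE / 10:
        hess = _gamma.numeric_hessian(nll_natural, full)
        cov = _gamma.covariance_from_hessian(hess)
    return CurveFit(
        model=model,
        params=mean_params,
        shape=shape,
        log_lik=ll,
        deviance=dev,
        n=n,
        k=n_mean + 1,
        resid_df=n - n_mean,
        cov=cov,
        converged=converged,
        n_starts_used=n_starts,
        param_names=tuple(param_names),
        data=ds,
    )


def fit_curve(ds: Dataset, model: ModelName) -> CurveFit:
    """Joint-ML gamma fit of the requested time-course model.

    Logistic fits optimize over (log a, b, x0) from a grid of scale-free
    data-driven starts; quadratic fits optimize (a, b, c) unconstrained with
    an infinite objective wherever a predicted mean is non-positive; the
    null model has the closed-form mean MLE (the sample mean).  The gamma
    shape is profiled at the optimum in every case.
    """
    if len(ds) == 0:
        raise CurveFitError("cannot fit an empty dataset")
    y = ds.cort_array()
    t = ds.time_array()
    n = y.size

    if model == "null":
        if n < 3:
            raise CurveFitError("null model needs at least 3 observations")
        mu_hat = float(np.mean(y))

        def mean_fn(tt, x):
            return np.full(np.asarray(tt, dtype=float).shape, float(np.atleast_1d(x)[0]))

        return _finalize_fit(
            "null", ds, mu_hat, ("mu", "shape"), np.array([mu_hat, 1.0]),
            mean_fn, converged=True, n_starts=1,
        )

    if np.ptp(t) == 0.0:
        raise CurveFitError(f"{model} model needs variation in sampling times")
    if n < 5:
        raise CurveFitError(f"{model} model needs at least 5 observations")

    if model == "logistic":
        trange = np.ptp(t)

        def obj(theta):
            if abs(theta[0]) > 500.0:  # exp overflow guard
                return np.inf
            a = np.exp(theta[0])
            mu = a * expit(theta[1] * (t - theta[2]))
            if np.any(mu <= 0.0) or not np.all(np.isfinite(mu)):
                return np.inf
            return _gamma.kernel(y, mu)

        ymax = float(np.max(y))
        starts = [
            (np.log(a0), b0, x00)
            for a0 in (ymax, 1.5 * ymax)
            for x00 in (float(np.median(t)), float(np.mean(t)))
            for b0 in (4.0 / trange, 0.1)
        ]
        best, n_starts, ok = _multistart(obj, starts)
        a, b, x0 = float(np.exp(best.x[0])), float(best.x[1]), float(best.x[2])
        params = LogisticParams(a=a, b=b, x0=x0)

        def mean_fn(tt, x):
            return x[0] * expit(x[1] * (np.asarray(tt, dtype=float) - x[2]))

        return _finalize_fit(
            "logistic", ds, params, ("a", "b", "x0", "shape"),
            np.array([a, b, x0, 1.0]), mean_fn, converged=ok, n_starts=n_starts,
        )

    if model == "quadratic":

        def obj(theta):
            mu = theta[0] + theta[1] * t + theta[2] * t * t
            if np.any(mu <= 0.0) or not np.all(np.isfinite(mu)):
                return np.inf
            return _gamma.kernel(y, mu)

        ls = np.polyfit(t, y, 2)  # highest power first
        starts = [(float(np.mean(y)), 0.0, 0.0)]
        ls_start = (float(ls[2]), float(ls[1]), float(ls[0]))
        if np.isfinite(obj(np.array(ls_start))):
            starts.insert(0, ls_start)
        best, n_starts, ok = _multistart(obj, starts)
        params = QuadraticParams(*[float(v) for v in best.x])

        def mean_fn(tt, x):
            tt = np.asarray(tt, dtype=float)
            return x[0] + x[1] * tt + x[2] * tt * tt

        return _finalize_fit(
            "quadratic", ds, params, ("a", "b", "c", "shape"),
            np.append(best.x, 1.0), mean_fn, converged=ok, n_starts=n_starts,
        )

    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# sex-specific logistic fits
# ---------------------------------------------------------------------------

SEX_PARAMS = ("a", "b", "x0")


def _sex_params_for(params: dict, sex: Sex) -> LogisticParams:
    idx = 0 if Sex(sex) is Sex.FEMALE else 1
    vals = {}
    for name in SEX_PARAMS:
        v = params[name]
        vals[name] = float(v[idx]) if isinstance(v, tuple) else float(v)
    return LogisticParams(**vals)


def fit_sex_logistic(ds: Dataset, varying: frozenset | set,
                     pooled: CurveFit | None = None) -> CurveFit:
    """Logistic fit in which the parameters in ``varying`` (subset of
    {'a','b','x0'}) take separate female/male values; the gamma shape is
    shared.  Started from the pooled fit, so the fitted log-likelihood can
    never fall below the shared-parameters member of the family.
    """
    varying = frozenset(varying)
    if not varying <= set(SEX_PARAMS):
        raise ValueError(f"varying must be a subset of {SEX_PARAMS}, got {varying}")
    sexes = ds.sex_array()
    if np.any(sexes == Sex.UNKNOWN.value):
        raise DataValidationError(
            ["sex-specific models require every bird's sex to be known "
             "(female or male); found sex=unknown"]
        )
    male = sexes == Sex.MALE.value
    n_f, n_m = int(np.sum(~male)), int(np.sum(male))
    if min(n_f, n_m) < 4:
        raise CurveFitError(
            f"per-sex parameters are inestimable with {n_f} females / {n_m} males "
            "(need at least 4 of each)"
        )
    if pooled is None:
        pooled = fit_curve(ds, "logistic")
    if not varying:
        return pooled

    y = ds.cort_array()
    t = ds.time_array()

    # parameter vector layout on the optimizer scale: log(a) entries, then b,
    # then x0, each duplicated (female, male) when varying
    names: list[str] = []
    for p in SEX_PARAMS:
        if p in varying:
            names.extend([f"{p}_female", f"{p}_male"])
        else:
            names.append(p)

    def unpack(theta):
        vals = {}
        i = 0
        for p in SEX_PARAMS:
            width = 2 if p in varying else 1
            chunk = theta[i:i + width]
            if p == "a":
                chunk = np.exp(chunk)
            vals[p] = tuple(float(c) for c in chunk) if width == 2 else float(chunk[0])
            i += width
        return vals

    def mu_of(theta_natural_free, tt, male_mask):
        vals = theta_natural_free
        def pick(p, m):
            v = vals[p]
            return np.where(m, v[1], v[0]) if isinstance(v, tuple) else v
        a = pick("a", male_mask)
        b = pick("b", male_mask)
        x0 = pick("x0", male_mask)
        return a * expit(b * (np.asarray(tt, dtype=float) - x0))

    def obj(theta):
        if np.any(np.abs(theta) > 500.0):  # exp overflow guard
            return np.inf
        mu = mu_of(unpack(theta), t, male)
        if np.any(mu <= 0.0) or not np.all(np.isfinite(mu)):
            return np.inf
        return _gamma.kernel(y, mu)

    p0 = pooled.params
    base = {"a": np.log(p0.a), "b": p0.b, "x0": p0.x0}
    start0, start1 = [], []
    for p in SEX_PARAMS:
        if p in varying:
            start0.extend([base[p], base[p]])
            delta = 0.1 if p != "x0" else 5.0
            start1.extend([base[p] - delta, base[p] + delta])
        else:
            start0.append(base[p])
            start1.append(base[p])
    best, n_starts, ok = _multistart(obj, [start0, start1])
    vals = unpack(best.x)
    params = {p: vals[p] for p in SEX_PARAMS}

    # natural parameter vector for the observed information
    natural = []
    for p in SEX_PARAMS:
        v = vals[p]
        natural.extend(v if isinstance(v, tuple) else (v,))

    def mean_fn(tt, x):
        vals_x = {}
        i = 0
        for p in SEX_PARAMS:
            width = 2 if p in varying else 1
            chunk = x[i:i + width]
            vals_x[p] = tuple(float(c) for c in chunk) if width == 2 else float(chunk[0])
            i += width
        return mu_of(vals_x, tt, male)

    fit = _finalize_fit(
        "logistic_sex", ds, params, tuple(names) + ("shape",),
        np.append(natural, 1.0), mean_fn, converged=ok, n_starts=n_starts,
    )
    return fit


# ---------------------------------------------------------------------------
# prediction bands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionBand:
    """Predicted mean CORT at one time with a 95% confidence band.

    ``lo95``/``hi95`` are None when the band is unavailable (singular
    covariance); the lower limit is floored at 0 (concentration scale).
    """

    time: float
    mean: float
    lo95: float | None
    hi95: float | None


def predict_with_ci(fit: CurveFit, times, level: float = 0.95) -> list[PredictionBand]:
    """Delta-method confidence bands for the fitted mean curve.

    The band at each time is the fitted mean ± z * sqrt(g' Σ g), with g the
    numerical gradient of the mean with respect to the mean parameters and
    Σ the corresponding block of the observed-information covariance.
    """
    if not fit.converged:
        raise CurveFitError("cannot form prediction bands from a non-converged fit")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    theta = fit.mean_params_array()
    m = theta.size

    def mean_vec(x):
        if fit.model == "null":
            return np.full(times.shape, float(x[0]))
        if fit.model == "logistic":
            return logistic_mean(times, LogisticParams(*x))
        if fit.model == "quadratic":
            return quadratic_mean(times, QuadraticParams(*x))
        raise ValueError(
            "prediction bands are defined for null/logistic/quadratic fits"
        )

    mean = mean_vec(theta)
    cov_ok = fit.cov is not None and fit.cov.shape[0] >= m
    if cov_ok:
        sub = fit.cov[:m, :m]
        grad = np.empty((times.size, m))
        for j in range(m):
            h = 1e-6 * max(abs(theta[j]), 1.0)
            up = theta.copy(); up[j] += h
            dn = theta.copy(); dn[j] -= h
            grad[:, j] = (mean_vec(up) - mean_vec(dn)) / (2.0 * h)
        var = np.einsum("ij,jk,ik->i", grad, sub, grad)
        cov_ok = bool(np.all(np.isfinite(var)) and np.all(var >= -1e-12))
        if cov_ok:
            se = np.sqrt(np.clip(var, 0.0, None))
            z = norm.ppf(0.5 + level / 2.0)
            lo = np.maximum(mean - z * se, 0.0)
            hi = mean + z * se

    bands = []
    for i, tt in enumerate(times):
        if cov_ok:
            bands.append(PredictionBand(float(tt), float(mean[i]),
                                        float(lo[i]), float(hi[i])))
        else:
            bands.append(PredictionBand(float(tt), float(mean[i]), None, None))
    return bands


def parametric_bootstrap_band(fit: CurveFit, times, n_boot: int = 500,
                              seed: int = 0, level: float = 0.95):
    """Percentile bootstrap band for the fitted mean curve.

    Resimulates gamma data at the original sampling times from the fitted
    model, refits (warm-started at the fitted parameters), and takes
    pointwise percentiles of the refitted mean curves.  Returns an array of
    shape (len(times), 3): mean, lo, hi.
    """
    if fit.model not in ("logistic", "quadratic", "null"):
        raise ValueError("bootstrap bands support null/logistic/quadratic fits")
    rng = np.random.default_rng(seed)
    t_obs = fit.data.time_array()
    mu_obs = fit.mean_at(t_obs)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    theta0 = fit.mean_params_array()

    if fit.model == "logistic":
        def obj_factory(yb):
            def obj(theta):
                mu = np.exp(theta[0]) * expit(theta[1] * (t_obs - theta[2]))
                if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
                    return np.inf
                return _gamma.kernel(yb, mu)
            return obj
        x0 = np.array([np.log(theta0[0]), theta0[1], theta0[2]])
        def curve(theta):
            return np.exp(theta[0]) * expit(theta[1] * (times - theta[2]))
    elif fit.model == "quadratic":
        def obj_factory(yb):
            def obj(theta):
                mu = theta[0] + theta[1] * t_obs + theta[2] * t_obs ** 2
                if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
                    return np.inf
                return _gamma.kernel(yb, mu)
            return obj
        x0 = theta0.copy()
        def curve(theta):
            return theta[0] + theta[1] * times + theta[2] * times ** 2
    else:
        def obj_factory(yb):
            return lambda theta: _gamma.kernel(yb, np.full(t_obs.shape, np.exp(theta[0])))
        x0 = np.array([np.log(theta0[0])])
        def curve(theta):
            return np.full(times.shape, np.exp(theta[0]))

    curves = np.empty((n_boot, times.size))
    for bidx in range(n_boot):
        yb = rng.gamma(shape=fit.shape, scale=mu_obs / fit.shape)
        res = minimize(obj_factory(yb), x0, method="Nelder-Mead",
                       options={"maxiter": 1500, "xatol": 1e-8, "fatol": 1e-9})
        curves[bidx] = curve(res.x)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(curves, alpha, axis=0)
    hi = np.quantile(curves, 1.0 - alpha, axis=0)
    return np.column_stack([fit.mean_at(times), np.maximum(lo, 0.0), hi])
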