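"""AICc-based model selection for the CORT time-course models.

Candidate fits are ranked by the small-sample-corrected Akaike criterion
AICc = -2 logL + 2k + 2k(k+1)/(n-k-1), with Akaike weights
w_i = exp(-Δ_i/2) / Σ exp(-Δ_j/2) computed from unrounded AICc values.
The selection rule is parsimonious: among models within ΔAICc < 2 of the
best, the one with fewest parameters wins.  Explanatory power is reported
as a deviance-based pseudo-R² (1 - D_model/D_null) with a likelihood-ratio
variant alongside.

The sex-varying family asks whether females and males differ in their
CORT response: the shared-curve null plus the seven logistic models in
which each non-empty subset of {a, b, x0} takes sex-specific values (the
gamma shape always shared, counted once).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import Dataset, DataValidationError, Sex
from .curve_models import CurveFit, CurveFitError, fit_curve, fit_sex_logistic

SEX_PARAMS = ("a", "b", "x0")


def aicc(log_lik: float, k: int, n: int) -> float:
    """Akaike criterion with small-sample correction; requires n > k + 1."""
    if n <= k + 1:
        raise ValueError(
            f"AICc undefined for n = {n} <= k + 1 = {k + 1} "
            "(correction denominator non-positive)"
        )
    return -2.0 * log_lik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights from a collection of AICc values (sum to 1)."""
    a = np.asarray(list(aicc_values), dtype=float)
    if a.size == 0:
        raise ValueError("need at least one AICc value")
    if not np.all(np.isfinite(a)):
        raise ValueError("AICc values must be finite")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def pseudo_r2(fit, null_fit) -> float:
    """Deviance-based pseudo-R²: ``1 - D(fit)/D(null)``.

    Both fits must carry a (shape-free) gamma ``deviance`` over the same
    observations; the null is the intercept-only model.
    """
    if getattr(fit, "n", None) != getattr(null_fit, "n", None):
        raise ValueError("pseudo_r2 requires fits to the same dataset")
    if null_fit.deviance <= 0.0:
        raise ValueError(
            "null deviance is zero (all observations identical); pseudo-R2 undefined"
        )
    return 1.0 - fit.deviance / null_fit.deviance


def pseudo_r2_lr(fit, null_fit) -> float:
    """Likelihood-ratio pseudo-R² variant:
    ``1 - exp((2/n) (logL_null - logL_model))``."""
    if getattr(fit, "n", None) != getattr(null_fit, "n", None):
        raise ValueError("pseudo_r2 requires fits to the same dataset")
    n = fit.n
    return 1.0 - float(np.exp((2.0 / n) * (null_fit.log_lik - fit.log_lik)))


@dataclass
class ModelComparisonRow:
    """One line of a model-comparison table.

    ``pseudo_r2`` is None for the null reference row (and for rows whose
    fit failed); ``weight`` is computed over the converged rows of the
    table from unrounded AICc.
    """

    name: str
    resid_df: int | None
    aicc: float
    delta_aicc: float
    k: int
    weight: float
    pseudo_r2: float | None
    pseudo_r2_lr: float | None = None
    converged: bool = True


def _rows_from_fits(named_fits: list[tuple[str, CurveFit | None]],
                    null_for_r2: CurveFit) -> list[ModelComparisonRow]:
    ok = [(name, f) for name, f in named_fits if f is not None]
    aiccs = {name: aicc(f.log_lik, f.k, f.n) for name, f in ok}
    finite = np.array([aiccs[name] for name, _ in ok])
    weights = akaike_weights(finite)
    best = finite.min()
    wmap = {name: float(w) for (name, _), w in zip(ok, weights)}

    rows = []
    for name, f in named_fits:
        if f is None:
            rows.append(ModelComparisonRow(
                name=name, resid_df=None, aicc=np.nan, delta_aicc=np.nan,
                k=0, weight=0.0, pseudo_r2=None, pseudo_r2_lr=None,
                converged=False,
            ))
            continue
        is_null_row = f is null_for_r2
        rows.append(ModelComparisonRow(
            name=name,
            resid_df=f.resid_df,
            aicc=aiccs[name],
            delta_aicc=aiccs[name] - best,
            k=f.k,
            weight=wmap[name],
            pseudo_r2=None if is_null_row else pseudo_r2(f, null_for_r2),
            pseudo_r2_lr=None if is_null_row else pseudo_r2_lr(f, null_for_r2),
            converged=f.converged,
        ))
    rows.sort(key=lambda r: (not r.converged, r.aicc if np.isfinite(r.aicc) else np.inf))
    return rows


def compare_time_models(ds: Dataset) -> list[ModelComparisonRow]:
    """Fit null / logistic / quadratic and rank them by AICc.

    Rows are sorted by AICc; a model whose fit fails to converge is kept as
    a flagged row with no AICc and zero weight.
    """
    fits: list[tuple[str, CurveFit | None]] = []
    null_fit = fit_curve(ds, "null")  # closed-form mean; must succeed
    fits.append(("null", null_fit))
    for name in ("logistic", "quadratic"):
        try:
            fits.append((name, fit_curve(ds, name)))
        except CurveFitError:
            fits.append((name, None))
    return _rows_from_fits(fits, null_for_r2=null_fit)


def select_best(rows: list[ModelComparisonRow], threshold: float = 2.0) -> str:
    """Parsimony rule: among rows with ΔAICc < threshold, the smallest-k
    model wins (ties by name order); otherwise the ΔAICc = 0 row."""
    if not rows:
        raise ValueError("no comparison rows to select from")
    usable = [r for r in rows if r.converged and np.isfinite(r.aicc)]
    if not usable:
        raise ValueError("no converged model to select")
    close = [r for r in usable if r.delta_aicc < threshold]
    if close:
        return min(close, key=lambda r: (r.k, r.name)).name
    return min(usable, key=lambda r: r.delta_aicc).name


@dataclass(frozen=True)
class SexModelSpec:
    """One member of the sex-varying logistic family.

    ``varying`` is the subset of {a, b, x0} taking separate female/male
    values; the empty set is the shared-curve null.  The parameter count
    ``k`` is 3 mean parameters + one duplicate per varying parameter + the
    shared gamma shape.
    """

    varying: frozenset

    @property
    def name(self) -> str:
        if not self.varying:
            return "null"
        return "+".join(p for p in SEX_PARAMS if p in self.varying)

    @property
    def k(self) -> int:
        return 3 + len(self.varying) + 1


def build_sex_model_family() -> list[SexModelSpec]:
    """The 8-member family: null plus every non-empty subset of {a, b, x0}."""
    specs = [SexModelSpec(frozenset())]
    for size in (1, 2, 3):
        for combo in itertools.combinations(SEX_PARAMS, size):
            specs.append(SexModelSpec(frozenset(combo)))
    return specs


def fit_sex_family(ds: Dataset) -> list[ModelComparisonRow]:
    """Fit and AICc-rank the full sex-varying logistic family.

    Requires every bird's sex to be known and at least 4 birds of each sex.
    Pseudo-R² is reported against the constant-mean (intercept-only) model
    for every row, including the family's shared-curve null.
    """
    sexes = ds.sex_array()
    if np.any(sexes == Sex.UNKNOWN.value):
        raise DataValidationError(
            ["sex-varying models require known sex for every bird"]
        )
    pooled = fit_curve(ds, "logistic")
    const_null = fit_curve(ds, "null")
    named_fits: list[tuple[str, CurveFit | None]] = []
    for spec in build_sex_model_family():
        try:
            fit = fit_sex_logistic(ds, spec.varying, pooled=pooled)
        except CurveFitError:
            named_fits.append((spec.name, None))
            continue
        named_fits.append((spec.name, fit))
    return _rows_from_fits(named_fits, null_for_r2=const_null)


def comparison_to_frame(rows: list[ModelComparisonRow]) -> pd.DataFrame:
    """Comparison table as a DataFrame with conventional column names."""
    return pd.DataFrame(
        {
            "model": [r.name for r in rows],
            "resid_df": [r.resid_df for r in rows],
            "aicc": [r.aicc for r in rows],
            "delta_aicc": [r.delta_aicc for r in rows],
            "k": [r.k for r in rows],
            "weight": [r.weight for r in rows],
            "pseudo_r2": [r.pseudo_r2 for r in rows],
            "pseudo_r2_lr": [r.pseudo_r2_lr for r in rows],
            "converged": [r.converged for r in rows],
        }
    )
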