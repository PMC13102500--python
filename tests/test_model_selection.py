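"""AICc, Akaike weights, pseudo-R², comparison tables, sex family."""

import dataclasses
import types

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cortstress import (DataValidationError, LogisticParams, SexEffect,
                        SimConfig, aicc, akaike_weights,
                        build_sex_model_family, compare_time_models,
                        fit_curve, fit_sex_family, pseudo_r2, select_best,
                        simulate_dataset)
from cortstress.model_selection import ModelComparisonRow


# ----------------------------------------------------------------------- aicc

def test_aicc_direct_formula():
    assert aicc(-5.0, 2, 10) == pytest.approx(10 + 4 + 12 / 7)
    # correction term alone, at the study's logistic bookkeeping
    assert aicc(0.0, 4, 63) - (2 * 4) == pytest.approx(2 * 4 * 5 / 58)


def test_aicc_converges_to_aic():
    assert aicc(-100.0, 3, 10 ** 7) == pytest.approx(200 + 6, abs=1e-3)


def test_aicc_requires_enough_observations():
    with pytest.raises(ValueError):
        aicc(-5.0, 4, 5)


@given(st.integers(min_value=1, max_value=8))
def test_aicc_increasing_in_k(k):
    assert aicc(-10.0, k + 1, 100) > aicc(-10.0, k, 100)


# -------------------------------------------------------------------- weights

def test_weight_examples():
    assert akaike_weights([123.4]) == pytest.approx([1.0])
    assert akaike_weights([10.0, 10.0]) == pytest.approx([0.5, 0.5])
    w = akaike_weights([0.0, 2.8, 111.4])
    # frozen from direct evaluation of exp(-delta/2)/sum
    assert w == pytest.approx([0.802183888559, 0.197816111441, 5.17691808504e-25],
                              rel=1e-9)


@given(st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=6),
       st.floats(min_value=-1000, max_value=1000))
def test_weights_shift_invariant_and_normalized(values, shift):
    w0 = akaike_weights(values)
    w1 = akaike_weights([v + shift for v in values])
    assert w0 == pytest.approx(w1, abs=1e-12)
    assert float(np.sum(w0)) == pytest.approx(1.0, abs=1e-9)


# ------------------------------------------------------------------ pseudo-R2

def test_pseudo_r2_limits(default_ds):
    null = fit_curve(default_ds, "null")
    assert pseudo_r2(null, null) == 0.0
    saturated = types.SimpleNamespace(deviance=0.0, n=null.n)
    assert pseudo_r2(saturated, null) == 1.0


def test_pseudo_r2_near_one_for_noiseless_logistic():
    cfg = SimConfig(
        n_shot=0, n_baseline=0, n_trapped=100, n_female=50, n_male=50,
        trapped_time_window=(0.5, 210.0), trapped_shape=1e4, seed=2,
    )
    ds = simulate_dataset(cfg)
    assert pseudo_r2(fit_curve(ds, "logistic"), fit_curve(ds, "null")) > 0.99


# ------------------------------------------------------------------ selection

def _row(name, delta, k):
    return ModelComparisonRow(name=name, resid_df=10, aicc=100 + delta,
                              delta_aicc=delta, k=k, weight=0.5, pseudo_r2=None)


def test_parsimony_rule():
    assert select_best([_row("big", 0.0, 4), _row("small", 1.5, 2)]) == "small"
    assert select_best([_row("first", 0.0, 4), _row("second", 2.8, 4)]) == "first"
    assert select_best([_row("only", 0.0, 3)]) == "only"


# ----------------------------------------------------------- comparison table

def test_table_bookkeeping_on_63_rows(default_ds):
    rows = {r.name: r for r in compare_time_models(default_ds)}
    assert rows["null"].resid_df == 62
    assert rows["logistic"].resid_df == 60
    assert rows["quadratic"].resid_df == 60
    assert sorted(r.k for r in rows.values()) == [2, 4, 4]
    deltas = [r.delta_aicc for r in rows.values()]
    assert min(deltas) == 0.0 and sum(d == 0.0 for d in deltas) == 1
    assert sum(r.weight for r in rows.values()) == pytest.approx(1.0, abs=1e-9)
    assert rows["null"].pseudo_r2 is None
    assert 0.0 <= rows["logistic"].pseudo_r2 <= 1.0


def test_table_invariant_to_row_order(default_ds):
    from cortstress import Dataset
    rng = np.random.default_rng(1)
    perm = rng.permutation(len(default_ds))
    shuffled = Dataset(samples=tuple(default_ds.samples[i] for i in perm))
    a = compare_time_models(default_ds)
    b = compare_time_models(shuffled)
    assert [r.name for r in a] == [r.name for r in b]
    assert [r.aicc for r in a] == pytest.approx([r.aicc for r in b], abs=1e-6)


def test_logistic_truth_selects_logistic(default_ds):
    rows = compare_time_models(default_ds)
    assert select_best(rows) == "logistic"


def test_constant_truth_selects_null():
    cfg = SimConfig(curve=LogisticParams(10.0, 0.0, 0.0), shot_mean=5.0,
                    shot_shape=5.0, trapped_shape=5.0, seed=8)
    rows = compare_time_models(simulate_dataset(cfg))
    assert select_best(rows) == "null"


# ----------------------------------------------------------------- sex family

def test_family_is_null_plus_seven():
    specs = build_sex_model_family()
    assert len(specs) == 8
    assert specs[0].varying == frozenset() and specs[0].name == "null"
    assert sorted(s.k for s in specs) == [4, 5, 5, 5, 6, 6, 6, 7]
    by_name = {s.name: s for s in specs}
    assert by_name["a"].k == 5
    assert by_name["a+b+x0"].k == 7
    # brute force: the varying sets are exactly the subsets of {a,b,x0}
    assert {s.varying for s in specs} == {
        frozenset(sub) for sub in
        [(), ("a",), ("b",), ("x0",), ("a", "b"), ("a", "x0"), ("b", "x0"),
         ("a", "b", "x0")]
    }


def test_sex_family_table_has_eight_rows(default_ds):
    rows = fit_sex_family(default_ds)
    assert len(rows) == 8
    assert {r.name for r in rows} == {"null", "a", "b", "x0", "a+b", "a+x0",
                                      "b+x0", "a+b+x0"}
    null_ll_row = [r for r in rows if r.name == "null"][0]
    assert null_ll_row.resid_df == 60 and null_ll_row.k == 4


def test_sex_family_rejects_unknown_sex():
    from helpers import toy_dataset
    ds = toy_dataset(np.linspace(1, 40, 20), times=np.linspace(1, 200, 20))
    with pytest.raises(DataValidationError, match="sex"):
        fit_sex_family(ds)


def test_strong_sex_effect_is_detected():
    """Males with a doubled asymptote: an a-varying model must win."""
    cfg = SimConfig(
        n_shot=0, n_baseline=0, n_trapped=200, n_female=100, n_male=100,
        trapped_time_window=(0.5, 210.0),
        curve=LogisticParams(30.0, 0.12, 25.0), trapped_shape=6.0,
        sex_effect=SexEffect(a_scale_male=2.0), seed=17,
    )
    rows = fit_sex_family(simulate_dataset(cfg))
    best = select_best(rows)
    assert "a" in best.split("+")
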