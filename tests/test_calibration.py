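"""Fitting and model selection: RSS, AICc, R², simplex fits, ranking."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phasensor import (
    CalibrationSet,
    CandidateRegressor,
    FitOptions,
    InputError,
    ModelSelector,
    REFERENCE_METRICS,
    REFERENCE_N,
    aicc,
    evaluate,
    fit,
    r_squared,
    rss,
    select,
    weighted_rss,
)
from phasensor.calibration import rank_metrics
from phasensor.catalog import get_structure

M_BY_ID = {s.id: s.M for s in map(get_structure, range(1, 14))}


# ---------------------------------------------------------------------------
# residual sums
# ---------------------------------------------------------------------------


def test_rss_hand_example():
    data = CalibrationSet.from_arrays([1.0, 2.0], [1.0, 3.0])
    assert rss(10, {"a": 0.0, "b": 1.0}, data) == pytest.approx(1.0)


def test_rss_zero_on_self_generated_data(phbv_model):
    od = np.array([1.0, 5.0, 10.0, 20.0, 30.0])
    data = CalibrationSet.from_arrays(od, phbv_model.predict(od))
    assert rss(1, phbv_model.params, data) <= 1e-18


def test_rss_infinite_outside_guard():
    data = CalibrationSet.from_arrays([0.0, 1.0], [0.0, 1.0])
    assert rss(2, {"a": 0.0, "b": 1.0}, data) == np.inf


def test_weighted_rss_reduces_to_rss_at_unit_weights(linear_data):
    p = {"a": 0.4, "b": 0.9}
    assert weighted_rss(10, p, linear_data) == pytest.approx(rss(10, p, linear_data))


def test_weighted_rss_single_point():
    data = CalibrationSet.from_arrays([1.0], [3.0], weight=[5.0])
    # prediction 1, residual 2, weight 5 -> 5 * 4
    assert weighted_rss(10, {"a": 0.0, "b": 1.0}, data) == pytest.approx(20.0)


@given(
    st.lists(
        st.tuples(
            st.floats(0.1, 50), st.floats(0, 10), st.integers(1, 4)
        ),
        min_size=1,
        max_size=8,
    )
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_weighted_rss_equals_row_replication(points):
    """Integer weights are equivalent to physically repeating the rows."""
    x = [p[0] for p in points]
    y = [p[1] for p in points]
    w = [float(p[2]) for p in points]
    weighted = CalibrationSet.from_arrays(x, y, weight=w)
    xr = [xi for xi, wi in zip(x, w) for _ in range(int(wi))]
    yr = [yi for yi, wi in zip(y, w) for _ in range(int(wi))]
    replicated = CalibrationSet.from_arrays(xr, yr)
    params = {"a": 0.5, "b": 0.7}
    assert weighted_rss(10, params, weighted) == pytest.approx(
        rss(10, params, replicated), rel=1e-12
    )


# ---------------------------------------------------------------------------
# AICc and R²
# ---------------------------------------------------------------------------


def test_aicc_reproduces_published_values():
    assert aicc(34.907, 24, 2) == pytest.approx(8.476, abs=0.01)
    assert aicc(0.133, 24, 2) == pytest.approx(-49.582, abs=0.01)


def test_aicc_log_identity():
    """Scaling RSS tenfold shifts AICc by exactly N (base-10 logarithm)."""
    for n, m in [(24, 2), (33, 3), (10, 4)]:
        assert aicc(10 * 0.5, n, m) - aicc(0.5, n, m) == pytest.approx(n, abs=1e-10)


def test_aicc_requires_enough_points():
    with pytest.raises(InputError):
        aicc(1.0, 4, 3)


def test_aicc_zero_rss_sentinel():
    with pytest.warns(UserWarning):
        assert aicc(0.0, 24, 2) == -np.inf


@given(st.floats(1e-6, 1e6), st.integers(8, 60), st.integers(1, 5))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_aicc_monotone_in_m_and_rss(rss_value, n, m):
    if n <= m + 2:
        return
    assert aicc(rss_value, n, m + 1) > aicc(rss_value, n, m)
    assert aicc(rss_value * 1.5, n, m) > aicc(rss_value, n, m)


def test_r_squared_limits_and_hand_value():
    data = CalibrationSet.from_arrays([1.0, 2.0], [1.0, 3.0])
    # perfect fit
    assert r_squared(10, {"a": -1.0, "b": 2.0}, data) == pytest.approx(1.0)
    # constant model at the mean
    assert r_squared(10, {"a": 2.0, "b": 0.0}, data) == pytest.approx(0.0)
    # hand arithmetic: TSS = 2, RSS = 1
    assert r_squared(10, {"a": 0.0, "b": 1.0}, data) == pytest.approx(0.5)
    flat = CalibrationSet.from_arrays([1.0, 2.0], [2.0, 2.0])
    with pytest.raises(InputError):
        r_squared(10, {"a": 2.0, "b": 0.0}, flat)


# ---------------------------------------------------------------------------
# published selection tables as a consistency oracle
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("process", ["phb", "phbv"])
def test_reference_aicc_cells_reconstructed(process):
    """N=24 and a base-10 log reproduce every published AICc cell."""
    for mid, row in REFERENCE_METRICS.iterrows():
        got = aicc(row[f"{process}_rss"], REFERENCE_N, M_BY_ID[mid])
        assert got == pytest.approx(row[f"{process}_aicc"], abs=0.05), mid


@pytest.mark.parametrize("process", ["phb", "phbv"])
def test_reference_r2_column_implies_constant_tss(process):
    """RSS/(1-R²) must agree across rows: both columns describe one dataset.

    Cells with 1-R² < 0.017 are excluded: there the ±0.0005 rounding of the
    three-decimal R² alone moves the implied TSS by more than the 3% band.
    """
    t = REFERENCE_METRICS[1.0 - REFERENCE_METRICS[f"{process}_r2"] >= 0.017]
    tss = t[f"{process}_rss"] / (1.0 - t[f"{process}_r2"])
    assert tss.max() / tss.min() < 1.03


def test_ranking_of_published_metrics():
    phb = REFERENCE_METRICS.reset_index()[["model", "phb_rss", "phb_aicc", "phb_r2"]]
    phb.columns = ["model", "rss", "aicc", "r2"]
    phb["M"] = phb["model"].map(M_BY_ID)
    best_aicc, best_r2, _ = rank_metrics(phb)
    assert best_aicc == 7

    phbv = REFERENCE_METRICS.reset_index()[["model", "phbv_rss", "phbv_aicc", "phbv_r2"]]
    phbv.columns = ["model", "rss", "aicc", "r2"]
    phbv["M"] = phbv["model"].map(M_BY_ID)
    best_aicc, best_r2, chosen = rank_metrics(phbv)
    assert best_aicc == 1
    assert best_r2 == 13
    # simple-structure preference keeps the 2-parameter power law
    assert chosen == 1


def test_tie_break_prefers_fewer_parameters():
    import pandas as pd

    metrics = pd.DataFrame(
        {
            "model": [7, 10],
            "M": [3, 2],
            "rss": [0.10, 0.11],
            "aicc": [-50.0, -49.0],
            "r2": [0.999, 0.998],
        }
    )
    best_aicc, _, chosen = rank_metrics(metrics, tie_delta=2.0)
    assert best_aicc == 7
    assert chosen == 10  # within the tie window, parsimony wins


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_linear_fit_equals_closed_form_ols(rng):
    """Simplex fit of the linear structure matches the OLS normal equations."""
    for _ in range(50):
        n = int(rng.integers(5, 20))
        x = rng.uniform(0, 50, n)
        y = np.clip(rng.normal(2 + 0.3 * x, 1.0), 0, None)
        fm = fit(10, CalibrationSet.from_arrays(x, y))
        b_ref, a_ref = np.polyfit(x, y, 1)
        assert fm.params["a"] == pytest.approx(a_ref, abs=1e-6)
        assert fm.params["b"] == pytest.approx(b_ref, abs=1e-6)


def test_noiseless_saturating_fit_recovers_truth():
    a, b = 8.0, 0.05
    od = np.linspace(1, 60, 24)
    data = CalibrationSet.from_arrays(od, a * (1 - np.exp(-b * od)))
    fm = fit(4, data)
    assert fm.params["a"] == pytest.approx(a, rel=1e-3)
    assert fm.params["b"] == pytest.approx(b, rel=1e-3)
    assert fm.rss < 1e-10


def test_constant_data_linear_fit():
    data = CalibrationSet.from_arrays([1.0, 2.0, 3.0, 4.0], [2.5] * 4)
    fm = fit(10, data)
    assert fm.params["b"] == pytest.approx(0.0, abs=1e-6)
    assert fm.params["a"] == pytest.approx(2.5, abs=1e-6)


def test_fit_no_worse_than_initial_guess(linear_data):
    for sid in (1, 3, 4, 7, 10, 11):
        s = get_structure(sid)
        start = s.initial_guess(linear_data)
        fm = fit(sid, linear_data)
        assert fm.rss <= rss(sid, start, linear_data) + 1e-12


def test_fit_is_deterministic(linear_data):
    f1 = fit(7, linear_data, FitOptions(seed=5))
    f2 = fit(7, linear_data, FitOptions(seed=5))
    assert f1.params == f2.params


def test_fit_rejects_too_few_points():
    data = CalibrationSet.from_arrays([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    with pytest.raises(InputError):
        fit(7, data)  # M + 2 = 5 > 3


def test_fitted_model_rss_is_reproducible(linear_data):
    fm = fit(11, linear_data)
    assert fm.rss == pytest.approx(rss(11, fm.params, linear_data), rel=1e-9)


# ---------------------------------------------------------------------------
# sklearn API
# ---------------------------------------------------------------------------


def test_estimator_follows_sklearn_conventions(linear_data):
    from sklearn.base import clone

    reg = CandidateRegressor(structure=10, seed=3)
    assert clone(reg).get_params()["structure"] == 10
    X = linear_data.od.reshape(-1, 1)
    reg.fit(X, linear_data.pha)
    assert reg.predict(X).shape == (len(linear_data),)
    assert reg.score(X, linear_data.pha) > 0.99
    assert reg.n_features_in_ == 1
    reg.set_params(structure=11)
    assert reg.get_params()["structure"] == 11


def test_selector_estimator_selects_truth_structure():
    od = np.linspace(1, 50, 20)
    y = 6.0 * od / (12.0 + od)
    sel = ModelSelector(candidates=(1, 3, 10)).fit(od, y)
    assert sel.best_by_aicc_ == 3
    assert sel.chosen_ == 3
    np.testing.assert_allclose(sel.predict(od), y, atol=1e-5)
    table = sel.selection_table_.table
    assert list(table["model"]) == [1, 3, 10]


def test_select_wrapper_matches_estimator(linear_data):
    tbl = select(linear_data, candidates=(10, 11))
    assert tbl.chosen == 10  # quadratic gains nothing on linear data
    assert set(tbl.models) == {10, 11}
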