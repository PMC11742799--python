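"""Online model updates: weighting, lagged availability, refits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phasensor import (
    CalibrationSet,
    FitOptions,
    InputError,
    UpdatePolicy,
    extend_training_set,
    fit,
    mae,
    schedule_updates,
    update,
)
from phasensor.simulate import (
    PHB_TRUTH_PARAMS,
    SimulationConfig,
    TEST_SAMPLING,
    simulate_experiment,
)


def _sim(n_points=24, seed=0, **kw):
    times = tuple(np.linspace(0, 45, n_points))
    return simulate_experiment(SimulationConfig(sampling_times=times, seed=seed, **kw))


def test_extension_counts_are_additive():
    prior = _sim(24)
    policy = UpdatePolicy()
    for n_new in (9, 20):
        new = _sim(n_new, seed=1)
        ext = extend_training_set(prior, new, policy)
        assert len(ext) == 24 + n_new
    assert len(extend_training_set(prior, _sim(9, seed=1), policy)) == 33
    assert len(extend_training_set(prior, _sim(20, seed=1), policy)) == 44


@given(st.integers(3, 40), st.integers(0, 40))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_extension_count_bookkeeping(n_prior, n_new):
    x = np.linspace(1, 50, max(n_prior, 1))
    prior = CalibrationSet.from_arrays(x, x * 0.1)
    if n_new:
        xn = np.linspace(1, 50, n_new)
        new = CalibrationSet.from_arrays(xn, xn * 0.1)
    else:
        new = CalibrationSet.from_arrays([], [])
    ext = extend_training_set(prior, new, UpdatePolicy())
    assert len(ext) == n_prior + n_new


def test_new_points_get_policy_weight_prior_weights_kept():
    prior = _sim(10)
    new = _sim(5, seed=2)
    ext = extend_training_set(prior, new, UpdatePolicy(weight_new=5.0))
    np.testing.assert_array_equal(ext.weights[:10], np.ones(10))
    np.testing.assert_array_equal(ext.weights[10:], np.full(5, 5.0))


def test_empty_new_set_is_a_no_op():
    prior = _sim(24)
    empty = CalibrationSet.from_arrays([], [])
    ext = extend_training_set(prior, empty, UpdatePolicy())
    assert ext == CalibrationSet(prior.frame, label=prior.label)
    event = update(prior, empty, UpdatePolicy(candidates=(7,)))
    baseline = fit(7, prior)
    assert event.refit.params == pytest.approx(baseline.params)


def test_update_without_shift_keeps_structure_and_parameters():
    """New points drawn from the incumbent's own curve barely move the fit."""
    prior = _sim(24, seed=0)
    incumbent = fit(7, prior)
    new = _sim(12, seed=3, truth_params=dict(incumbent.params))
    event = update(prior, new, UpdatePolicy(candidates=(1, 4, 7, 10)), incumbent=incumbent)
    assert event.refit.structure.id == 7
    for k, v in incumbent.params.items():
        assert event.refit.params[k] == pytest.approx(v, rel=0.10)


def test_update_corrects_a_biased_process():
    """Up-weighted post-shift data pull the curve toward the biased truth."""
    prior = _sim(24, seed=0)
    biased = _sim(15, seed=4, shift_time=0.0, shift_bias=0.8)
    incumbent = fit(7, prior)
    policy = UpdatePolicy(weight_new=5.0, allow_structure_change=False)
    event = update(prior, biased, policy, incumbent=incumbent)
    further = _sim(15, seed=5, shift_time=0.0, shift_bias=0.8)
    assert mae(event.refit, further) < mae(incumbent, further)


def test_fixed_structure_restricts_selection_to_incumbent():
    prior = _sim(24)
    new = _sim(6, seed=6)
    incumbent = fit(7, prior)
    event = update(
        prior, new, UpdatePolicy(allow_structure_change=False), incumbent=incumbent
    )
    assert len(event.selection.table) == 1
    assert event.selection.table.iloc[0]["model"] == 7
    with pytest.raises(InputError):
        update(prior, new, UpdatePolicy(allow_structure_change=False))


def test_update_idempotent_on_exact_fit_data():
    """Duplicating points of an exact fit (RSS=0) cannot move the optimum."""
    od = np.linspace(1, 60, 24)
    y = 8.0 * (1 - np.exp(-0.05 * od))
    prior = CalibrationSet.from_arrays(od, y, time=np.linspace(0, 45, 24))
    incumbent = fit(4, prior)
    event = update(
        prior,
        CalibrationSet.from_arrays(od, y, time=np.linspace(0, 45, 24)),
        UpdatePolicy(weight_new=1.0, allow_structure_change=False),
        incumbent=incumbent,
    )
    for k, v in incumbent.params.items():
        assert event.refit.params[k] == pytest.approx(v, abs=1e-6)


# -- scheduling ---------------------------------------------------------------


def test_schedule_reproduces_lagged_apply_times():
    """Triggers at 12 h and 40 h with a 2 h assay lag apply at 14 h and 43 h."""
    prior = _sim(24, seed=0)
    test = simulate_experiment(
        SimulationConfig(sampling_times=TEST_SAMPLING, seed=1, shift_time=12.0, shift_bias=0.85)
    )
    policy = UpdatePolicy(allow_structure_change=False)
    incumbent = fit(7, prior)
    events = schedule_updates(prior, test, [12.0, 40.0], policy, incumbent=incumbent)
    assert [e.apply_time for e in events] == [14.0, 43.0]
    assert [e.usable_new_points for e in events] == [9, 20]
    assert [e.extended_n for e in events] == [33, 44]


def test_schedule_zero_lag_after_last_sample_uses_everything():
    prior = _sim(10, seed=0)
    series = _sim(8, seed=2)
    incumbent = fit(10, prior)
    policy = UpdatePolicy(lag_h=0.0, allow_structure_change=False)
    (event,) = schedule_updates(prior, series, [100.0], policy, incumbent=incumbent)
    assert event.usable_new_points == 8
    assert event.extended_n == 18


def test_schedule_before_first_sample_is_a_no_op():
    prior = _sim(10, seed=0)
    times = tuple(np.linspace(20, 45, 8))
    series = simulate_experiment(SimulationConfig(sampling_times=times, seed=2))
    incumbent = fit(10, prior)
    policy = UpdatePolicy(allow_structure_change=False)
    (event,) = schedule_updates(prior, series, [5.0], policy, incumbent=incumbent)
    assert event.usable_new_points == 0
    baseline = fit(10, prior)
    assert event.refit.params == pytest.approx(baseline.params)


def test_schedule_rejects_descending_triggers():
    prior = _sim(10)
    with pytest.raises(InputError):
        schedule_updates(prior, prior, [40.0, 12.0], UpdatePolicy(candidates=(10,)))
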