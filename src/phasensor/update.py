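"""Online model updating with lagged, up-weighted in-process measurements.

A calibration trained on one fermentation (say, a batch) systematically
drifts when the process mode changes (say, to continuous operation): cell
size and granule content shift the OD-to-PHA relation — a plant-model
mismatch.  The remedy implemented here is to extend the original training
set with the reference measurements accumulated so far during the running
process, up-weight those new points (default factor 5) so the refit leans
toward current behaviour, refit all candidate structures, and re-select.

Reference measurements are not instantaneous: the offline HPLC assay takes
about two hours, so a measurement sampled at time ``s`` only becomes usable
at ``s + lag_h``.  An update triggered at process time ``t`` (e.g. a known
feed-rate shift) is therefore applied at the first sampling time at or
after ``t + lag_h``, using every sample whose result is available by then.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import (
    FitOptions,
    FittedModel,
    ModelSelector,
    SelectionTable,
    TIE_DELTA_DEFAULT,
)
from .dataset import CalibrationSet
from .errors import InputError

__all__ = ["UpdatePolicy", "UpdateEvent", "extend_training_set", "update", "schedule_updates"]


@dataclass(frozen=True)
class UpdatePolicy:
    """How new in-process measurements enter the refit.

    weight_new : weight given to each new point (prior points keep theirs).
    lag_h : delay between sampling and availability of the PHA reference
        measurement, in hours.
    allow_structure_change : if False, only the incumbent structure is
        refitted; otherwise all ``candidates`` compete again.
    candidates : catalog ids to re-select among (None = all 13).
    """

    weight_new: float = 5.0
    lag_h: float = 2.0
    allow_structure_change: bool = True
    candidates: tuple[int, ...] | None = None
    tie_delta: float = TIE_DELTA_DEFAULT
    fit_options: FitOptions = field(default_factory=FitOptions)

    def __post_init__(self):
        if self.weight_new <= 0:
            raise InputError("weight_new must be positive")
        if self.lag_h < 0:
            raise InputError("lag_h must be non-negative")


@dataclass
class UpdateEvent:
    """One applied model update."""

    trigger_time: float
    apply_time: float
    usable_new_points: int
    extended_n: int
    refit: FittedModel
    selection: SelectionTable


def extend_training_set(
    prior: CalibrationSet, new_points: CalibrationSet, policy: UpdatePolicy
) -> CalibrationSet:
    """Concatenate prior and new data, up-weighting only the new points."""
    if len(new_points) == 0:
        return CalibrationSet(prior.frame.copy(), label=prior.label)
    reweighted = new_points.with_weights(policy.weight_new)
    return prior.concat(reweighted, label=prior.label or "extended")


def update(
    prior: CalibrationSet,
    new_points: CalibrationSet,
    policy: UpdatePolicy,
    incumbent: FittedModel | None = None,
    trigger_time: float = float("nan"),
    apply_time: float = float("nan"),
) -> UpdateEvent:
    """Refit (and optionally re-select) on the weighted extended set.

    The weighted data drive the parameter fit; the ranking metrics are
    computed with unit weights on the extended set.  With
    ``allow_structure_change=False`` the selection degenerates to the
    incumbent structure alone.
    """
    extended = extend_training_set(prior, new_points, policy)
    if policy.allow_structure_change:
        candidates = policy.candidates
    else:
        if incumbent is None:
            raise InputError("allow_structure_change=False requires an incumbent model")
        candidates = (incumbent.structure.id,)
    opts = policy.fit_options
    sel = ModelSelector(
        candidates=candidates,
        tie_delta=policy.tie_delta,
        seed=opts.seed,
        n_restarts=opts.n_restarts,
        xatol=opts.xatol,
        fatol=opts.fatol,
        maxiter_per_param=opts.maxiter_per_param,
    )
    sel.fit(extended.od, extended.pha, sample_weight=extended.weights)
    return UpdateEvent(
        trigger_time=trigger_time,
        apply_time=apply_time,
        usable_new_points=len(new_points),
        extended_n=len(extended),
        refit=sel.chosen_model_,
        selection=sel.selection_table_,
    )


def schedule_updates(
    prior: CalibrationSet,
    labeled_series: CalibrationSet,
    trigger_times: list[float],
    policy: UpdatePolicy,
    incumbent: FittedModel | None = None,
) -> list[UpdateEvent]:
    """Run updates at each trigger, honouring the measurement lag.

    ``labeled_series`` holds the in-process samples (time-ordered; times
    required).  For a trigger at ``t`` the update is applied at the first
    sampling time ``>= t + lag_h`` (or at ``t + lag_h`` if sampling has
    ended); usable new points are those sampled at ``s`` with
    ``s + lag_h <= apply_time``.  Later events include earlier events' new
    points, so successive refits accumulate information.
    """
    if any(b < a for a, b in zip(trigger_times, trigger_times[1:])):
        raise InputError("trigger_times must be ascending")
    series = labeled_series.sorted_by_time()
    times = series.time
    if np.any(~np.isfinite(times)):
        raise InputError("labeled_series needs finite sampling times")
    events = []
    for t in trigger_times:
        later = times[times >= t + policy.lag_h]
        apply_time = float(later[0]) if later.size else t + policy.lag_h
        usable = series.frame[times + policy.lag_h <= apply_time]
        new_points = CalibrationSet(usable, label=series.label)
        events.append(
            update(
                prior,
                new_points,
                policy,
                incumbent=incumbent,
                trigger_time=float(t),
                apply_time=apply_time,
            )
        )
    return events
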