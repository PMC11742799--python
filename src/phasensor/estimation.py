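"""Applying a calibrated curve to OD time series.

The soft sensor proper: given a fitted OD600 → PHA curve, turn a monitored
OD trajectory into a PHA concentration trajectory with a first-order
uncertainty band, and score estimates against offline reference
measurements (HPLC) with the mean absolute error.

Uncertainty is propagated to first order in the OD replicate noise only:

    sigma_PHA = |df/dx (OD)| * sigma_OD

Parameter uncertainty is deliberately excluded — replicate SDs of the OD
measurement are the dominant, and the only routinely available, noise
source at estimation time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import FittedModel
from .dataset import CalibrationSet
from .errors import InputError

__all__ = ["EstimateSeries", "estimate_series", "propagate_sd", "mae", "cross_validate"]


@dataclass
class EstimateSeries:
    """Time-indexed PHA estimates with propagated SD and provenance.

    ``frame`` columns: time_h, od_mean, od_sd, pha_est, pha_sd_est,
    extrapolated.  ``extrapolated`` flags OD values outside the calibration
    range of the model; they are estimated anyway (a batch-trained model is
    routinely applied to a continuous process that grows further) but the
    flag lets downstream consumers discount them.
    """

    frame: pd.DataFrame
    structure_id: int
    params: dict[str, float]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def pha_est(self) -> np.ndarray:
        return self.frame["pha_est"].to_numpy()

    @property
    def pha_sd_est(self) -> np.ndarray:
        return self.frame["pha_sd_est"].to_numpy()


def propagate_sd(model: FittedModel, od, od_sd) -> np.ndarray | float:
    """First-order propagated PHA SD: ``|df/dx(od)| * od_sd`` (g/L)."""
    od_arr = np.asarray(od, dtype=float)
    sd_arr = np.asarray(od_sd, dtype=float)
    if np.any(sd_arr < 0):
        raise InputError("od_sd must be non-negative")
    slope = np.abs(model.slope(od_arr))
    out = np.asarray(slope * sd_arr, dtype=float)
    # exact zero in, exact zero out — even where the slope is infinite
    out = np.where(sd_arr == 0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def estimate_series(model: FittedModel, od_series) -> EstimateSeries:
    """Estimate PHA (with SD) for a time-ordered OD series.

    ``od_series`` may be a DataFrame with columns ``time_h``, ``od_mean``
    and optionally ``od_sd``, a :class:`CalibrationSet`, or a plain
    (time, od, od_sd) tuple of arrays.
    """
    if isinstance(od_series, CalibrationSet):
        t, od, od_sd = od_series.time, od_series.od, od_series.od_sd
    elif isinstance(od_series, pd.DataFrame):
        if "od_mean" not in od_series.columns:
            raise InputError("od_series needs an od_mean column")
        t = od_series.get("time_h", pd.Series(np.nan, index=od_series.index)).to_numpy(float)
        od = od_series["od_mean"].to_numpy(float)
        od_sd = (
            od_series["od_sd"].to_numpy(float)
            if "od_sd" in od_series.columns
            else np.zeros_like(od)
        )
    else:
        t, od, od_sd = (np.asarray(a, dtype=float) for a in od_series)
    pha_est = np.atleast_1d(model.predict(od))
    pha_sd = np.atleast_1d(propagate_sd(model, od, od_sd))
    frame = pd.DataFrame(
        {
            "time_h": t,
            "od_mean": od,
            "od_sd": od_sd,
            "pha_est": pha_est,
            "pha_sd_est": pha_sd,
            "extrapolated": model.is_extrapolation(od),
        }
    )
    return EstimateSeries(frame=frame, structure_id=model.structure.id, params=dict(model.params))


def mae(model: FittedModel, labeled: CalibrationSet) -> float:
    """Mean absolute error of the model on labeled (OD, PHA) data, in g/L."""
    if len(labeled) == 0:
        raise InputError("cannot compute MAE on an empty dataset")
    yhat = np.atleast_1d(model.predict(labeled.od))
    return float(np.mean(np.abs(labeled.pha - yhat)))


def cross_validate(
    models: list[FittedModel] | dict[str, FittedModel],
    datasets: list[CalibrationSet] | dict[str, CalibrationSet],
) -> pd.DataFrame:
    """MAE of every model on every dataset.

    Returns a float DataFrame with one row per model and one column per
    dataset; ``result.attrs["best_model"]`` maps each dataset to its
    minimising model.  This is the cross-validation used to compare
    process-specific calibrations: each process's own calibration should
    beat the other's on its data.
    """
    if not isinstance(models, dict):
        models = {f"model_{m.structure.id}": m for m in models}
    if not isinstance(datasets, dict):
        datasets = {d.label or f"dataset_{i}": d for i, d in enumerate(datasets)}
    mat = pd.DataFrame(
        {
            dname: {mname: mae(m, d) for mname, m in models.items()}
            for dname, d in datasets.items()
        }
    )
    mat.attrs["best_model"] = {c: mat[c].idxmin() for c in mat.columns}
    return mat
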