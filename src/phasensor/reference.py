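"""Published reference calibrations for the two benchmark processes.

Two fermentation campaigns with *Cupriavidus necator* serve as the
package's reference cases:

* **PHB** — poly(3-hydroxybutyrate) produced on fructose; the training
  experiment is a batch cultivation.  The selected calibration is the
  three-parameter saturating-exponential-power curve (structure 7)::

      c_PHB = 8.2031 * (1 - exp(-0.0556 * OD))^3.1885

* **PHBV** — poly(3-hydroxybutyrate-co-3-hydroxyvalerate) produced on
  fructose plus propionic acid; the training experiment is a fed-batch.
  The selected calibration is the two-parameter power law (structure 1)::

      c_PHBV = 0.0404 * OD^1.4341

``REFERENCE_METRICS`` holds the complete published selection table for both
training sets (residual sum of squares, small-sample corrected AIC, and R²
for all 13 candidate structures).  Both training sets contained N = 24
points; the AICc values are reproduced by the base-10 form implemented in
:func:`phasensor.calibration.aicc`.  The raw OD-PHA pairs themselves were
never deposited, so these tables and the two fitted curves are the only
quantitative anchors available for regression testing.
"""

from __future__ import annotations

import pandas as pd

from .calibration import FittedModel
from .catalog import get_structure

__all__ = [
    "REFERENCE_N",
    "REFERENCE_METRICS",
    "phb_reference_model",
    "phbv_reference_model",
]

#: training-set size of both reference calibrations
REFERENCE_N = 24

_METRICS_ROWS = [
    # model, phb_rss, phb_aicc, phb_r2, phbv_rss, phbv_aicc, phbv_r2
    (1, 0.735, -31.757, 0.994, 0.133, -49.582, 0.988),
    (2, 34.907, 8.476, 0.696, 2.776, -17.912, 0.753),
    (3, 4.830, -12.139, 0.958, 0.480, -36.206, 0.957),
    (4, 4.861, -12.072, 0.958, 0.483, -36.143, 0.957),
    (5, 108.557, 22.931, 0.056, 11.221, -0.724, 0.003),
    (6, 0.992, -26.006, 0.991, 0.120, -48.001, 0.989),
    (7, 0.189, -43.308, 0.998, 0.134, -46.843, 0.988),
    (8, 49.129, 17.572, 0.573, 0.181, -40.840, 0.984),
    (9, 67.522, 20.887, 0.413, 6.014, -4.319, 0.466),
    (10, 2.066, -20.989, 0.982, 0.245, -43.219, 0.978),
    (11, 2.779, -15.270, 0.976, 0.390, -35.743, 0.965),
    (12, 0.216, -38.986, 0.998, 0.120, -45.130, 0.989),
    (13, 0.199, -36.629, 0.998, 0.084, -45.573, 0.993),
]

#: published per-candidate selection metrics for both training fermentations
REFERENCE_METRICS = pd.DataFrame(
    _METRICS_ROWS,
    columns=[
        "model",
        "phb_rss",
        "phb_aicc",
        "phb_r2",
        "phbv_rss",
        "phbv_aicc",
        "phbv_r2",
    ],
).set_index("model")

_PHB_PARAMS = {"a": 8.2031, "b": 0.0556, "c": 3.1885}
_PHBV_PARAMS = {"a": 0.0404, "b": 1.4341}


def phb_reference_model() -> FittedModel:
    """The published PHB calibration (structure 7) as a FittedModel."""
    row = REFERENCE_METRICS.loc[7]
    return FittedModel(
        structure=get_structure(7),
        params=dict(_PHB_PARAMS),
        rss=float(row["phb_rss"]),
        n_points=REFERENCE_N,
        converged=True,
        n_restarts_used=0,
        aicc=float(row["phb_aicc"]),
        r2=float(row["phb_r2"]),
        od_range=(0.4, 60.0),
        label="PHB reference",
    )


def phbv_reference_model() -> FittedModel:
    """The published PHBV calibration (structure 1) as a FittedModel."""
    row = REFERENCE_METRICS.loc[1]
    return FittedModel(
        structure=get_structure(1),
        params=dict(_PHBV_PARAMS),
        rss=float(row["phbv_rss"]),
        n_points=REFERENCE_N,
        converged=True,
        n_restarts_used=0,
        aicc=float(row["phbv_aicc"]),
        r2=float(row["phbv_r2"]),
        od_range=(0.4, 35.0),
        label="PHBV reference",
    )
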