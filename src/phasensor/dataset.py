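"""Calibration data containers.

A :class:`CalibrationSet` is a thin, validated wrapper around a pandas
DataFrame with one row per sampling point: time (h), OD600 replicate mean
and SD, measured PHA concentration (g/L) and SD, and a positive fitting
weight.  Weights default to 1 and only matter during model updates, where
freshly measured in-process points are up-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError

__all__ = ["COLUMNS", "CalibrationSet"]

#: canonical column order, shared with the CSV dialect in :mod:`phasensor.io`
COLUMNS = ("time_h", "od_mean", "od_sd", "pha_g_per_l", "pha_sd", "weight")

_DEFAULTS = {"time_h": np.nan, "od_sd": 0.0, "pha_sd": 0.0, "weight": 1.0}


@dataclass
class CalibrationSet:
    """Paired (OD, PHA) observations with replicate SDs and fit weights."""

    frame: pd.DataFrame
    label: str = ""

    def __post_init__(self):
        df = pd.DataFrame(self.frame).copy()
        for col in COLUMNS:
            if col not in df.columns:
                if col in _DEFAULTS:
                    df[col] = _DEFAULTS[col]
                else:
                    raise InputError(f"calibration data lacks required column {col!r}")
        df = df[list(COLUMNS)].astype(float).reset_index(drop=True)
        df["od_sd"] = df["od_sd"].fillna(0.0)
        df["pha_sd"] = df["pha_sd"].fillna(0.0)
        df["weight"] = df["weight"].fillna(1.0)
        self._validate(df)
        self.frame = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        labeled = df.dropna(subset=["pha_g_per_l"])
        if not np.isfinite(labeled[["od_mean", "pha_g_per_l"]].to_numpy()).all():
            raise ValidationError("od_mean and pha_g_per_l must be finite")
        if (df["od_mean"] < 0).any():
            raise ValidationError("negative OD values are not physical")
        if (labeled["pha_g_per_l"] < 0).any():
            raise ValidationError("negative PHA concentrations are not physical")
        if (df["weight"] <= 0).any():
            raise ValidationError("weights must be strictly positive")
        if ((df[["od_sd", "pha_sd"]] < 0).any()).any():
            raise ValidationError("standard deviations must be non-negative")

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        od,
        pha,
        *,
        time=None,
        od_sd=None,
        pha_sd=None,
        weight=None,
        label: str = "",
    ) -> "CalibrationSet":
        od = np.atleast_1d(np.asarray(od, dtype=float))
        pha = np.atleast_1d(np.asarray(pha, dtype=float))
        if od.shape != pha.shape:
            raise InputError("od and pha must have the same length")
        n = od.size
        df = pd.DataFrame(
            {
                "time_h": np.full(n, np.nan) if time is None else np.asarray(time, float),
                "od_mean": od,
                "od_sd": np.zeros(n) if od_sd is None else np.asarray(od_sd, float),
                "pha_g_per_l": pha,
                "pha_sd": np.zeros(n) if pha_sd is None else np.asarray(pha_sd, float),
                "weight": np.ones(n) if weight is None else np.asarray(weight, float),
            }
        )
        return cls(df, label=label)

    # -- accessors -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n(self) -> int:
        """Number of labeled calibration points N."""
        return len(self.frame)

    @property
    def time(self) -> np.ndarray:
        return self.frame["time_h"].to_numpy()

    @property
    def od(self) -> np.ndarray:
        return self.frame["od_mean"].to_numpy()

    @property
    def od_sd(self) -> np.ndarray:
        return self.frame["od_sd"].to_numpy()

    @property
    def pha(self) -> np.ndarray:
        return self.frame["pha_g_per_l"].to_numpy()

    @property
    def pha_sd(self) -> np.ndarray:
        return self.frame["pha_sd"].to_numpy()

    @property
    def weights(self) -> np.ndarray:
        return self.frame["weight"].to_numpy()

    def with_weights(self, weight: float) -> "CalibrationSet":
        """Copy of the set with every point's weight replaced."""
        df = self.frame.copy()
        df["weight"] = float(weight)
        return CalibrationSet(df, label=self.label)

    def concat(self, other: "CalibrationSet", label: str | None = None) -> "CalibrationSet":
        df = pd.concat([self.frame, other.frame], ignore_index=True)
        return CalibrationSet(df, label=self.label if label is None else label)

    def sorted_by_time(self) -> "CalibrationSet":
        df = self.frame.sort_values("time_h", kind="stable").reset_index(drop=True)
        return CalibrationSet(df, label=self.label)

    def __eq__(self, other) -> bool:  # field-by-field equality, NaN-tolerant
        if not isinstance(other, CalibrationSet):
            return NotImplemented
        return self.label == other.label and self.frame.equals(other.frame)
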