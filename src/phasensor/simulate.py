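"""Fermentation-like synthetic data for the soft-sensor workflow.

No raw OD-PHA trajectories from the two reference campaigns were ever
deposited, so testable inputs have to be generated.  The generator emulates
the statistical structure the workflow consumes, nothing more:

* OD follows a logistic growth curve — the simplest monotone sigmoid
  consistent with typical batch/fed-batch OD600 trajectories of
  *C. necator* (inoculation near OD 0.4, plateau at the process-specific
  maximum).  No mechanistic substrate/biomass model is attempted; the
  workflow only ever sees (OD, PHA) pairs.
* Observed OD is the mean of ``replicates`` noisy readings with
  multiplicative Gaussian noise (spectrophotometric error scales with the
  signal); the replicate SD is recorded alongside.
* PHA is the ground-truth calibration curve evaluated at the true OD, plus
  additive Gaussian noise truncated at zero (HPLC replicate scatter is
  roughly constant in concentration), optionally times a constant
  multiplicative bias after a process shift — the plant-model mismatch
  that motivates online updating.

Everything is driven by one integer seed; identical configs give identical
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import FittedModel
from .catalog import get_structure
from .dataset import CalibrationSet
from .errors import InputError

__all__ = [
    "SimulationConfig",
    "simulate_od",
    "simulate_experiment",
    "make_benchmark_pair",
    "PHB_TRUTH_PARAMS",
    "PHBV_TRUTH_PARAMS",
]

#: ground-truth parameters of the PHB reference calibration (structure 7)
PHB_TRUTH_PARAMS = {"a": 8.2031, "b": 0.0556, "c": 3.1885}
#: ground-truth parameters of the PHBV reference calibration (structure 1)
PHBV_TRUTH_PARAMS = {"a": 0.0404, "b": 1.4341}

#: default sampling grid: 24 samples over 45 h (one every ~2 h)
DEFAULT_SAMPLING = tuple(np.linspace(0.0, 45.0, 24))

#: test-process sampling grid: denser early sampling, then every 2.5 h,
#: with a gap before the final samples so updates triggered at 12 h and
#: 40 h (2 h assay lag) are applied at the 14 h and 43 h samplings with 9
#: and 20 usable points, respectively
TEST_SAMPLING = (
    0.0, 1.5, 3.0, 4.5, 6.0, 7.5, 9.0, 10.5, 12.0,
    14.0, 16.5, 19.0, 21.5, 24.0, 26.5, 29.0, 31.5, 34.0, 36.5, 39.0,
    43.0, 45.0,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and noise model for one simulated fermentation.

    Defaults describe a PHB-like batch: inoculation at OD 0.4, plateau
    near OD 60, specific growth rate 0.25 1/h, 24 samples over 45 h in
    triplicate, 2% relative OD noise and 0.1 g/L HPLC noise.
    """

    od0: float = 0.4
    od_max: float = 60.0
    growth_rate: float = 0.25
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING
    truth_structure: int = 7
    truth_params: dict[str, float] = field(
        default_factory=lambda: dict(PHB_TRUTH_PARAMS)
    )
    pha_noise_sd: float = 0.1
    od_rel_noise_sd: float = 0.02
    replicates: int = 3
    shift_time: float | None = None
    shift_bias: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.od0 <= 0 or self.od_max <= self.od0:
            raise InputError("need 0 < od0 < od_max")
        if self.growth_rate <= 0:
            raise InputError("growth_rate must be positive")
        t = np.asarray(self.sampling_times, dtype=float)
        if t.size == 0 or np.any(np.diff(t) <= 0) or np.any(t < 0):
            raise InputError("sampling_times must be non-negative and strictly increasing")
        if self.pha_noise_sd < 0 or self.od_rel_noise_sd < 0:
            raise InputError("noise SDs must be non-negative")
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")


def simulate_od(config: SimulationConfig) -> pd.DataFrame:
    """Noise-free logistic OD trajectory at the configured sampling times.

    od(t) = od_max / (1 + ((od_max - od0)/od0) * exp(-growth_rate * t)),
    so od(0) = od0 and od -> od_max; strictly increasing in t.
    """
    t = np.asarray(config.sampling_times, dtype=float)
    q = (config.od_max - config.od0) / config.od0
    od = config.od_max / (1.0 + q * np.exp(-config.growth_rate * t))
    return pd.DataFrame({"time_h": t, "od_true": od})


def truth_model(config: SimulationConfig) -> FittedModel:
    """The generator's ground-truth curve packaged as a FittedModel."""
    s = get_structure(config.truth_structure)
    traj = simulate_od(config)
    return FittedModel(
        structure=s,
        params=dict(config.truth_params),
        rss=0.0,
        n_points=len(traj),
        converged=True,
        od_range=(float(traj["od_true"].min()), float(traj["od_true"].max())),
        label="simulation truth",
    )


def simulate_experiment(
    config: SimulationConfig, return_replicates: bool = False
):
    """Draw one noisy fermentation dataset from the configured ground truth.

    Returns a labeled :class:`CalibrationSet`; with
    ``return_replicates=True`` also the replicate-level OD table.
    """
    rng = np.random.default_rng(config.seed)
    traj = simulate_od(config)
    t = traj["time_h"].to_numpy()
    od_true = traj["od_true"].to_numpy()
    n = t.size

    eps = rng.normal(0.0, config.od_rel_noise_sd, size=(n, config.replicates))
    od_reps = od_true[:, None] * (1.0 + eps)
    od_mean = od_reps.mean(axis=1)
    od_sd = od_reps.std(axis=1, ddof=1) if config.replicates > 1 else np.zeros(n)

    s = get_structure(config.truth_structure)
    pha_true = np.atleast_1d(s.evaluate(config.truth_params, od_true))
    if config.shift_time is not None:
        pha_true = np.where(t >= config.shift_time, pha_true * config.shift_bias, pha_true)
    pha = pha_true + rng.normal(0.0, config.pha_noise_sd, size=n)
    pha = np.clip(pha, 0.0, None)

    data = CalibrationSet.from_arrays(
        od_mean,
        pha,
        time=t,
        od_sd=od_sd,
        pha_sd=np.full(n, config.pha_noise_sd),
        label=f"sim(model {config.truth_structure}, seed {config.seed})",
    )
    if return_replicates:
        reps = pd.DataFrame(
            od_reps, columns=[f"od_rep_{i + 1}" for i in range(config.replicates)]
        )
        reps.insert(0, "time_h", t)
        return data, reps
    return data


def make_benchmark_pair(
    process: str, seed: int = 0
) -> tuple[CalibrationSet, CalibrationSet, SimulationConfig, SimulationConfig]:
    """Training/test pair emulating one of the two reference campaigns.

    ``process="PHB"``: structure-7 truth, batch-like training run (OD to
    ~60) and a continuous-mode test run in which the true PHA falls 15%
    below the calibration curve after the 12 h shift to continuous feeding
    (the batch-trained model then overestimates, as observed when a
    batch calibration is applied to a continuous process).

    ``process="PHBV"``: structure-1 truth, fed-batch-like runs with OD to
    ~35 and no shift (the test run differs only in its noise draw).

    Returns (training set, test set, training config, test config); the
    configs carry the ground truth for oracle checks.
    """
    process = process.upper()
    if process == "PHB":
        train_cfg = SimulationConfig(seed=seed)
        test_cfg = replace(
            train_cfg,
            sampling_times=TEST_SAMPLING,
            shift_time=12.0,
            shift_bias=0.85,
            seed=seed + 1,
        )
    elif process == "PHBV":
        train_cfg = SimulationConfig(
            od_max=35.0,
            growth_rate=0.2,
            truth_structure=1,
            truth_params=dict(PHBV_TRUTH_PARAMS),
            seed=seed,
        )
        test_cfg = replace(train_cfg, seed=seed + 1)
    else:
        raise InputError(f"unknown process {process!r}; expected 'PHB' or 'PHBV'")
    train = simulate_experiment(train_cfg)
    test = simulate_experiment(test_cfg)
    train = CalibrationSet(train.frame, label=f"{process} training (synthetic)")
    test = CalibrationSet(test.frame, label=f"{process} test (synthetic)")
    return train, test, train_cfg, test_cfg
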