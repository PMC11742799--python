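"""Curve fitting and model selection for the OD600 → PHA soft sensor.

Each candidate structure is calibrated by minimising the (optionally
weighted) residual sum of squares

    RSS(theta) = sum_i w_i * (y_i - f(x_i; theta))^2

with a derivative-free Nelder-Mead simplex search started from a
deterministic heuristic guess plus a fixed number of seeded log-uniform
perturbations of it; the best feasible local optimum wins.  Candidates are
then ranked by the small-sample corrected Akaike information criterion

    AICc = N log10(RSS/N) + 2 M N / (N - M - 1)

and by R².  Note the base-10 logarithm: the reference selection tables for
the PHB and PHBV benchmark calibrations are reproduced by this form (with
N = 24) and not by the natural-log variant, so base 10 is what this package
implements throughout.

Selection metrics (RSS, AICc, R²) are always computed with unit weights,
even when the fit itself was weighted: N in the AICc penalty is a count of
data points, and up-weighting recent measurements is a statement about the
objective, not about how much data exists.

The primary interface is a pair of scikit-learn style estimators,
:class:`CandidateRegressor` (one structure) and :class:`ModelSelector`
(fit all candidates, rank, choose); the module-level functions ``fit``,
``select``, ``rss``, ``weighted_rss``, ``aicc`` and ``r_squared`` are thin
wrappers over them for script use.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin

from .catalog import ModelStructure, catalog, get_structure
from .dataset import CalibrationSet
from .errors import FitError, InputError, SelectionError

logger = logging.getLogger(__name__)

__all__ = [
    "FitOptions",
    "FittedModel",
    "SelectionTable",
    "CandidateRegressor",
    "ModelSelector",
    "rss",
    "weighted_rss",
    "aicc",
    "r_squared",
    "fit",
    "select",
]

#: candidates within this AICc distance of the minimum count as tied
TIE_DELTA_DEFAULT = 2.0


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for the simplex search.

    ``n_restarts`` extra starts are drawn by multiplying each nonzero
    component of the heuristic guess by a log-uniform factor in
    ``perturb_range`` (zero components get a small additive jitter); the
    draw is fixed by ``seed``, so fits are fully deterministic.
    """

    seed: int = 0
    n_restarts: int = 10
    perturb_range: tuple[float, float] = (0.2, 5.0)
    xatol: float = 1e-8
    fatol: float = 1e-8
    maxiter_per_param: int = 400
    polish: bool = True


@dataclass
class FittedModel:
    """A candidate structure with calibrated parameters and fit provenance.

    ``rss`` is always the unweighted residual sum of squares on the fitting
    set; ``aicc``/``r2`` are the unit-weight selection metrics (NaN when not
    computable, ``-inf`` for an exact interpolation).
    """

    structure: ModelStructure
    params: dict[str, float]
    rss: float
    n_points: int
    converged: bool
    n_restarts_used: int = 0
    aicc: float = float("nan")
    r2: float = float("nan")
    od_range: tuple[float, float] | None = None
    seed: int | None = None
    label: str = ""

    @property
    def M(self) -> int:
        return self.structure.M

    def predict(self, od):
        """Predicted PHA concentration (g/L) at the given OD value(s)."""
        return self.structure.evaluate(self.params, od)

    def slope(self, od):
        """Analytic d(PHA)/d(OD) at the given OD value(s)."""
        return self.structure.derivative_dx(self.params, od)

    def is_extrapolation(self, od) -> np.ndarray:
        """True where ``od`` lies outside the calibration OD range."""
        od = np.asarray(od, dtype=float)
        if self.od_range is None:
            return np.zeros(od.shape, dtype=bool)
        lo, hi = self.od_range
        return (od < lo) | (od > hi)


# ---------------------------------------------------------------------------
# objective pieces
# ---------------------------------------------------------------------------


def _safe_predictions(structure: ModelStructure, params, x: np.ndarray):
    """Model predictions, or None if any point violates the domain guard."""
    try:
        ok = structure.guard_ok(params, x)
    except InputError:
        raise
    except Exception:
        return None
    if not np.all(ok):
        return None
    with np.errstate(all="ignore"):
        yhat = np.asarray(structure._eval(*structure._values(params), x), dtype=float)
    yhat = np.broadcast_to(yhat, x.shape)
    if not np.all(np.isfinite(yhat)):
        return None
    return yhat


def _objective(structure, x, y, w):
    """Weighted-RSS objective returning +inf outside the domain guard."""

    def obj(theta):
        params = structure.params_from_array(theta)
        yhat = _safe_predictions(structure, params, x)
        if yhat is None:
            return np.inf
        r = y - yhat
        val = float(np.sum(w * r * r))
        return val if np.isfinite(val) else np.inf

    return obj


def rss(structure, params, data: CalibrationSet) -> float:
    """Unweighted residual sum of squares of a candidate on ``data``.

    Returns ``+inf`` (rather than raising) when any point violates the
    structure's domain guard, matching the optimizer's convention.
    """
    s = get_structure(structure) if isinstance(structure, int) else structure
    yhat = _safe_predictions(s, params, data.od)
    if yhat is None:
        return float("inf")
    r = data.pha - yhat
    return float(np.sum(r * r))


def weighted_rss(structure, params, data: CalibrationSet) -> float:
    """Weighted residual sum of squares, sum_i w_i (y_i - f(x_i))^2."""
    s = get_structure(structure) if isinstance(structure, int) else structure
    yhat = _safe_predictions(s, params, data.od)
    if yhat is None:
        return float("inf")
    r = data.pha - yhat
    return float(np.sum(data.weights * r * r))


def aicc(rss_value: float, n: int, m: int) -> float:
    """Small-sample corrected Akaike information criterion (base-10 log).

    AICc = N log10(RSS/N) + 2MN/(N - M - 1).  Requires N > M + 1; an RSS of
    exactly zero (perfect interpolation) yields ``-inf`` with a warning.
    """
    n, m = int(n), int(m)
    if n <= m + 1:
        raise InputError(f"AICc needs N > M + 1 (got N={n}, M={m})")
    if rss_value < 0:
        raise InputError("RSS must be non-negative")
    if rss_value == 0:
        warnings.warn("RSS is exactly zero; AICc is -inf", stacklevel=2)
        return float("-inf")
    return float(n * np.log10(rss_value / n) + 2.0 * m * n / (n - m - 1))


def r_squared(structure, params, data: CalibrationSet) -> float:
    """Coefficient of determination, 1 - RSS / sum (y_i - mean(y))^2."""
    y = data.pha
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise InputError("R^2 undefined: all PHA values are identical")
    return 1.0 - rss(structure, params, data) / tss


def mean_absolute_error_model(structure, params, data: CalibrationSet) -> float:
    """MAE of a candidate's predictions on labeled data (helper)."""
    s = get_structure(structure) if isinstance(structure, int) else structure
    yhat = s.evaluate(params, data.od)
    return float(np.mean(np.abs(data.pha - yhat)))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _starting_points(structure, data, options: FitOptions) -> list[np.ndarray]:
    guess = structure.initial_guess(data)
    theta0 = np.array([guess[p] for p in structure.param_names], dtype=float)
    starts = [theta0]
    rng = np.random.default_rng(options.seed)
    lo, hi = options.perturb_range
    for _ in range(options.n_restarts):
        factors = np.exp(rng.uniform(np.log(lo), np.log(hi), size=theta0.size))
        jitter = rng.normal(0.0, 0.1, size=theta0.size)
        theta = np.where(theta0 != 0.0, theta0 * factors, jitter)
        starts.append(theta)
    return starts


def _fit_arrays(
    structure: ModelStructure,
    od: np.ndarray,
    pha: np.ndarray,
    weights: np.ndarray,
    options: FitOptions,
    label: str = "",
) -> FittedModel:
    n = od.size
    if n < structure.M + 2:
        raise InputError(
            f"model {structure.id} needs at least M + 2 = {structure.M + 2} "
            f"points, got {n}"
        )
    data = CalibrationSet.from_arrays(od, pha, weight=weights, label=label)
    obj = _objective(structure, od, pha, weights)
    nm_opts = {
        "xatol": options.xatol,
        "fatol": options.fatol,
        "maxiter": options.maxiter_per_param * structure.M,
        "maxfev": 2 * options.maxiter_per_param * structure.M,
    }

    best = None
    best_val = np.inf
    n_feasible = 0
    converged = False
    for theta0 in _starting_points(structure, data, options):
        if not np.isfinite(obj(theta0)):
            continue
        n_feasible += 1
        res = minimize(obj, theta0, method="Nelder-Mead", options=nm_opts)
        if res.fun < best_val:
            best, best_val, converged = res.x, res.fun, bool(res.success)
    if best is None:
        raise FitError(structure.id)
    if options.polish:
        res = minimize(obj, best, method="Nelder-Mead", options=nm_opts)
        if res.fun <= best_val:
            best, best_val, converged = res.x, res.fun, bool(res.success)

    params = structure.params_from_array(best)
    rss_val = rss(structure, params, data)
    aicc_val = float("nan")
    if n > structure.M + 1 and np.isfinite(rss_val):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aicc_val = aicc(rss_val, n, structure.M) if rss_val >= 0 else float("nan")
    try:
        r2_val = r_squared(structure, params, data)
    except InputError:
        r2_val = float("nan")
    logger.info(
        "fit model %d: %d/%d starts feasible, RSS=%.6g, converged=%s",
        structure.id, n_feasible, options.n_restarts + 1, rss_val, converged,
    )
    return FittedModel(
        structure=structure,
        params=params,
        rss=rss_val,
        n_points=n,
        converged=converged,
        n_restarts_used=n_feasible,
        aicc=aicc_val,
        r2=r2_val,
        od_range=(float(od.min()), float(od.max())),
        seed=options.seed,
        label=label,
    )


# ---------------------------------------------------------------------------
# scikit-learn estimators
# ---------------------------------------------------------------------------


def _as_1d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise InputError("exactly one feature (the OD600 column) is expected")
        X = X[:, 0]
    elif X.ndim != 1:
        raise InputError("X must be a 1-d array or a single-column 2-d array")
    return X


class CandidateRegressor(RegressorMixin, BaseEstimator):
    """Calibrate one candidate curve structure as a sklearn regressor.

    Parameters
    ----------
    structure : int, default=7
        Catalog id (1-13) of the candidate structure.
    seed : int, default=0
        Seed for the multi-start perturbations; fits are deterministic.
    n_restarts, perturb_low, perturb_high, xatol, fatol, maxiter_per_param :
        Simplex-search settings, see :class:`FitOptions`.

    Attributes
    ----------
    model_ : FittedModel
        The calibrated curve with provenance.
    params_ : dict
        Fitted parameter values keyed by name.
    rss_, aicc_, r2_ : float
        Unweighted selection metrics on the training data.

    Examples
    --------
    >>> reg = CandidateRegressor(structure=10).fit([[1.0], [2.0], [3.0]],
    ...                                            [1.0, 2.0, 3.0])
    >>> float(round(reg.params_["b"], 6))
    1.0
    """

    def __init__(
        self,
        structure: int = 7,
        *,
        seed: int = 0,
        n_restarts: int = 10,
        perturb_low: float = 0.2,
        perturb_high: float = 5.0,
        xatol: float = 1e-8,
        fatol: float = 1e-8,
        maxiter_per_param: int = 400,
    ):
        self.structure = structure
        self.seed = seed
        self.n_restarts = n_restarts
        self.perturb_low = perturb_low
        self.perturb_high = perturb_high
        self.xatol = xatol
        self.fatol = fatol
        self.maxiter_per_param = maxiter_per_param

    def _options(self) -> FitOptions:
        return FitOptions(
            seed=self.seed,
            n_restarts=self.n_restarts,
            perturb_range=(self.perturb_low, self.perturb_high),
            xatol=self.xatol,
            fatol=self.fatol,
            maxiter_per_param=self.maxiter_per_param,
        )

    def fit(self, X, y, sample_weight=None):
        x = _as_1d(X)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise InputError("X and y must have the same number of samples")
        w = np.ones_like(x) if sample_weight is None else np.asarray(sample_weight, float)
        if w.shape != x.shape or np.any(w <= 0):
            raise InputError("sample_weight must be positive and match X")
        s = self.structure if isinstance(self.structure, ModelStructure) else get_structure(self.structure)
        self.model_ = _fit_arrays(s, x, y, w, self._options())
        self.params_ = dict(self.model_.params)
        self.rss_ = self.model_.rss
        self.aicc_ = self.model_.aicc
        self.r2_ = self.model_.r2
        self.n_points_ = self.model_.n_points
        self.converged_ = self.model_.converged
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        return np.atleast_1d(self.model_.predict(_as_1d(X)))

    def predict_sd(self, X, od_sd):
        """First-order propagated PHA SD, |df/dx| * od_sd."""
        x = _as_1d(X)
        sd = np.broadcast_to(np.asarray(od_sd, dtype=float), x.shape)
        return np.abs(np.atleast_1d(self.model_.slope(x))) * sd


@dataclass
class SelectionTable:
    """Per-candidate fit metrics with AICc/R² ranking.

    ``table`` has one row per requested candidate (``rss`` is ``inf`` for
    candidates that could not be fitted; those are excluded from ranking).
    ``chosen`` applies the parsimony tie-break: among candidates within
    ``tie_delta`` AICc units of the minimum, take the fewest parameters,
    then the lowest id.
    """

    table: pd.DataFrame
    models: dict[int, FittedModel]
    best_by_aicc: int
    best_by_r2: int
    chosen: int
    tie_delta: float = TIE_DELTA_DEFAULT

    @property
    def chosen_model(self) -> FittedModel:
        return self.models[self.chosen]


def rank_metrics(
    metrics: pd.DataFrame, tie_delta: float = TIE_DELTA_DEFAULT
) -> tuple[int, int, int]:
    """Rank a metrics table (columns model/M/rss/aicc/r2) as ``select`` would.

    Returns (best_by_aicc, best_by_r2, chosen).  Useful for ranking metric
    tables computed elsewhere, e.g. the published reference tables.
    """
    t = metrics.reset_index() if "model" not in metrics.columns else metrics.copy()
    finite = t[np.isfinite(t["aicc"])]
    if finite.empty:
        raise SelectionError("no candidate has a finite AICc")
    best_aicc = int(finite.loc[finite["aicc"].idxmin(), "model"])
    best_r2 = int(finite.loc[finite["r2"].idxmax(), "model"])
    amin = float(finite["aicc"].min())
    ties = finite[finite["aicc"] <= amin + tie_delta].copy()
    ties = ties.sort_values(["M", "model"], kind="stable")
    chosen = int(ties.iloc[0]["model"])
    return best_aicc, best_r2, chosen


class ModelSelector(RegressorMixin, BaseEstimator):
    """Fit every candidate structure and select by AICc with parsimony ties.

    Mirrors the full calibration workflow: each candidate in ``candidates``
    (catalog ids; default all 13) is fitted by multi-start simplex search,
    unit-weight RSS/AICc/R² are tabulated, candidates are ranked by AICc
    ascending, and the chosen model applies the tie-break (within
    ``tie_delta`` of the minimum AICc, prefer fewer parameters, then lower
    id — a sigmoid and a quartic that fit equally well should lose to the
    simpler curve).  ``predict`` uses the chosen model.
    """

    def __init__(
        self,
        candidates: tuple[int, ...] | None = None,
        *,
        tie_delta: float = TIE_DELTA_DEFAULT,
        seed: int = 0,
        n_restarts: int = 10,
        xatol: float = 1e-8,
        fatol: float = 1e-8,
        maxiter_per_param: int = 400,
    ):
        self.candidates = candidates
        self.tie_delta = tie_delta
        self.seed = seed
        self.n_restarts = n_restarts
        self.xatol = xatol
        self.fatol = fatol
        self.maxiter_per_param = maxiter_per_param

    def fit(self, X, y, sample_weight=None):
        x = _as_1d(X)
        y = np.asarray(y, dtype=float)
        ids = tuple(self.candidates) if self.candidates is not None else tuple(
            s.id for s in catalog()
        )
        w = np.ones_like(x) if sample_weight is None else np.asarray(sample_weight, float)
        unit = CalibrationSet.from_arrays(x, y)

        rows, models = [], {}
        options = FitOptions(
            seed=self.seed,
            n_restarts=self.n_restarts,
            xatol=self.xatol,
            fatol=self.fatol,
            maxiter_per_param=self.maxiter_per_param,
        )
        for sid in ids:
            s = get_structure(sid)
            row = {"model": s.id, "name": s.name, "M": s.M}
            try:
                fm = _fit_arrays(s, x, y, w, options)
            except (FitError, InputError) as exc:
                logger.warning("model %d infeasible: %s", s.id, exc)
                row.update(rss=np.inf, aicc=np.nan, r2=np.nan, converged=False)
                rows.append(row)
                continue
            # selection metrics are always unit-weight, even for weighted fits
            rss_u = rss(s, fm.params, unit)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                aicc_u = (
                    aicc(rss_u, unit.n, s.M)
                    if unit.n > s.M + 1 and np.isfinite(rss_u)
                    else np.nan
                )
            try:
                r2_u = r_squared(s, fm.params, unit)
            except InputError:
                r2_u = np.nan
            fm = replace(fm, rss=rss_u, aicc=aicc_u, r2=r2_u)
            models[s.id] = fm
            row.update(rss=rss_u, aicc=aicc_u, r2=r2_u, converged=fm.converged)
            row.update({f"param_{p}": v for p, v in fm.params.items()})
            rows.append(row)

        table = pd.DataFrame(rows)
        if not models or not np.isfinite(table["aicc"]).any():
            raise SelectionError("no candidate structure could be fitted")
        best_aicc, best_r2, chosen = rank_metrics(table, self.tie_delta)
        self.selection_table_ = SelectionTable(
            table=table,
            models=models,
            best_by_aicc=best_aicc,
            best_by_r2=best_r2,
            chosen=chosen,
            tie_delta=self.tie_delta,
        )
        self.best_by_aicc_ = best_aicc
        self.best_by_r2_ = best_r2
        self.chosen_ = chosen
        self.chosen_model_ = self.selection_table_.chosen_model
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        return np.atleast_1d(self.chosen_model_.predict(_as_1d(X)))


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def fit(structure, data: CalibrationSet, options: FitOptions | None = None) -> FittedModel:
    """Fit one candidate structure to a calibration set (weighted RSS)."""
    s = get_structure(structure) if isinstance(structure, int) else structure
    opts = options or FitOptions()
    fm = _fit_arrays(s, data.od, data.pha, data.weights, opts, label=data.label)
    return fm


def select(
    data: CalibrationSet,
    candidates: tuple[int, ...] | None = None,
    options: FitOptions | None = None,
    tie_delta: float = TIE_DELTA_DEFAULT,
) -> SelectionTable:
    """Fit all candidates to ``data`` and rank them by AICc."""
    opts = options or FitOptions()
    sel = ModelSelector(
        candidates=candidates,
        tie_delta=tie_delta,
        seed=opts.seed,
        n_restarts=opts.n_restarts,
        xatol=opts.xatol,
        fatol=opts.fatol,
        maxiter_per_param=opts.maxiter_per_param,
    )
    sel.fit(data.od, data.pha, sample_weight=data.weights)
    return sel.selection_table_
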