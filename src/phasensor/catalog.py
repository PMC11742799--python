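"""Catalog of candidate curve structures relating OD600 to PHA concentration.

The soft sensor rests on a static calibration curve ``y = f(x)`` where ``x``
is the (dilution-corrected, dimensionless) optical density at 600 nm and
``y`` the intracellular PHA concentration in g/L.  Because no single
functional form suits every organism/process combination, the workflow fits
a whole catalog of 13 candidate structures — power laws, saturating
exponentials, hyperbolae, sigmoids, and polynomials up to degree four — and
lets an information criterion pick among them.

Each structure is a first-class :class:`ModelStructure` object bundling

* a vectorised evaluation rule ``f(params, x)``,
* its analytic derivative ``df/dx`` (needed for first-order error
  propagation of OD replicate noise into the PHA estimate),
* a domain guard marking where the formula is real and finite, and
* a deterministic initial-guess heuristic for the simplex optimizer.

Model 8 is read as ``y = a*(1 - [1 + (x/c)^d]^(-b))``, the standard
four-parameter log-logistic saturation curve; this is the only well-formed,
sigmoidal reading of its occasionally mis-bracketed printed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence, TYPE_CHECKING

import numpy as np

from .errors import DomainError, InputError

if TYPE_CHECKING:  # pragma: no cover
    from .dataset import CalibrationSet

__all__ = [
    "ModelStructure",
    "catalog",
    "get_structure",
    "evaluate",
    "derivative_dx",
    "default_initial_guess",
]

ParameterVector = Mapping[str, float]


@dataclass(frozen=True)
class ModelStructure:
    """One candidate calibration-curve structure.

    Attributes
    ----------
    id : int
        Catalog position, 1-13.
    name : str
        Short human label, e.g. ``"power"`` or ``"cubic"``.
    param_names : tuple of str
        Ordered parameter names drawn from ``(a, b, c, d, e)``.
    formula_text : str
        Human-readable formula, for reports and logs.
    domain_guard : str
        Prose description of where evaluation is real and finite.
    """

    id: int
    name: str
    param_names: tuple[str, ...]
    formula_text: str
    domain_guard: str
    _eval: Callable[..., np.ndarray] = field(repr=False, compare=False)
    _deriv: Callable[..., np.ndarray] = field(repr=False, compare=False)
    _guard: Callable[..., np.ndarray] = field(repr=False, compare=False)
    _guess: Callable[["CalibrationSet"], dict[str, float]] = field(
        repr=False, compare=False
    )

    @property
    def M(self) -> int:
        """Number of free parameters."""
        return len(self.param_names)

    # -- parameter plumbing -------------------------------------------------
    def _values(self, params: ParameterVector) -> tuple[float, ...]:
        missing = [p for p in self.param_names if p not in params]
        if missing:
            raise InputError(
                f"model {self.id} requires parameters {self.param_names}, "
                f"missing {missing}"
            )
        extras = [p for p in params if p not in self.param_names]
        if extras:
            raise InputError(f"model {self.id} got unexpected parameters {extras}")
        return tuple(float(params[p]) for p in self.param_names)

    def params_from_array(self, values: Sequence[float]) -> dict[str, float]:
        if len(values) != self.M:
            raise InputError(
                f"model {self.id} expects {self.M} parameters, got {len(values)}"
            )
        return dict(zip(self.param_names, (float(v) for v in values)))

    # -- core surface --------------------------------------------------------
    def guard_ok(self, params: ParameterVector, x) -> np.ndarray:
        """Boolean mask: True where (params, x) is inside the domain."""
        vals = self._values(params)
        x = np.asarray(x, dtype=float)
        ok = np.broadcast_to(np.asarray(self._guard(*vals, x)), x.shape).copy()
        ok &= np.isfinite(x)
        return ok

    def evaluate(self, params: ParameterVector, x) -> np.ndarray | float:
        """Predicted PHA concentration (g/L) at OD ``x``.

        Raises :class:`DomainError` if any point violates the domain guard.
        """
        vals = self._values(params)
        xa = np.asarray(x, dtype=float)
        ok = self.guard_ok(params, xa)
        if not np.all(ok):
            bad = np.atleast_1d(xa)[~np.atleast_1d(ok)]
            raise DomainError(self.id, f"x={bad[0]!r} outside domain ({self.domain_guard})")
        with np.errstate(all="ignore"):
            y = np.asarray(self._eval(*vals, xa), dtype=float)
        y = np.broadcast_to(y, xa.shape)
        if not np.all(np.isfinite(y)):
            raise DomainError(self.id, "evaluation produced a non-finite value")
        return float(y) if np.isscalar(x) or xa.ndim == 0 else y.copy()

    def derivative_dx(self, params: ParameterVector, x) -> np.ndarray | float:
        """Analytic slope df/dx (g/L per OD unit) at OD ``x``."""
        vals = self._values(params)
        xa = np.asarray(x, dtype=float)
        ok = self.guard_ok(params, xa)
        if not np.all(ok):
            bad = np.atleast_1d(xa)[~np.atleast_1d(ok)]
            raise DomainError(self.id, f"x={bad[0]!r} outside domain ({self.domain_guard})")
        with np.errstate(all="ignore"):
            d = np.asarray(self._deriv(*vals, xa), dtype=float)
        d = np.broadcast_to(d, xa.shape)
        if not np.all(np.isfinite(d)):
            raise DomainError(self.id, "derivative is non-finite")
        return float(d) if np.isscalar(x) or xa.ndim == 0 else d.copy()

    def initial_guess(self, data: "CalibrationSet") -> dict[str, float]:
        """Deterministic, feasible simplex start for this structure."""
        if len(data) == 0:
            raise InputError("cannot build an initial guess from an empty dataset")
        return self._guess(data)


# ---------------------------------------------------------------------------
# formula implementations
#
# Each _eval/_deriv takes the parameter scalars (in param_names order)
# followed by an ndarray x; guards take the same signature and return a
# boolean array.  np.errstate is suppressed by the caller; guards must make
# non-finite results impossible.
# ---------------------------------------------------------------------------


def _safe_pow(base, expo):
    # real-valued power; caller's guard guarantees base >= 0
    return np.power(base, expo)


# model 1: y = a * x^b ------------------------------------------------------
def _g1(a, b, x):
    # x >= 0; at x == 0 the power is real only for b > 0 (y -> 0) or integer b
    ok = x >= 0
    if b <= 0 and b != int(b):
        ok = ok & (x > 0)
    elif b < 0:
        ok = ok & (x != 0)
    return ok


def _e1(a, b, x):
    out = np.where(x > 0, a * _safe_pow(np.where(x > 0, x, 1.0), b), 0.0)
    if b == 0:
        out = np.where(x == 0, a, out)
    elif b < 0:  # integer negative b, x != 0 by guard
        out = a * _safe_pow(x, b)
    return out


def _d1(a, b, x):
    inner = np.where(x > 0, a * b * _safe_pow(np.where(x > 0, x, 1.0), b - 1.0), 0.0)
    if b > 1 or b == 0:
        return np.where(x == 0, 0.0, inner)
    if b == 1:
        return np.full_like(x, a)
    # 0 < b < 1 has an infinite slope at 0; guard already allows x=0 so we
    # report the one-sided limit only for x > 0 and fail loudly at 0
    return np.where(x == 0, np.inf, inner)


# model 2: y = a + b*log(x) -------------------------------------------------
def _g2(a, b, x):
    return x > 0


def _e2(a, b, x):
    return a + b * np.log(x)


def _d2(a, b, x):
    return b / x


# model 3: y = a*x/(b+x) ----------------------------------------------------
def _g3(a, b, x):
    return b + x != 0


def _e3(a, b, x):
    return a * x / (b + x)


def _d3(a, b, x):
    return a * b / (b + x) ** 2


# model 4: y = a*(1 - exp(-b x)) --------------------------------------------
def _g4(a, b, x):
    return np.ones_like(x, dtype=bool)


def _e4(a, b, x):
    return a * -np.expm1(-b * x)


def _d4(a, b, x):
    return a * b * np.exp(-b * x)


# model 5: y = a - b*c^x ----------------------------------------------------
def _g5(a, b, c, x):
    # real exponential base
    return np.full_like(x, c > 0, dtype=bool)


def _e5(a, b, c, x):
    return a - b * _safe_pow(c, x)


def _d5(a, b, c, x):
    return -b * _safe_pow(c, x) * math.log(c)


# model 6: y = (a + b x)/(1 + c x) ------------------------------------------
def _g6(a, b, c, x):
    return 1.0 + c * x != 0


def _e6(a, b, c, x):
    return (a + b * x) / (1.0 + c * x)


def _d6(a, b, c, x):
    return (b - a * c) / (1.0 + c * x) ** 2


# model 7: y = a*(1 - exp(-b x))^c -------------------------------------------
def _g7(a, b, c, x):
    base = -np.expm1(-b * x)
    ok = base >= 0
    if c <= 0:
        ok = ok & (base > 0)
    return ok


def _e7(a, b, c, x):
    base = -np.expm1(-b * x)
    return a * _safe_pow(base, c)


def _d7(a, b, c, x):
    base = -np.expm1(-b * x)
    inner = a * c * b * np.exp(-b * x)
    out = np.where(
        base > 0, inner * _safe_pow(np.where(base > 0, base, 1.0), c - 1.0), 0.0
    )
    if 0 < c < 1:
        out = np.where(base == 0, np.inf, out)
    elif c == 1:
        out = inner
    return out


# model 8: y = a*(1 - [1 + (x/c)^d]^(-b)) ------------------------------------
def _g8(a, b, c, d, x):
    if c == 0:
        return np.zeros_like(x, dtype=bool)
    r = x / c
    ok = r >= 0
    if d <= 0 and d != int(d):
        ok = ok & (r > 0)
    elif d < 0:
        ok = ok & (r != 0)
    with np.errstate(all="ignore"):
        u = 1.0 + _safe_pow(np.where(ok & (r > 0), r, 1.0), d)
    return ok & (u > 0)


def _e8(a, b, c, d, x):
    r = x / c
    rd = np.where(r > 0, _safe_pow(np.where(r > 0, r, 1.0), d), 0.0 if d > 0 else 1.0)
    if d == 0:
        rd = np.ones_like(r)
    u = 1.0 + rd
    return a * (1.0 - _safe_pow(u, -b))


def _d8(a, b, c, d, x):
    r = x / c
    rpos = np.where(r > 0, r, 1.0)
    rd = np.where(r > 0, _safe_pow(rpos, d), 0.0 if d > 0 else 1.0)
    if d == 0:
        return np.zeros_like(x)
    u = 1.0 + rd
    inner = a * b * _safe_pow(u, -b - 1.0) * (d / c) * _safe_pow(rpos, d - 1.0)
    out = np.where(r > 0, inner, 0.0)
    if 0 < d < 1:
        out = np.where(r == 0, np.inf, out)
    elif d == 1:
        out = a * b * _safe_pow(u, -b - 1.0) / c
    return out


# model 9: y = a*(1 - exp(-(b(x-c))^d)) ---------------------------------------
def _g9(a, b, c, d, x):
    v = b * (x - c)
    ok = v >= 0
    if d <= 0 and d != int(d):
        ok = ok & (v > 0)
    elif d < 0:
        ok = ok & (v != 0)
    return ok


def _e9(a, b, c, d, x):
    v = b * (x - c)
    vd = np.where(v > 0, _safe_pow(np.where(v > 0, v, 1.0), d), 0.0 if d > 0 else 1.0)
    if d == 0:
        vd = np.ones_like(v)
    return a * -np.expm1(-vd)


def _d9(a, b, c, d, x):
    v = b * (x - c)
    vpos = np.where(v > 0, v, 1.0)
    vd = np.where(v > 0, _safe_pow(vpos, d), 0.0 if d > 0 else 1.0)
    if d == 0:
        return np.zeros_like(x)
    inner = a * np.exp(-vd) * d * _safe_pow(vpos, d - 1.0) * b
    out = np.where(v > 0, inner, 0.0)
    if 0 < d < 1:
        out = np.where(v == 0, np.inf, out)
    elif d == 1:
        out = a * np.exp(-vd) * b
    return out


# models 10-13: polynomials ---------------------------------------------------
def _gpoly(*args):
    x = args[-1]
    return np.ones_like(x, dtype=bool)


def _e10(a, b, x):
    return b * x + a


def _d10(a, b, x):
    return np.full_like(x, b)


def _e11(a, b, c, x):
    return c * x**2 + b * x + a


def _d11(a, b, c, x):
    return 2 * c * x + b


def _e12(a, b, c, d, x):
    return d * x**3 + c * x**2 + b * x + a


def _d12(a, b, c, d, x):
    return 3 * d * x**2 + 2 * c * x + b


def _e13(a, b, c, d, e, x):
    return e * x**4 + d * x**3 + c * x**2 + b * x + a


def _d13(a, b, c, d, e, x):
    return 4 * e * x**3 + 3 * d * x**2 + 2 * c * x + b


# ---------------------------------------------------------------------------
# initial-guess heuristics
#
# All are deterministic, cheap, and feasible by construction.  They matter
# because the simplex search is local: a start on the right scale is worth
# more than extra restarts.
# ---------------------------------------------------------------------------


def _polyfit_guess(degree: int):
    names = ("a", "b", "c", "d", "e")[: degree + 1]

    def guess(data):
        x, y = data.od, data.pha
        if len(np.unique(x)) <= degree:
            coeffs = np.zeros(degree + 1)
            coeffs[0] = float(np.mean(y))
        else:
            coeffs = np.polyfit(x, y, degree)[::-1]  # ascending order
        return dict(zip(names, (float(v) for v in coeffs)))

    return guess


def _guess1(data):
    # log-log OLS: log y = log a + b log x
    x, y = data.od, data.pha
    m = (x > 0) & (y > 0)
    if m.sum() < 2:
        return {"a": max(float(np.max(y)), 1e-3), "b": 1.0}
    slope, intercept = np.polyfit(np.log(x[m]), np.log(y[m]), 1)
    return {"a": float(np.exp(intercept)), "b": float(slope)}


def _guess2(data):
    # semi-log OLS: y on log x
    x, y = data.od, data.pha
    m = x > 0
    if m.sum() < 2:
        return {"a": float(np.mean(y)), "b": 1.0}
    slope, intercept = np.polyfit(np.log(x[m]), y[m], 1)
    return {"a": float(intercept), "b": float(slope)}


def _ymax_scale(data):
    a = 1.1 * float(np.max(data.pha))
    xs = float(np.median(data.od))
    return a, max(xs, 1e-6)


def _guess3(data):
    a, xmed = _ymax_scale(data)
    return {"a": a, "b": xmed}


def _guess4(data):
    a, xmed = _ymax_scale(data)
    return {"a": a, "b": 1.0 / xmed}


def _guess5(data):
    a, xmed = _ymax_scale(data)
    b = a - float(np.min(data.pha))
    return {"a": a, "b": max(b, 1e-3), "c": math.exp(-1.0 / xmed)}


def _guess6(data):
    x, y = data.od, data.pha
    order = np.argsort(x)
    x, y = x[order], y[order]
    dx = x[-1] - x[0]
    slope = (y[-1] - y[0]) / dx if dx > 0 else 0.0
    return {"a": float(np.min(y)), "b": float(slope), "c": 0.01}


def _guess7(data):
    a, xmed = _ymax_scale(data)
    return {"a": a, "b": 1.0 / xmed, "c": 1.0}


def _guess8(data):
    a, xmed = _ymax_scale(data)
    return {"a": a, "b": 1.0, "c": xmed, "d": 2.0}


def _guess9(data):
    a, xmed = _ymax_scale(data)
    c = 0.5 * float(np.min(data.od))
    return {"a": a, "b": 1.0 / xmed, "c": c, "d": 1.0}


# ---------------------------------------------------------------------------
# the catalog itself
# ---------------------------------------------------------------------------

_CATALOG: tuple[ModelStructure, ...] = (
    ModelStructure(1, "power", ("a", "b"), "y = a*x^b",
                   "x >= 0 (x > 0 if b is negative or fractional)",
                   _e1, _d1, _g1, _guess1),
    ModelStructure(2, "log", ("a", "b"), "y = a + b*log(x)",
                   "x > 0", _e2, _d2, _g2, _guess2),
    ModelStructure(3, "hyperbolic", ("a", "b"), "y = a*x/(b + x)",
                   "b + x != 0", _e3, _d3, _g3, _guess3),
    ModelStructure(4, "sat-exp", ("a", "b"), "y = a*(1 - exp(-b*x))",
                   "all real x", _e4, _d4, _g4, _guess4),
    ModelStructure(5, "geometric", ("a", "b", "c"), "y = a - b*c^x",
                   "c > 0", _e5, _d5, _g5, _guess5),
    ModelStructure(6, "rational", ("a", "b", "c"), "y = (a + b*x)/(1 + c*x)",
                   "1 + c*x != 0", _e6, _d6, _g6, _guess6),
    ModelStructure(7, "sat-exp-power", ("a", "b", "c"), "y = a*(1 - exp(-b*x))^c",
                   "1 - exp(-b*x) >= 0, i.e. b*x >= 0",
                   _e7, _d7, _g7, _guess7),
    ModelStructure(8, "log-logistic", ("a", "b", "c", "d"),
                   "y = a*(1 - [1 + (x/c)^d]^(-b))",
                   "c != 0, x/c >= 0, 1 + (x/c)^d > 0",
                   _e8, _d8, _g8, _guess8),
    ModelStructure(9, "weibull", ("a", "b", "c", "d"),
                   "y = a*(1 - exp(-(b*(x - c))^d))",
                   "b*(x - c) >= 0", _e9, _d9, _g9, _guess9),
    ModelStructure(10, "linear", ("a", "b"), "y = b*x + a",
                   "all real x", _e10, _d10, _gpoly, _polyfit_guess(1)),
    ModelStructure(11, "quadratic", ("a", "b", "c"), "y = c*x^2 + b*x + a",
                   "all real x", _e11, _d11, _gpoly, _polyfit_guess(2)),
    ModelStructure(12, "cubic", ("a", "b", "c", "d"),
                   "y = d*x^3 + c*x^2 + b*x + a",
                   "all real x", _e12, _d12, _gpoly, _polyfit_guess(3)),
    ModelStructure(13, "quartic", ("a", "b", "c", "d", "e"),
                   "y = e*x^4 + d*x^3 + c*x^2 + b*x + a",
                   "all real x", _e13, _d13, _gpoly, _polyfit_guess(4)),
)


def catalog() -> tuple[ModelStructure, ...]:
    """The 13 candidate structures, in catalog order (ids 1-13)."""
    return _CATALOG


def get_structure(structure_id: int) -> ModelStructure:
    """Look a structure up by its 1-based catalog id."""
    if not 1 <= int(structure_id) <= 13:
        raise InputError(f"structure id must be 1..13, got {structure_id}")
    return _CATALOG[int(structure_id) - 1]


def evaluate(structure: ModelStructure | int, params: ParameterVector, x):
    """Predicted PHA concentration (g/L) at OD ``x`` under a candidate curve."""
    s = get_structure(structure) if isinstance(structure, int) else structure
    return s.evaluate(params, x)


def derivative_dx(structure: ModelStructure | int, params: ParameterVector, x):
    """Analytic slope df/dx of a candidate curve at OD ``x``."""
    s = get_structure(structure) if isinstance(structure, int) else structure
    return s.derivative_dx(params, x)


def default_initial_guess(structure: ModelStructure | int, data) -> dict[str, float]:
    """Deterministic simplex starting point for ``structure`` on ``data``."""
    s = get_structure(structure) if isinstance(structure, int) else structure
    return s.initial_guess(data)
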