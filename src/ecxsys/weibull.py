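"""Four-parameter Weibull curve: evaluation, closed-form inversion, fitting.

The curve ``f(x) = c + (d - c) * exp(-exp(b * (log(x) - log(e))))`` is used
twice in the package: survival versus toxicant concentration (x in µg/L) and
system stress versus toxicant stress (x in general-stress units).  For
``b > 0`` it decreases from ``d`` (the continuity value at x = 0) to ``c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateDataError, DomainError

__all__ = ["WeibullParams", "FitResult", "weibull_evaluate", "weibull_inverse", "weibull_fit"]

PARAM_NAMES = ("b", "c", "d", "e")


@dataclass(frozen=True)
class WeibullParams:
    """Parameters of the 4-parameter Weibull curve.

    b : relative slope around the inflection point (> 0)
    c : lower limit
    d : upper limit (>= c)
    e : inflection point (> 0); f(e) = c + (d - c)/e^... = c + (d-c)*exp(-1)
    """

    b: float
    c: float
    d: float
    e: float

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise DomainError(f"slope b must be > 0, got {self.b}")
        if not self.e > 0:
            raise DomainError(f"inflection e must be > 0, got {self.e}")
        if self.c > self.d:
            raise DomainError(f"lower limit c={self.c} exceeds upper limit d={self.d}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.b, self.c, self.d, self.e)


@dataclass
class FitResult:
    """Outcome of a least-squares Weibull fit."""

    params: WeibullParams
    fixed_mask: dict[str, float] = field(default_factory=dict)
    residual_sum_of_squares: float = 0.0
    n_points: int = 0
    converged: bool = False


def weibull_evaluate(params: WeibullParams, x):
    """Evaluate the Weibull curve at ``x`` (scalar or array, >= 0).

    ``x = 0`` returns ``d``, the continuity limit for ``b > 0``.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise DomainError(f"abscissa must be non-negative, got {x}")
    b, c, d, e = params.as_tuple()
    with np.errstate(divide="ignore", over="ignore"):
        inner = np.exp(b * (np.log(x_arr) - np.log(e)))
    out = c + (d - c) * np.exp(-inner)
    out = np.where(x_arr == 0.0, d, out)
    return out.item() if np.isscalar(x) or x_arr.ndim == 0 else out


def weibull_inverse(params: WeibullParams, y):
    """Closed-form preimage of ``y`` under the Weibull curve.

    ``y`` must lie strictly between ``c`` and ``d`` (no finite preimage
    otherwise).
    """
    y_arr = np.asarray(y, dtype=float)
    b, c, d, e = params.as_tuple()
    if np.any(y_arr <= c) or np.any(y_arr >= d):
        raise DomainError(f"value must lie strictly in ({c}, {d}), got {y}")
    out = e * np.exp(np.log(-np.log((y_arr - c) / (d - c))) / b)
    return out.item() if np.isscalar(y) or y_arr.ndim == 0 else out


def _default_initial_e(xs: np.ndarray, ys: np.ndarray, c: float, d: float) -> float:
    """Geometric mean of positive xs whose y falls in the middle response band."""
    lo, hi = c + 0.25 * (d - c), c + 0.75 * (d - c)
    pos = xs > 0
    mid = pos & (ys >= lo) & (ys <= hi)
    pick = xs[mid] if np.any(mid) else xs[pos]
    if pick.size == 0:
        raise DegenerateDataError("no positive abscissae to seed the inflection guess")
    return float(np.exp(np.mean(np.log(pick)))) if np.any(mid) else float(np.median(pick))


def weibull_fit(
    xs,
    ys,
    fixed: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    initial_guess: dict[str, float] | None = None,
    weights=None,
) -> FitResult:
    """Bounded least-squares fit of the Weibull curve.

    Parameters named in ``fixed`` are held at the given values; the rest are
    optimized within ``bounds`` (sensible defaults are derived from the
    data).  The fit is deterministic: no random restarts, a fixed initial
    guess policy (b = 1, e = geometric mean of mid-response abscissae).

    ``weights`` (optional, same length as the data) multiply the residuals;
    use e.g. sqrt(n_exposed) for binomial weighting.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise DomainError("xs and ys must be 1-D arrays of equal length")
    if np.any(xs < 0):
        raise DomainError("abscissae must be non-negative")
    fixed = dict(fixed or {})
    unknown = set(fixed) - set(PARAM_NAMES)
    if unknown:
        raise DomainError(f"unknown fixed parameters: {sorted(unknown)}")
    free = [n for n in PARAM_NAMES if n not in fixed]
    if not free:
        raise DomainError("at least one parameter must be free")
    if np.allclose(ys, ys[0]):
        raise DegenerateDataError("all response values identical; nothing to fit")
    if len(free) >= 2 and np.unique(xs[~np.isclose(ys, ys[0])]).size < 2:
        raise DegenerateDataError("need >=2 distinct informative points")
    w = np.ones_like(ys) if weights is None else np.asarray(weights, dtype=float)

    pos = xs[xs > 0]
    if pos.size == 0:
        raise DegenerateDataError("no positive abscissae")
    c0 = fixed.get("c", float(min(ys.min(), 0.0)))
    d0 = fixed.get("d", float(min(max(ys.max(), c0 + 1e-6), 1.0)))
    default_bounds = {
        "b": (0.05, 50.0),
        "c": (min(0.0, c0), max(d0, 0.0)),
        "d": (0.0, 1.0),
        "e": (pos.min() / 100.0, pos.max() * 100.0),
    }
    if bounds:
        default_bounds.update(bounds)

    guess = {
        "b": 1.0,
        "c": c0,
        "d": d0,
        "e": _default_initial_e(xs, ys, c0, d0),
    }
    if initial_guess:
        guess.update(initial_guess)

    lo = np.array([default_bounds[n][0] for n in free])
    hi = np.array([default_bounds[n][1] for n in free])
    x0 = np.clip(np.array([guess[n] for n in free]), lo, hi)

    def residuals(theta: np.ndarray) -> np.ndarray:
        kw = dict(fixed)
        kw.update(zip(free, theta))
        # bypass WeibullParams validation inside the optimizer loop: bounds
        # already keep b, e positive and c <= d is not enforced mid-search
        b, c, d, e = kw["b"], kw["c"], kw["d"], kw["e"]
        with np.errstate(divide="ignore", over="ignore"):
            inner = np.exp(b * (np.log(xs) - np.log(e)))
        pred = np.where(xs == 0.0, d, c + (d - c) * np.exp(-inner))
        return w * (pred - ys)

    sol = least_squares(
        residuals, x0, bounds=(lo, hi), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=20000,
    )
    values = dict(fixed)
    values.update(zip(free, sol.x))
    params = WeibullParams(**{n: float(values[n]) for n in PARAM_NAMES})
    rss = float(np.sum(residuals(sol.x) ** 2))
    return FitResult(
        params=params,
        fixed_mask=fixed,
        residual_sum_of_squares=rss,
        n_points=int(xs.size),
        # an exact (numerically zero-residual) solution can exhaust max_nfev
        # wandering a flat cost region without tripping xtol/ftol/gtol
        converged=bool(sol.success or rss <= 1e-16 * xs.size),
    )
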