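"""Monotonic log-logistic baseline fit and its LC_x values.

This is the conventional concentration-response model used for comparison:
``survival(x) = d / (1 + exp(b * (log(x) - log(e))))`` with the lower limit
fixed at 0.  It is fitted to ALL observations (no SyS correction, no
smoothing points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateDataError, DomainError, EffectNotReachedError, NonConvergenceError
from .pipeline import ConcentrationResponseData

__all__ = ["LogLogisticParams", "loglogistic_evaluate", "fit_loglogistic", "lc_traditional"]


@dataclass(frozen=True)
class LogLogisticParams:
    """Two/three-parameter log-logistic with lower limit 0.

    b : slope (> 0 for decreasing survival); d : upper limit in (0, 1];
    e : inflection point = LC_50 under the relative definition.
    """

    b: float
    d: float
    e: float

    def __post_init__(self) -> None:
        if not self.e > 0:
            raise DomainError(f"inflection e must be > 0, got {self.e}")
        if not 0.0 < self.d <= 1.0:
            raise DomainError(f"upper limit d must lie in (0, 1], got {self.d}")


def loglogistic_evaluate(params: LogLogisticParams, x):
    """Evaluate the log-logistic survival curve; x = 0 returns d."""
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise DomainError("concentration must be non-negative")
    with np.errstate(divide="ignore", over="ignore"):
        t = np.exp(params.b * (np.log(x_arr) - np.log(params.e)))
    out = np.where(x_arr == 0.0, params.d, params.d / (1.0 + t))
    return out.item() if np.isscalar(x) or x_arr.ndim == 0 else out


def fit_loglogistic(data: ConcentrationResponseData,
                    fix_d: float | None = None) -> LogLogisticParams:
    """Least-squares log-logistic fit to all observations.

    ``d`` is estimated (capped at 1) unless ``fix_d`` pins it.
    """
    xs, ys = data.concentration, data.survival
    if np.unique(xs).size < 3:
        raise DegenerateDataError("log-logistic fit needs >=3 distinct concentrations")
    if np.allclose(ys, ys[0]):
        raise DegenerateDataError("all survival values identical")
    pos = xs[xs > 0]

    if fix_d is None:
        free = ("b", "d", "e")
        x0 = [1.0, min(float(ys.max()), 1.0), float(np.exp(np.mean(np.log(pos))))]
        lo = [0.05, 1e-6, pos.min() / 100.0]
        hi = [50.0, 1.0, pos.max() * 100.0]
    else:
        free = ("b", "e")
        x0 = [1.0, float(np.exp(np.mean(np.log(pos))))]
        lo = [0.05, pos.min() / 100.0]
        hi = [50.0, pos.max() * 100.0]

    def residuals(theta):
        kw = dict(zip(free, theta))
        d = kw.get("d", fix_d)
        with np.errstate(divide="ignore", over="ignore"):
            t = np.exp(kw["b"] * (np.log(xs) - np.log(kw["e"])))
        pred = np.where(xs == 0.0, d, d / (1.0 + t))
        return pred - ys

    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=10000)
    if not sol.success:
        raise NonConvergenceError("log-logistic fit did not converge")
    kw = dict(zip(free, sol.x))
    return LogLogisticParams(b=float(kw["b"]), d=float(kw.get("d", fix_d)), e=float(kw["e"]))


def lc_traditional(params: LogLogisticParams, x: float,
                   definition: str = "relative") -> float:
    """Closed-form LC_x of the log-logistic curve.

    relative: survival falls to d*(1 - x/100); absolute: survival = 1 - x/100.
    """
    if not 0.0 < x < 100.0:
        raise DomainError(f"effect percent must lie in (0, 100), got {x}")
    alpha = x / 100.0
    if definition == "relative":
        ratio = alpha / (1.0 - alpha)
    elif definition == "absolute":
        target = 1.0 - alpha
        if target >= params.d:
            raise EffectNotReachedError(
                f"absolute survival target {target:g} is above the upper limit d={params.d:g}")
        ratio = params.d / target - 1.0
    else:
        raise DomainError(f"unknown LC definition {definition!r}")
    return float(params.e * np.exp(np.log(ratio) / params.b))


def rss(params: LogLogisticParams, data: ConcentrationResponseData) -> float:
    """Residual sum of squares of the fitted curve against observed survival."""
    pred = loglogistic_evaluate(params, data.concentration)
    return float(np.sum((np.asarray(pred) - data.survival) ** 2))
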