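"""Tri-phasic concentration-response fitting with system stress (SyS).

The fitting procedure decomposes observed mortality into three additive
general-stress components:

* toxicant stress ``S_Tox`` — a monotone Weibull curve of concentration,
  anchored by the control and by observations at and above the hormesis
  concentration (where no SyS-related mortality is assumed);
* system stress ``S_SyS`` — internal stress present at zero/low toxicant
  stress and suppressed by increasing toxicant stress, modelled as a second
  Weibull curve of ``S_Tox``;
* environmental stress ``S_Env`` — a constant offset estimated at the
  hormesis concentration when a parallel experiment with an environmental
  stressor is supplied.

Summing the components and converting the total back through the beta
capacity law yields the tri-phasic predicted survival curve, from which
low-effect concentrations (LC_x) and the hormetic range are read off.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import sam
from .errors import (
    DegenerateDataError,
    DesignMismatchError,
    DomainError,
    EffectNotReachedError,
    InsufficientDesignError,
    NonConvergenceError,
    ValidationError,
)
from .sam import StressCapacityDistribution
from .weibull import FitResult, WeibullParams, weibull_evaluate, weibull_fit, weibull_inverse

logger = logging.getLogger(__name__)

__all__ = [
    "ConcentrationResponseData",
    "StressDecomposition",
    "PipelineConfig",
    "EcxSysFit",
    "identify_hormesis",
    "fit_toxicant_curve",
    "estimate_sys",
    "fit_sys_curve",
    "sys_ec",
    "estimate_env_stress",
    "predict_survival",
    "compute_lc",
    "hormetic_range",
    "fit_full",
]

#: SyS-extinction level used to anchor environmental-stress estimation and
#: the upper end of the hormetic range: the toxicant stress at which SyS is
#: reduced by 99% is taken as "SyS approaches zero".
SYS_EXTINCTION_LEVEL = 99.0


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcentrationResponseData:
    """Aggregated survival counts for one experiment on one observation day.

    One record per concentration; must include a control (concentration 0).
    """

    concentration: np.ndarray
    n_exposed: np.ndarray
    n_surviving: np.ndarray
    day: int | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentration, dtype=float)
        n_exp = np.asarray(self.n_exposed, dtype=int)
        n_sur = np.asarray(self.n_surviving, dtype=int)
        if not (conc.shape == n_exp.shape == n_sur.shape) or conc.ndim != 1:
            raise ValidationError("concentration, n_exposed, n_surviving must be equal-length 1-D")
        if np.any(conc < 0):
            raise ValidationError("concentrations must be non-negative")
        if np.unique(conc).size != conc.size:
            raise ValidationError("concentrations must be unique within a day")
        if np.any(n_exp <= 0):
            raise ValidationError("n_exposed must be positive")
        if np.any(n_sur < 0) or np.any(n_sur > n_exp):
            raise ValidationError("need 0 <= n_surviving <= n_exposed (survival cannot exceed 100%)")
        if not np.any(conc == 0):
            raise ValidationError("data must contain a control (concentration 0)")
        order = np.argsort(conc)
        object.__setattr__(self, "concentration", conc[order])
        object.__setattr__(self, "n_exposed", n_exp[order])
        object.__setattr__(self, "n_surviving", n_sur[order])

    @property
    def survival(self) -> np.ndarray:
        return self.n_surviving / self.n_exposed

    @property
    def control_survival(self) -> float:
        return float(self.survival[self.concentration == 0][0])

    def survival_at(self, concentration: float) -> float:
        idx = np.flatnonzero(np.isclose(self.concentration, concentration))
        if idx.size == 0:
            raise DesignMismatchError(f"concentration {concentration} not tested")
        return float(self.survival[idx[0]])

    @classmethod
    def from_records(cls, records: Sequence[dict], day: int | None = None,
                     label: str | None = None) -> "ConcentrationResponseData":
        return cls(
            concentration=np.array([r["concentration"] for r in records], dtype=float),
            n_exposed=np.array([r["n_exposed"] for r in records], dtype=int),
            n_surviving=np.array([r["n_surviving"] for r in records], dtype=int),
            day=day,
            label=label,
        )


@dataclass(frozen=True)
class StressDecomposition:
    """Per-concentration stress components on the general-stress scale.

    ``s_sys`` holds the raw (clamped, pre-fit) SyS estimates used to fit the
    SyS curve; ``s_ext = s_env + s_tox`` and ``s_sum = s_sys + s_ext`` are
    stored unclamped.
    """

    concentration: np.ndarray
    s_obs: np.ndarray
    s_tox: np.ndarray
    s_sys: np.ndarray
    s_env: float
    s_ext: np.ndarray
    s_sum: np.ndarray

    def to_dict(self) -> dict:
        return {
            "concentration": self.concentration.tolist(),
            "s_obs": self.s_obs.tolist(),
            "s_tox": self.s_tox.tolist(),
            "s_sys": self.s_sys.tolist(),
            "s_env": self.s_env,
            "s_ext": self.s_ext.tolist(),
            "s_sum": self.s_sum.tolist(),
        }


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the fitting procedure; defaults follow the reference method."""

    p: float = sam.DEFAULT_SHAPE
    q: float = sam.DEFAULT_SHAPE
    hormesis_concentration: float | None = None
    #: what the three smoothing points interpolate toward at the sub-hormetic
    #: concentration: "toxicant" (toxicant-only survival of 1.0, default) or
    #: "observed" (the observed sub-hormetic survival).
    smoothing: str = "toxicant"
    lc_levels: tuple[float, ...] = (5.0, 50.0)
    lc_definition: str = "relative"  # or "absolute"

    def capacity(self) -> StressCapacityDistribution:
        return StressCapacityDistribution(self.p, self.q)


@dataclass
class EcxSysFit:
    """Complete fitted tri-phasic model for one experiment/day."""

    toxicant_curve: WeibullParams
    sys_curve: WeibullParams
    s_env: float
    hormesis_concentration: float
    smoothing_points: list[tuple[float, float]]
    decomposition: StressDecomposition
    capacity: StressCapacityDistribution
    config: PipelineConfig
    toxicant_fit: FitResult | None = None
    sys_fit: FitResult | None = None
    lc: dict[float, float | None] = field(default_factory=dict)
    hormetic_range: tuple[float, float] | None = None
    sys_ec99_stress: float | None = None
    warnings: list[str] = field(default_factory=list)
    converged: bool = True

    def predict_survival(self, concentration):
        return predict_survival(self, concentration)

    @property
    def residual_sum_of_squares(self) -> float:
        """RSS of the predicted tri-phasic curve against observed survival."""
        pred = self.predict_survival(self.decomposition.concentration)
        obs = 1.0 - sam.stress_to_mortality(self.capacity, self.decomposition.s_obs)
        return float(np.sum((np.asarray(pred) - obs) ** 2))


# ---------------------------------------------------------------------------
# step (iii) prerequisite: locating the hormesis concentration
# ---------------------------------------------------------------------------

def identify_hormesis(data: ConcentrationResponseData,
                      override: float | None = None) -> float:
    """Locate the hormesis concentration among the tested concentrations.

    Default rule: among positive concentrations below the steepest survival
    decline, pick the one with maximum observed survival provided it is a
    local maximum (survival exceeds that of the next-lower tested
    concentration).  If no local maximum exists — the monotone "step" case —
    return the largest concentration immediately preceding the greatest drop
    in survival between adjacent tested concentrations.  A user override
    always wins.
    """
    conc = data.concentration
    surv = data.survival
    if override is not None:
        if not np.any(np.isclose(conc, override)):
            raise ValidationError(f"hormesis override {override} is not a tested concentration")
        return float(override)
    if np.count_nonzero(conc > 0) < 3:
        raise InsufficientDesignError(
            "hormesis detection needs >=3 positive tested concentrations"
        )
    drops = surv[:-1] - surv[1:]  # drop between adjacent sorted concentrations
    i_drop = int(np.argmax(drops))  # steepest decline happens into conc[i_drop + 1]
    below = np.flatnonzero((conc > 0) & (conc < conc[i_drop + 1]))
    candidates = [i for i in below if surv[i] > surv[i - 1]]
    if candidates:
        chosen = max(candidates, key=lambda i: (surv[i], conc[i]))
        logger.info("hormesis auto-detected at %g (local survival maximum %.3f)",
                    conc[chosen], surv[chosen])
        return float(conc[chosen])
    # fallback: the concentration just before the steepest drop
    if conc[i_drop] <= 0:
        raise InsufficientDesignError(
            "steepest decline starts at the control; cannot place hormesis"
        )
    logger.info("hormesis fallback ('step' rule) at %g", conc[i_drop])
    return float(conc[i_drop])


# ---------------------------------------------------------------------------
# steps (i)-(ii): monotone toxicant curve with smoothing points
# ---------------------------------------------------------------------------

def _smoothing_points(data: ConcentrationResponseData, hormesis_concentration: float,
                      mode: str) -> list[tuple[float, float]]:
    conc = data.concentration
    below = conc[(conc > 0) & (conc < hormesis_concentration)]
    if below.size == 0:
        logger.warning("no positive sub-hormetic concentration; smoothing points skipped")
        return []
    sub = float(below.max())
    lo, hi = math.log10(sub), math.log10(hormesis_concentration)
    y_hi = data.survival_at(hormesis_concentration)
    y_lo = 1.0 if mode == "toxicant" else data.survival_at(sub)
    pts = []
    for k in (1, 2, 3):
        t = k / 4.0
        pts.append((10 ** (lo + t * (hi - lo)), y_lo + t * (y_hi - y_lo)))
    logger.info("smoothing points (%s mode): %s", mode, pts)
    return pts


def fit_toxicant_curve(data: ConcentrationResponseData, hormesis_concentration: float,
                       smoothing: str = "toxicant",
                       return_details: bool = False):
    """Fit the monotone toxicant-survival Weibull (c = 0, d = 1 fixed).

    The fit set is: the control at toxicant-only survival 1.0 (all control
    mortality is attributed to SyS), every observation at and above the
    hormesis concentration, and three smoothing points placed equally spaced
    in log-concentration strictly between the sub-hormetic and hormesis
    concentrations, interpolating linearly (in log concentration) toward the
    hormesis observation.
    """
    if smoothing not in ("toxicant", "observed"):
        raise DomainError(f"unknown smoothing mode {smoothing!r}")
    conc = data.concentration
    if not np.any(np.isclose(conc, hormesis_concentration)):
        raise ValidationError("hormesis concentration must be a tested concentration")
    if not np.any(conc > hormesis_concentration):
        raise InsufficientDesignError("need at least one concentration above hormesis")

    pts = [(0.0, 1.0)]
    smooth = _smoothing_points(data, hormesis_concentration, smoothing)
    pts.extend(smooth)
    at_or_above = conc >= hormesis_concentration - 1e-12
    pts.extend(zip(conc[at_or_above], data.survival[at_or_above]))
    xs, ys = map(np.array, zip(*pts))
    result = weibull_fit(xs, ys, fixed={"c": 0.0, "d": 1.0})
    if not result.converged:
        raise NonConvergenceError("toxicant-curve fit did not converge")
    if return_details:
        return result, smooth
    return result.params


# ---------------------------------------------------------------------------
# steps (iii), (v), (vi): stress decomposition
# ---------------------------------------------------------------------------

def estimate_sys(data: ConcentrationResponseData, toxicant_curve: WeibullParams,
                 hormesis_concentration: float, s_env: float = 0.0,
                 capacity: StressCapacityDistribution | None = None) -> StressDecomposition:
    """Per-concentration stress decomposition with raw SyS estimates.

    ``S_SyS = S_Obs - S_Ext`` with ``S_Ext = S_Env + S_Tox``; negative
    residuals are clamped to 0 and SyS is forced to 0 at and above the
    hormesis concentration.
    """
    capacity = capacity or StressCapacityDistribution()
    conc = data.concentration
    s_obs = np.array([sam.mortality_to_stress(capacity, 1.0 - s) for s in data.survival])
    tox_survival = np.asarray(weibull_evaluate(toxicant_curve, conc))
    s_tox = np.array([sam.mortality_to_stress(capacity, 1.0 - s) for s in tox_survival])
    s_ext = s_env + s_tox
    raw = s_obs - s_ext
    s_sys = np.maximum(raw, 0.0)
    clamped = np.flatnonzero(raw < -1e-12)
    if clamped.size:
        logger.info("clamped negative SyS at concentrations %s", conc[clamped].tolist())
    s_sys[conc >= hormesis_concentration - 1e-12] = 0.0
    return StressDecomposition(
        concentration=conc,
        s_obs=s_obs,
        s_tox=s_tox,
        s_sys=s_sys,
        s_env=float(s_env),
        s_ext=s_ext,
        s_sum=s_sys + s_ext,
    )


def fit_sys_curve(decomposition: StressDecomposition) -> FitResult:
    """Fit SyS as a Weibull function of toxicant stress (c = 0 fixed).

    The fit uses ``S_Tox`` (not ``S_Ext``) as abscissa: environmental stress
    does not reduce system stress.  ``d`` estimates SyS at zero toxicant
    stress.
    """
    xs, ys = decomposition.s_tox, decomposition.s_sys
    if xs.size < 3:
        raise InsufficientDesignError("SyS fit needs >=3 (s_tox, s_sys) pairs")
    if np.allclose(ys, 0.0):
        raise DegenerateDataError("all SyS estimates are zero; no SyS curve to fit")
    result = weibull_fit(xs, ys, fixed={"c": 0.0})
    if not result.converged:
        raise NonConvergenceError("SyS-curve fit did not converge")
    return result


def sys_ec(sys_curve: WeibullParams, level: float) -> float:
    """Toxicant stress at which SyS is reduced by ``level`` percent of d."""
    if not 0.0 < level < 100.0:
        raise DomainError(f"level must lie in (0, 100), got {level}")
    if not sys_curve.d > 0:
        raise DegenerateDataError("SyS curve has zero height; EC level undefined")
    return float(weibull_inverse(sys_curve, (1.0 - level / 100.0) * sys_curve.d))


def estimate_env_stress(data_env: ConcentrationResponseData,
                        toxicant_curve: WeibullParams,
                        hormesis_concentration: float,
                        capacity: StressCapacityDistribution | None = None) -> float:
    """Environmental stress from the survival gap at the hormesis concentration.

    At hormesis SyS is ~0 (the SyS EC99), so any extra mortality in the
    environmental-stressor experiment relative to the toxicant-only curve is
    attributed to constant environmental stress.
    """
    capacity = capacity or StressCapacityDistribution()
    obs = data_env.survival_at(hormesis_concentration)  # raises on design mismatch
    s_obs = sam.mortality_to_stress(capacity, 1.0 - obs)
    tox_survival = weibull_evaluate(toxicant_curve, hormesis_concentration)
    s_tox = sam.mortality_to_stress(capacity, 1.0 - tox_survival)
    return max(0.0, s_obs - s_tox)


# ---------------------------------------------------------------------------
# steps (iv), (vii): prediction and summaries
# ---------------------------------------------------------------------------

def predict_survival(fit: EcxSysFit, concentration):
    """Predicted survival of the full tri-phasic model at ``concentration``."""
    conc = np.asarray(concentration, dtype=float)
    if np.any(conc < 0):
        raise DomainError("concentration must be non-negative")
    tox_survival = np.asarray(weibull_evaluate(fit.toxicant_curve, conc))
    s_tox = np.asarray(sam.mortality_to_stress(fit.capacity, 1.0 - tox_survival))
    s_sys = np.asarray(weibull_evaluate(fit.sys_curve, s_tox))
    total = s_sys + fit.s_env + s_tox
    out = np.asarray(sam.survival_from_stress(fit.capacity, total))
    if np.isscalar(concentration) or conc.ndim == 0:
        return float(out)
    return out


def compute_lc(fit: EcxSysFit, x: float, definition: str | None = None,
               search_range: tuple[float, float] | None = None,
               grid_points: int = 1200, log_tol: float = 1e-4) -> float:
    """Smallest concentration producing an ``x``-percent lethal effect.

    definition="relative" (default): smallest c > 0 whose predicted survival
    falls below ``(1 - x/100) * predicted_survival(0)``.
    definition="absolute": smallest c > 0 with predicted survival below
    ``1 - x/100``.

    Found by scanning a log-spaced grid for the first crossing, then
    bisecting to ``log_tol`` in log10 units.
    """
    if not 0.0 < x < 100.0:
        raise DomainError(f"effect percent must lie in (0, 100), got {x}")
    definition = definition or fit.config.lc_definition
    if definition not in ("relative", "absolute"):
        raise DomainError(f"unknown LC definition {definition!r}")
    if search_range is None:
        pos = fit.decomposition.concentration[fit.decomposition.concentration > 0]
        search_range = (float(pos.min()) * 1e-6, float(pos.max()) * 1e3)
    lo, hi = search_range
    if definition == "relative":
        target = (1.0 - x / 100.0) * predict_survival(fit, 0.0)
    else:
        target = 1.0 - x / 100.0

    grid = np.logspace(math.log10(lo), math.log10(hi), grid_points)
    surv = predict_survival(fit, grid)
    hit = np.flatnonzero(surv <= target)
    if hit.size == 0:
        raise EffectNotReachedError(
            f"{x}% effect ({definition}) not reached on [{lo:g}, {hi:g}] µg/L",
            search_range=search_range,
        )
    i = int(hit[0])
    if i == 0:
        return float(grid[0])
    a, b = math.log10(grid[i - 1]), math.log10(grid[i])
    while b - a > log_tol:
        mid = 0.5 * (a + b)
        if predict_survival(fit, 10 ** mid) <= target:
            b = mid
        else:
            a = mid
    return float(10 ** b)


def hormetic_range(fit: EcxSysFit) -> tuple[float, float]:
    """Concentration band where SyS falls from 50% to 1% of its height.

    The SyS EC levels live on the toxicant-stress axis; they are mapped back
    to concentration through the toxicant curve.
    """
    if fit.sys_curve.d <= 1e-9:
        raise DegenerateDataError("SyS height ~0; hormetic range undefined")

    def to_concentration(s_tox: float) -> float:
        survival = 1.0 - sam.stress_to_mortality(fit.capacity, s_tox)
        return weibull_inverse(fit.toxicant_curve, survival)

    lower = to_concentration(sys_ec(fit.sys_curve, 50.0))
    upper = to_concentration(sys_ec(fit.sys_curve, SYS_EXTINCTION_LEVEL))
    return (lower, upper)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def fit_full(data: ConcentrationResponseData,
             data_env: ConcentrationResponseData | None = None,
             config: PipelineConfig | None = None) -> EcxSysFit:
    """Run the complete fitting procedure.

    Without ``data_env`` the model is fitted to ``data`` alone (s_env = 0).
    With ``data_env``, the toxicant curve and hormesis concentration come
    from the toxicant-only experiment ``data``, the environmental stress is
    estimated at the hormesis concentration of ``data_env``, and the SyS
    decomposition and all predictions describe the environmental-stress
    experiment.
    """
    config = config or PipelineConfig()
    capacity = config.capacity()
    warnings: list[str] = []

    stage = "identify_hormesis"
    try:
        hormesis = identify_hormesis(data, override=config.hormesis_concentration)

        stage = "fit_toxicant_curve"
        tox_result, smooth = fit_toxicant_curve(
            data, hormesis, smoothing=config.smoothing, return_details=True)
        tox_curve = tox_result.params

        stage = "estimate_env_stress"
        if data_env is not None:
            s_env = estimate_env_stress(data_env, tox_curve, hormesis, capacity)
            target = data_env
        else:
            s_env = 0.0
            target = data

        stage = "estimate_sys"
        decomposition = estimate_sys(target, tox_curve, hormesis, s_env, capacity)

        stage = "fit_sys_curve"
        try:
            sys_result = fit_sys_curve(decomposition)
            sys_curve = sys_result.params
        except DegenerateDataError:
            warnings.append("all SyS estimates zero; SyS curve degenerate (d=0)")
            sys_curve = WeibullParams(b=1.0, c=0.0, d=0.0, e=1.0)
            sys_result = None
    except Exception as err:
        # annotate with the failing stage but preserve the error class so
        # callers can still distinguish validation from convergence problems
        err.args = (f"pipeline failed at stage {stage!r}: {err}",)
        raise

    fit = EcxSysFit(
        toxicant_curve=tox_curve,
        sys_curve=sys_curve,
        s_env=s_env,
        hormesis_concentration=hormesis,
        smoothing_points=smooth,
        decomposition=decomposition,
        capacity=capacity,
        config=config,
        toxicant_fit=tox_result,
        sys_fit=sys_result,
        warnings=warnings,
        converged=True,
    )

    if sys_curve.d > 1e-9:
        fit.sys_ec99_stress = sys_ec(sys_curve, SYS_EXTINCTION_LEVEL)
        try:
            fit.hormetic_range = hormetic_range(fit)
        except DomainError:
            warnings.append("hormetic range endpoints outside toxicant curve image")
    else:
        warnings.append("degenerate SyS: EC levels and hormetic range undefined")

    for level in config.lc_levels:
        try:
            fit.lc[level] = compute_lc(fit, level)
        except EffectNotReachedError as err:
            warnings.append(f"LC_{level:g} not reached: {err}")
            fit.lc[level] = None
    return fit
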