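"""Generative simulator of tri-phasic survival experiments.

The forward model composes the same primitives the fitting pipeline inverts:
a Weibull toxicant-survival curve, a Weibull SyS-versus-toxicant-stress
curve, an optional constant environmental stress, and the beta capacity law
that converts total general stress back to survival.  Observed counts are
binomial draws around the deterministic truth (individually kept animals,
independent deaths), with optional beta-binomial overdispersion for
robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import sam
from .errors import DomainError, ValidationError
from .pipeline import ConcentrationResponseData
from .sam import StressCapacityDistribution
from .weibull import WeibullParams, weibull_evaluate

__all__ = [
    "TrueModel",
    "ExperimentDesign",
    "true_survival",
    "simulate_experiment",
    "reference_model",
    "coarse_design",
    "log_grid_design",
]


@dataclass(frozen=True)
class TrueModel:
    """Ground-truth parameter set for simulation."""

    toxicant_curve: WeibullParams
    sys_curve: WeibullParams
    s_env: float = 0.0
    capacity: StressCapacityDistribution = field(default_factory=StressCapacityDistribution)

    def __post_init__(self) -> None:
        if self.toxicant_curve.c != 0.0 or self.toxicant_curve.d != 1.0:
            raise ValidationError("toxicant curve must have c=0, d=1")
        if self.sys_curve.c != 0.0:
            raise ValidationError("SyS curve must have c=0")
        if self.s_env < 0:
            raise DomainError("s_env must be non-negative")


@dataclass(frozen=True)
class ExperimentDesign:
    """Concentrations, group sizes and RNG seed of a simulated experiment."""

    concentrations: tuple[float, ...]
    n_exposed: tuple[int, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentrations)
        n = self.n_exposed
        if np.isscalar(n):
            n = tuple(int(n) for _ in conc)
        else:
            n = tuple(int(v) for v in n)
        if len(n) != len(conc):
            raise ValidationError("n_exposed must match concentrations in length")
        if len(set(conc)) != len(conc) or len(conc) < 4 or 0.0 not in conc:
            raise ValidationError("need >=4 unique concentrations including the control 0")
        if any(v < 1 for v in n):
            raise ValidationError("n_exposed counts must be >= 1")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "n_exposed", n)


def true_survival(model: TrueModel, concentration):
    """Deterministic survival of the forward model at ``concentration``."""
    conc = np.asarray(concentration, dtype=float)
    tox_survival = np.asarray(weibull_evaluate(model.toxicant_curve, conc))
    s_tox = np.asarray(sam.mortality_to_stress(model.capacity, 1.0 - tox_survival))
    s_sys = np.asarray(weibull_evaluate(model.sys_curve, s_tox))
    out = np.asarray(sam.survival_from_stress(model.capacity, s_sys + model.s_env + s_tox))
    if np.isscalar(concentration) or conc.ndim == 0:
        return float(out)
    return out


def simulate_experiment(model: TrueModel, design: ExperimentDesign,
                        overdispersion: float = 0.0,
                        day: int | None = None,
                        label: str | None = None) -> ConcentrationResponseData:
    """Draw binomial survival counts around the true curve.

    ``overdispersion`` is the beta-binomial intra-class correlation rho in
    [0, 1); 0 gives plain binomial sampling.  Reproducible from the design's
    seed.
    """
    if not 0.0 <= overdispersion < 1.0:
        raise DomainError("overdispersion rho must lie in [0, 1)")
    rng = np.random.default_rng(design.seed)
    conc = np.array(design.concentrations)
    n = np.array(design.n_exposed)
    p = np.clip(true_survival(model, conc), 0.0, 1.0)
    if overdispersion == 0.0:
        surviving = rng.binomial(n, p)
    else:
        rho = overdispersion
        kappa = (1.0 - rho) / rho
        a = np.clip(p * kappa, 1e-12, None)
        b = np.clip((1.0 - p) * kappa, 1e-12, None)
        surviving = rng.binomial(n, rng.beta(a, b))
    return ConcentrationResponseData(
        concentration=conc, n_exposed=n, n_surviving=surviving, day=day, label=label,
    )


def reference_model(s_env: float = 0.0) -> TrueModel:
    """Default tri-phasic truth mirroring the reference experiment's fits."""
    return TrueModel(
        toxicant_curve=WeibullParams(b=1.256, c=0.0, d=1.0, e=2.877),
        sys_curve=WeibullParams(b=3.476, c=0.0, d=0.299, e=0.152),
        s_env=s_env,
    )


def coarse_design(n_exposed: int = 48, seed: int = 0) -> ExperimentDesign:
    """The 4-concentration design of the reference experiments."""
    return ExperimentDesign((0.0, 0.03, 0.3, 3.0), (n_exposed,) * 4, seed=seed)


def log_grid_design(n_exposed: int = 48, seed: int = 0) -> ExperimentDesign:
    """Control plus an 8-point log grid for curve-resolution studies."""
    conc = (0.0, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0)
    return ExperimentDesign(conc, (n_exposed,) * len(conc), seed=seed)
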