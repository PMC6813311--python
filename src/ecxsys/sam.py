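"""Stress arithmetic of the stress addition model (SAM).

Individual tolerance to "general stress" is modelled as a beta(p, q) law on
[0, 1]: an individual dies when the ambient general stress exceeds its
capacity.  Mortality at stress level ``s`` is therefore the beta CDF at
``s``, and the general-stress equivalent of an observed mortality ``m`` is
the beta quantile at ``m``.  Independent stressors combine by plain addition
of their general-stress levels; the sum is only clamped to [0, 1] when it is
converted back to mortality or survival.

The default calibration is ``p = q = 3.2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .errors import DomainError

__all__ = [
    "StressCapacityDistribution",
    "stress_density",
    "stress_to_mortality",
    "mortality_to_stress",
    "survival_from_stress",
    "add_stresses",
]

DEFAULT_SHAPE = 3.2


@dataclass(frozen=True)
class StressCapacityDistribution:
    """Beta(p, q) distribution of individual general-stress capacity.

    Parameters
    ----------
    p, q : float
        Strictly positive shape parameters.  The default ``p = q = 3.2``
        encodes a symmetric capacity distribution.
    """

    p: float = DEFAULT_SHAPE
    q: float = DEFAULT_SHAPE

    def __post_init__(self) -> None:
        if not (self.p > 0 and self.q > 0):
            raise DomainError(
                f"shape parameters must be > 0, got p={self.p}, q={self.q}"
            )


def stress_density(dist: StressCapacityDistribution, s):
    """Probability density of the stress-capacity law at general stress ``s``.

    ``s`` must lie in [0, 1].  Accepts scalars or arrays.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0) or np.any(s_arr > 1):
        raise DomainError(f"general stress must lie in [0, 1], got {s}")
    with np.errstate(divide="ignore"):
        log_pdf = (
            special.xlogy(dist.p - 1.0, s_arr)
            + special.xlog1py(dist.q - 1.0, -s_arr)
            - special.betaln(dist.p, dist.q)
        )
    out = np.exp(log_pdf)
    return out.item() if np.isscalar(s) or s_arr.ndim == 0 else out


def stress_to_mortality(dist: StressCapacityDistribution, s):
    """Mortality fraction caused by general stress ``s``.

    The beta CDF at ``s`` clamped to [0, 1]: 0 for ``s <= 0`` and 1 for
    ``s >= 1``.  Unclamped stress sums greater than 1 are accepted here.
    """
    s_arr = np.clip(np.asarray(s, dtype=float), 0.0, 1.0)
    out = special.betainc(dist.p, dist.q, s_arr)
    return out.item() if np.isscalar(s) or s_arr.ndim == 0 else out


def mortality_to_stress(dist: StressCapacityDistribution, m):
    """General-stress level whose mortality equals ``m`` (beta quantile)."""
    m_arr = np.asarray(m, dtype=float)
    if np.any(m_arr < 0) or np.any(m_arr > 1):
        raise DomainError(f"mortality must lie in [0, 1], got {m}")
    out = special.betaincinv(dist.p, dist.q, m_arr)
    return out.item() if np.isscalar(m) or m_arr.ndim == 0 else out


def survival_from_stress(dist: StressCapacityDistribution, s):
    """Survival fraction under general stress ``s``: ``1 - mortality``."""
    return 1.0 - stress_to_mortality(dist, s)


def add_stresses(stresses) -> float:
    """Sum general-stress levels of independent stressors.

    The sum is returned unclamped; values above 1 simply mean certain death
    once converted through :func:`stress_to_mortality`.
    """
    arr = np.asarray(list(stresses), dtype=float)
    if np.any(arr < 0):
        raise DomainError(f"stress levels must be non-negative, got {list(arr)}")
    return float(arr.sum())
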