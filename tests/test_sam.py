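import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from ecxsys import (
    DomainError,
    StressCapacityDistribution,
    add_stresses,
    mortality_to_stress,
    stress_density,
    stress_to_mortality,
    survival_from_stress,
)


def beta_density_reference(p: float, q: float, s: float) -> float:
    """Independent density oracle via log-gamma (no scipy.special.beta)."""
    log_b = math.lgamma(p) + math.lgamma(q) - math.lgamma(p + q)
    return math.exp((p - 1) * math.log(s) + (q - 1) * math.log(1 - s) - log_b)


class TestStressCapacityDistribution:
    def test_defaults(self, capacity):
        assert capacity.p == capacity.q == 3.2

    @pytest.mark.parametrize("p,q", [(0, 1), (-1, 2), (3, -0.5)])
    def test_invalid_shapes_rejected(self, p, q):
        with pytest.raises(DomainError):
            StressCapacityDistribution(p, q)

    def test_density_integrates_to_one(self, capacity):
        total, _ = integrate.quad(lambda s: stress_density(capacity, s), 0, 1)
        assert total == pytest.approx(1.0, abs=1e-9)


class TestStressDensity:
    def test_symmetric_for_equal_shapes(self, capacity):
        assert stress_density(capacity, 0.3) == pytest.approx(
            stress_density(capacity, 0.7), rel=1e-12)

    def test_matches_independent_log_gamma_evaluation(self, capacity):
        # frozen oracle value at s=0.17: 0.5515996361653...
        assert beta_density_reference(3.2, 3.2, 0.17) == pytest.approx(0.5516, abs=5e-4)
        for s in np.linspace(0.01, 0.99, 25):
            assert stress_density(capacity, s) == pytest.approx(
                beta_density_reference(3.2, 3.2, s), rel=1e-12)

    def test_out_of_domain(self, capacity):
        with pytest.raises(DomainError):
            stress_density(capacity, 1.2)
        with pytest.raises(DomainError):
            stress_density(capacity, -0.1)


class TestConversions:
    def test_boundaries(self, capacity):
        assert stress_to_mortality(capacity, 0.0) == 0.0
        assert stress_to_mortality(capacity, 1.0) == 1.0
        assert stress_to_mortality(capacity, 1.7) == 1.0  # clamped above 1
        assert mortality_to_stress(capacity, 0.0) == 0.0
        assert mortality_to_stress(capacity, 1.0) == 1.0

    def test_symmetric_median(self, capacity):
        assert stress_to_mortality(capacity, 0.5) == pytest.approx(0.5, abs=1e-12)

    # reference conversion table: (stressor level, general stress, mortality)
    @pytest.mark.parametrize("stress,mortality", [
        (0.384, 0.284),  # strong UV
        (0.374, 0.267),  # high temperature
        (0.170, 0.033),  # low food
        (0.034, 0.0002),  # weak UV
    ])
    def test_reference_stress_mortality_pairs(self, capacity, stress, mortality):
        assert mortality_to_stress(capacity, mortality) == pytest.approx(stress, abs=2e-3)
        assert stress_to_mortality(capacity, stress) == pytest.approx(mortality, abs=2e-3)

    def test_survival_complement(self, capacity):
        assert survival_from_stress(capacity, 0.374) == pytest.approx(0.733, abs=2e-3)
        assert survival_from_stress(capacity, 0.0) == 1.0
        assert survival_from_stress(capacity, 1.0) == 0.0
        assert survival_from_stress(capacity, 2.5) == 0.0

    def test_cdf_matches_quadrature_of_density(self, capacity):
        for s in np.linspace(0.02, 0.98, 20):
            ref, _ = integrate.quad(lambda t: stress_density(capacity, t), 0, s,
                                    epsabs=1e-12, epsrel=1e-12)
            assert stress_to_mortality(capacity, s) == pytest.approx(ref, abs=1e-8)

    def test_monotonicity(self, capacity):
        grid = np.linspace(0, 1, 101)
        m = np.array([stress_to_mortality(capacity, s) for s in grid])
        assert np.all(np.diff(m) >= 0)
        s = np.array([mortality_to_stress(capacity, v) for v in grid])
        assert np.all(np.diff(s) >= 0)

    def test_mortality_out_of_domain(self, capacity):
        with pytest.raises(DomainError):
            mortality_to_stress(capacity, 1.3)
        with pytest.raises(DomainError):
            mortality_to_stress(capacity, -0.01)

    def test_asymmetric_shapes_still_invert(self):
        dist = StressCapacityDistribution(2.0, 5.0)
        for m in (0.1, 0.5, 0.9):
            s = mortality_to_stress(dist, m)
            assert stress_to_mortality(dist, s) == pytest.approx(m, abs=1e-10)


# near s=1 the CDF saturates to 1.0 in double precision ((1-s)^q underflows
# relative to 1), so the round trip is only testable away from the endpoints
@settings(max_examples=200, deadline=None)
@given(st.floats(min_value=1e-3, max_value=1 - 1e-3))
def test_roundtrip_stress_mortality(s):
    dist = StressCapacityDistribution()
    assert mortality_to_stress(dist, stress_to_mortality(dist, s)) == pytest.approx(s, abs=1e-8)


@settings(max_examples=200, deadline=None)
@given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
def test_symmetry_of_quantiles(m):
    dist = StressCapacityDistribution()
    assert mortality_to_stress(dist, m) + mortality_to_stress(dist, 1 - m) == pytest.approx(
        1.0, abs=1e-8)


class TestAddStresses:
    def test_arithmetic_sum(self):
        assert add_stresses([0.2, 0.3]) == pytest.approx(0.5)

    def test_sum_above_one_kept_unclamped_until_conversion(self, capacity):
        total = add_stresses([0.7, 0.6])
        assert total == pytest.approx(1.3)
        assert survival_from_stress(capacity, total) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            add_stresses([0.2, -0.1])

    def test_combined_mortality_dominates_components(self, capacity):
        grid = np.arange(0.05, 0.51, 0.05)
        for s1 in grid:
            for s2 in grid:
                combined = stress_to_mortality(capacity, add_stresses([s1, s2]))
                assert combined >= max(stress_to_mortality(capacity, s1),
                                       stress_to_mortality(capacity, s2)) - 1e-12
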