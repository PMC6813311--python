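import numpy as np
import pytest

from ecxsys import (
    ConcentrationResponseData,
    EcxSysFit,
    PipelineConfig,
    StressCapacityDistribution,
    estimate_sys,
    reference_model,
)


@pytest.fixture(scope="session")
def capacity() -> StressCapacityDistribution:
    return StressCapacityDistribution()


@pytest.fixture(scope="session")
def ref_model():
    """Tri-phasic truth with the reference parameter values."""
    return reference_model()


def make_data(survival: dict[float, float], n: int = 1000) -> ConcentrationResponseData:
    """Build an aggregated dataset from a {concentration: survival} mapping."""
    conc = np.array(sorted(survival))
    return ConcentrationResponseData(
        concentration=conc,
        n_exposed=np.full(conc.size, n),
        n_surviving=np.round(np.array([survival[c] for c in conc]) * n).astype(int),
    )


def make_true_fit(model, concentrations=(0.0, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0),
                  hormesis=0.3) -> EcxSysFit:
    """An EcxSysFit assembled directly from true parameters (no fitting)."""
    from ecxsys import true_survival

    conc = np.array(concentrations)
    n = 10 ** 6
    data = ConcentrationResponseData(
        concentration=conc,
        n_exposed=np.full(conc.size, n),
        n_surviving=np.round(np.clip(np.asarray(true_survival(model, conc)), 0, 1) * n).astype(int),
    )
    decomposition = estimate_sys(data, model.toxicant_curve, hormesis,
                                 s_env=model.s_env, capacity=model.capacity)
    return EcxSysFit(
        toxicant_curve=model.toxicant_curve,
        sys_curve=model.sys_curve,
        s_env=model.s_env,
        hormesis_concentration=hormesis,
        smoothing_points=[],
        decomposition=decomposition,
        capacity=model.capacity,
        config=PipelineConfig(),
    )
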