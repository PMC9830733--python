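import numpy as np
import pytest

from ctvent import PhantomSpec, generate_patient
from ctvent.phantom import GaussianBump, VentilationPattern


def bumpy_pattern() -> VentilationPattern:
    """Ventilation pattern with localized bumps: spatially heterogeneous,
    no large tie blocks, genuinely nonlinear (finite differences are not
    exact), used wherever distinct per-voxel values matter."""
    return VentilationPattern(
        base_expansion=0.05,
        expansion_gradient=(1e-4, 5e-5, 3e-4),
        bumps=(
            GaussianBump((-18.0, 0.0, 30.0), 0.08, 25.0),
            GaussianBump((18.0, 5.0, -40.0), 0.06, 30.0),
            GaussianBump((-18.0, -4.0, -20.0), -0.04, 20.0),
        ),
    )


@pytest.fixture(scope="session")
def default_patient():
    return generate_patient(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def bumpy_patient():
    """Patient with heterogeneous, tie-free ventilation (noiseless images)."""
    spec = PhantomSpec(
        ventilation_pattern=bumpy_pattern(), noise_sigma_hu=0.0, seed=7
    )
    return generate_patient(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_study():
    """A seeded two-arm phantom study: 8 benefit patients and 9 non-benefit
    patients run through the full analysis pipeline (ground-truth fields,
    6 strategies each)."""
    from ctvent import PipelineConfig, run_pipeline

    benefit = run_pipeline(PipelineConfig(n_patients=8, scenario="benefit", seed=1))
    non_benefit = run_pipeline(
        PipelineConfig(n_patients=9, scenario="non_benefit", seed=1)
    )
    return {"benefit": benefit, "non_benefit": non_benefit}
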