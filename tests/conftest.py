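import numpy as np
import pytest

from phenolink import SensorModel, StudyConfig, WellGeometry, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_study_config(**overrides) -> StudyConfig:
    """A reduced study for fast end-to-end tests: short traces, same design."""
    defaults = dict(
        trace_duration_min=25.0,
        trace_dt_min=1.0,
        sensor=SensorModel(noise_sd=0.01),
        geometry=WellGeometry(),
    )
    defaults.update(overrides)
    return StudyConfig(**defaults)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """A full synthetic study written to disk once per session."""
    out = tmp_path_factory.mktemp("study")
    manifest, traces, expression = generate_study(
        small_study_config(), seed=11, out_dir=out
    )
    return out, manifest, traces, expression
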