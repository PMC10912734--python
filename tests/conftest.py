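import pytest

from nephromorph.pipeline import PipelineConfig, run_pipeline
from nephromorph.synthetic import SyntheticParams, fast_params, generate_case, generate_cohort

#: Very small field for cheap unit tests: 320×320 μm at 2 μm/px.
TINY = dict(
    field_width_um=320.0,
    field_height_um=320.0,
    pixel_size_um=2.0,
    n_glomeruli=1,
    n_arteries=1,
    glomerulus_radius_um=60.0,
)


def tiny_params(**overrides) -> SyntheticParams:
    kw = dict(TINY)
    kw.update(overrides)
    return SyntheticParams(**kw)


@pytest.fixture
def mid_case():
    """One mid-severity case on the reduced 600 μm field."""
    return generate_case(fast_params(chronicity=0.4, acuity=0.4, seed=5))


@pytest.fixture(scope="session")
def continuous_cohort():
    """200 cases with (chronicity, acuity) iid uniform — parameter-recovery bed."""
    return generate_cohort(200, design="continuous", seed=7, base_params=fast_params())


@pytest.fixture(scope="session")
def continuous_report(continuous_cohort):
    return run_pipeline(continuous_cohort, PipelineConfig(sampling="none", k=4, seed=0))


@pytest.fixture(scope="session")
def archetype_cohort():
    """160 cases planted around the four phenotype archetypes."""
    return generate_cohort(160, design="archetypes", seed=11, base_params=fast_params())


@pytest.fixture(scope="session")
def archetype_report(archetype_cohort):
    return run_pipeline(archetype_cohort, PipelineConfig(sampling="none", k=None, seed=0))
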