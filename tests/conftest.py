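import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def msm_profiles():
    """The seven measured M. smegmatis cell profiles."""
    from structome import load_msmegmatis_profiles

    return load_msmegmatis_profiles()


@pytest.fixture(scope="session")
def mtb_summaries():
    from structome import species_summary_map

    return species_summary_map("M_tuberculosis")


@pytest.fixture
def default_model():
    from structome import SpherocylinderModel

    return SpherocylinderModel()
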