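import pytest
from hypothesis import HealthCheck, settings

from blindtrial import run_analysis
from blindtrial.reconstruction import build_study_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_df():
    """Reconstructed respondent-level dataset of the 24-person study."""
    return build_study_fixture()


@pytest.fixture(scope="session")
def study_report(study_df):
    """Full pipeline report on the packaged study fixture."""
    return run_analysis(study_df, seed=1)
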