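import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

from grazefoot.pipeline import build_baseline_bundle, run_footprint  # noqa: E402


@pytest.fixture(scope="session")
def baseline_bundle():
    return build_baseline_bundle(seed=1)


@pytest.fixture(scope="session")
def baseline_run_rcp26(baseline_bundle):
    return run_footprint(baseline_bundle, "rcp26")


@pytest.fixture(scope="session")
def baseline_run_rcp85(baseline_bundle):
    return run_footprint(baseline_bundle, "rcp85")
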