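import pytest

from cnvreclass.acmg import load_rubric
from cnvreclass.reanalysis import reanalyze, triage
from cnvreclass.synthetic import build_fixture


@pytest.fixture(scope="session")
def rubric():
    return load_rubric()


@pytest.fixture(scope="session")
def fixture_bundle():
    return build_fixture()


@pytest.fixture(scope="session")
def fixture_results(fixture_bundle, rubric):
    """Curated reanalysis of the packaged fixture against the current era."""
    fx = fixture_bundle
    return reanalyze(fx.cohort, fx.snapshot_current, fx.manual_evidence, rubric)


@pytest.fixture(scope="session")
def fixture_triage(fixture_bundle, rubric):
    fx = fixture_bundle
    return triage(fx.cohort, fx.snapshot_current, rubric)
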