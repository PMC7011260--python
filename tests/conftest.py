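import pytest
from hypothesis import HealthCheck, settings

from metacred import assoc_io

settings.register_profile(
    "default-seeded",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default-seeded")


@pytest.fixture(scope="session")
def table1():
    return assoc_io.load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return assoc_io.load_fixture("table2")


@pytest.fixture(scope="session")
def table6():
    return assoc_io.load_fixture("table6")


@pytest.fixture
def make_record():
    """Factory for valid association records with overridable fields."""

    def _make(**overrides):
        base = dict(
            author="Doe J", year=2018, gene="GENE1", variant="rs1",
            comparison="A vs. G", odds_ratio=1.25, ci_lower=1.10,
            ci_upper=1.42, p_value=0.001, study_type="observational",
            ethnicity="Overall", n_cases=1000, n_controls=1000,
        )
        base.update(overrides)
        return assoc_io.MetaAnalysisRecord(**base)

    return _make
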