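import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_proteome():
    """Planted proteome: 5 set-A, 2 set-B, 10 set-C proteins."""
    from famsurvey.synthetic import gen_proteome

    return gen_proteome(5, 2, 10, seed=11)


@pytest.fixture(scope="session")
def element_table():
    from famsurvey.regulatory import load_element_table

    return load_element_table()


@pytest.fixture(scope="session")
def planted_genome():
    from famsurvey.synthetic import gen_genome

    return gen_genome(seed=7)


@pytest.fixture(scope="session")
def expression_bundle():
    from famsurvey.synthetic import gen_expression_qpcr

    return gen_expression_qpcr(seed=3)
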