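import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_genome():
    """The shipped M. kuntee 37-gene reference feature table (no sequence)."""
    from mitochar.genome_io import reference_feature_table

    return reference_feature_table()


@pytest.fixture(scope="session")
def synthetic_genome():
    from mitochar.synthetic import GenomeSpec, make_genome

    return make_genome(GenomeSpec(seed=1))


@pytest.fixture(scope="session")
def study_set():
    """Default-condition study set: 14 ingroup + 3 outgroup mitogenomes
    evolved on a known two-clade tree."""
    from mitochar.synthetic import make_study_set

    return make_study_set(seed=3)
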