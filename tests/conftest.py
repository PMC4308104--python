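import pytest
from hypothesis import HealthCheck, settings

from pyrostar import (
    AlleleModel,
    RatioBinTable,
    SampleInput,
    SNPQuantCall,
    expected_variant_fraction,
    parse_diplotype_string,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    return AlleleModel.default()


@pytest.fixture(scope="session")
def bins():
    return RatioBinTable.default()


@pytest.fixture(scope="session")
def noiseless_sample(model):
    """Factory: exact forward-model sample sheet for a genotype string."""

    def make(genotype: str, total_copies=None, sample_id="s1") -> SampleInput:
        config = parse_diplotype_string(genotype, model)
        calls = []
        for snp_id in model.panel:
            frac = expected_variant_fraction(config, snp_id, model)
            calls.append(SNPQuantCall(snp_id, 100.0 * (1 - frac), 100.0 * frac))
        total = total_copies if total_copies is not None else config.total_copies
        return SampleInput(sample_id, tuple(calls), total_copies=total)

    return make
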