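import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20130207)


@pytest.fixture(scope="session")
def balance_vcf(tmp_path_factory):
    """Synthetic VCF with known heterozygote allele balance 0.483."""
    from poolsim.allele_balance import generate_vcf_fixture

    path = tmp_path_factory.mktemp("vcf") / "balance.vcf"
    info = generate_vcf_fixture(
        n_samples=4, n_sites=2500, true_balance=0.483,
        depth_mean=60.0, seed=42, out_path=path,
    )
    return info
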