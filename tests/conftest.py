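import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

from edscan.variant_qc import VariantSite


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


def make_site(chrom="Chr1", pos=100, high=(10, 10), low=(10, 10), ref="A", alt="G"):
    return VariantSite(
        chromosome=chrom,
        position=pos,
        ref_allele=ref,
        alt_allele=alt,
        depths={"HIGH": high, "LOW": low},
    )


@pytest.fixture
def site_factory():
    return make_site
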