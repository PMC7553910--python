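import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from finnprs import SnpPanel, SnpRecord, load_default_panel

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def panel55() -> SnpPanel:
    """The packaged 55-locus synthetic demonstration panel."""
    return load_default_panel()


def make_snp(rsid="rs1", eaf=0.3, or_=1.2, pvalue=1e-9, chrom="1", pos=1000,
             ea="A", oa="G", fdr_q=None) -> SnpRecord:
    return SnpRecord(rsid, chrom, pos, ea, oa, eaf, or_, pvalue, fdr_q)


@pytest.fixture
def tiny_panel() -> SnpPanel:
    """Two loci with hand-checkable weights: beta = (ln 1.2, ln 0.9)."""
    return SnpPanel.from_records(
        [make_snp("rs1", eaf=0.3, or_=1.2), make_snp("rs2", eaf=0.4, or_=0.9)]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20201013)
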