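import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cnvpd.models import CnvCall, CnvType

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_call(
    individual="I1",
    chrom="1",
    start=0,
    end=10_000,
    cnv_type=CnvType.DELETION,
    rd=0.5,
    pvalue=1e-6,
    q0=0.1,
):
    return CnvCall(
        individual_id=individual,
        chrom=chrom,
        start=start,
        end=end,
        cnv_type=cnv_type,
        normalized_rd=rd,
        pvalue=pvalue,
        q0=q0,
    )


@pytest.fixture
def block_presence():
    """Two groups of 10 individuals with disjoint CNVR sets plus 5% noise:
    a presence matrix whose two blocks should cluster with full support."""
    rng = np.random.default_rng(0)
    n_per, m_per = 10, 50
    block = np.zeros((2 * n_per, 2 * m_per))
    block[:n_per, :m_per] = 1
    block[n_per:, m_per:] = 1
    noise = rng.random(block.shape) < 0.05
    data = np.abs(block - noise)
    labels = [f"A{i:02d}" for i in range(n_per)] + [f"B{i:02d}" for i in range(n_per)]
    return data, labels
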