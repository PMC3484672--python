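import numpy as np
import pytest

from wormko.seqmodel import Amplicon, GeneModel


def bare_amplicon(seq: str, amp_id: str = "amp") -> Amplicon:
    """Amplicon wrapper with trivial primer anchors, for tiny examples."""
    return Amplicon(
        id=amp_id, seq=seq, ext_left=0, int_left=0,
        int_right=len(seq), ext_right=len(seq),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_exon_gene():
    return GeneModel(
        gene_id="g1", chrom="chrI", strand="+", exons=((0, 100), (200, 300))
    )
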