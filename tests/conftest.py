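import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ibdbench import GeneticMap, HapPair, HaplotypeId, segment_from_bp

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def umap():
    """Uniform 1 cM/Mb map over 100 Mb: cM values equal Mb values."""
    return GeneticMap.uniform(100_000_000)


def make_pair(tag: str = "p") -> HapPair:
    return HapPair(HaplotypeId(f"{tag}_a", 0), HaplotypeId(f"{tag}_b", 0))


def cm_segment(gmap: GeneticMap, start_cm: float, end_cm: float, pair=None, chrom="1"):
    """Segment at exact cM bounds on a uniform map (1 cM == 1 Mb)."""
    pair = pair or make_pair()
    return segment_from_bp(
        pair, chrom, int(round(start_cm * 1e6)), int(round(end_cm * 1e6)), gmap
    )


@pytest.fixture
def pair():
    return make_pair()
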