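import pytest

from pericore import GenomicInterval, ChromosomeArm, design_all
from pericore.simulate import SimConfig, generate_genome


@pytest.fixture(scope="session")
def sim_tracks():
    return generate_genome(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_design(sim_tracks):
    return design_all(sim_tracks)


@pytest.fixture(scope="session")
def sim_junctions(sim_design):
    return sim_design[0]


@pytest.fixture(scope="session")
def sim_panels(sim_design):
    return sim_design[1]


def make_arm(chrom: str, arm: str, length: int = 200_000_000, mid: int | None = None):
    """A bare chromosome arm for constructing hand-written cases."""
    mid = length // 2 if mid is None else mid
    if arm == "p":
        return ChromosomeArm(chrom, "p", GenomicInterval(chrom, 0, mid))
    return ChromosomeArm(chrom, "q", GenomicInterval(chrom, mid, length))


@pytest.fixture
def arm4p():
    # hg19-like chromosome 4 short arm; centromere boundary ~50.4 Mb
    return make_arm("chr4", "p", length=191_154_276, mid=50_400_000)


@pytest.fixture
def arm11p():
    return make_arm("chr11", "p", length=135_006_516, mid=53_700_000)


@pytest.fixture
def arm22q():
    return make_arm("chr22", "q", length=51_304_566, mid=14_700_000)
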