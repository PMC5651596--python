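import numpy as np
import pytest

from recvalley import GeneticMap, GenomeAssembly, GenomicInterval, Link, LinkType
from recvalley.simulate import make_scenario


@pytest.fixture()
def toy_map() -> GeneticMap:
    """Three markers: 1000 -> 0.0 cM, 2000 -> 0.01, 4000 -> 0.05."""
    return GeneticMap(
        {"chr1": np.array([1000, 2000, 4000])},
        {"chr1": np.array([0.0, 0.01, 0.05])},
    )


@pytest.fixture()
def small_assembly() -> GenomeAssembly:
    return GenomeAssembly((("chr1", 1_000_000), ("chr2", 500_000)))


@pytest.fixture(scope="session")
def toy_scenario():
    return make_scenario("toy", 3)


def point_link(chrom: str, pa: int, pb: int, score: float = 1e-6, target=None) -> Link:
    return Link(
        GenomicInterval(chrom, pa, pa + 1),
        GenomicInterval(chrom, pb, pb + 1),
        link_type=LinkType.eQTL,
        score=score,
        target_id=target,
    )


@pytest.fixture()
def make_point_link():
    return point_link
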