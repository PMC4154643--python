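import numpy as np
import pytest

from meirec.marker_map import Marker, MarkerMap, rosy_marker_map


@pytest.fixture(scope="session")
def rosy_map() -> MarkerMap:
    return rosy_marker_map()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def snp(pos: int, a: str = "A", b: str = "G") -> Marker:
    return Marker(pos, "snp", 1, a, b)


@pytest.fixture()
def sparse_map() -> MarkerMap:
    """Ten evenly spaced SNPs, selection sites inside the span."""
    markers = tuple(snp(i * 500, "A", "G") for i in range(10))
    return MarkerMap(markers, selection_sites=(1000, 3500), locus_bounds=(-200, 4700))


def pair_map(distance: int) -> MarkerMap:
    """Two target markers ``distance`` apart plus distant flanking markers."""
    markers = (
        snp(0, "A", "G"),
        snp(1000, "T", "C"),
        snp(1000 + distance, "G", "A"),
        snp(2500 + distance, "C", "T"),
    )
    return MarkerMap(markers, selection_sites=(-468, 2300), locus_bounds=(-600, 2700 + distance))
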