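import numpy as np
import pytest

from popsweep import (
    GenomeLayout,
    PopulationMap,
    VariantTable,
)


@pytest.fixture
def layout() -> GenomeLayout:
    return GenomeLayout(("1", "2"), (1_000_000, 500_000))


@pytest.fixture
def small_vt() -> VariantTable:
    """Three samples, four hand-written SNVs on one chromosome."""
    chrom = np.asarray(["1"] * 4, dtype=object)
    pos = np.asarray([100, 200, 300, 400], dtype=np.int64)
    ref = np.asarray(list("ACGT"), dtype=object)
    alt = np.asarray(list("GTAC"), dtype=object)
    gt = np.asarray(
        [
            [0, 1, 2, -1],
            [1, 1, 0, 2],
            [2, 0, 0, 1],
        ],
        dtype=np.int8,
    )
    return VariantTable(chrom, pos, ref, alt, ("s1", "s2", "s3"), gt)


@pytest.fixture
def three_pop_map() -> PopulationMap:
    return PopulationMap(
        {"s1": "MS", "s2": "DU", "s3": "TB"}, ("MS", "DU", "TB"), focal="MS"
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
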