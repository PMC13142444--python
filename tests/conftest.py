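import numpy as np
import pytest
import scipy.sparse as sp

from scads.io_formats import CellRegionMatrix, GenomicRegion


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_regions(J, chrom="1", width=500, pitch=2000, gc=None):
    if gc is None:
        gc = np.linspace(0.35, 0.65, J)
    return [
        GenomicRegion(chrom, i * pitch, i * pitch + width, gc=float(gc[i]))
        for i in range(J)
    ]


@pytest.fixture
def small_matrix(rng):
    """5 cells x 8 regions with strictly positive depths."""
    counts = rng.poisson(3.0, size=(5, 8))
    counts[:, 0] += 1  # guarantee nonzero depth per cell
    return CellRegionMatrix(
        sp.csr_matrix(counts),
        barcodes=[f"bc{i}" for i in range(5)],
        regions=make_regions(8),
    )
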