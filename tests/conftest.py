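import numpy as np
import pytest

from tfclust.genomic_io import GenomicInterval, TfbsRecord


def make_site(pos: int, tf: str = "TFA", cell: str = "cellX", width: int = 10) -> TfbsRecord:
    """A TFBS record whose interval midpoint is exactly ``pos``."""
    half = width // 2
    return TfbsRecord(GenomicInterval("chr1", pos - half, pos - half + width), tf, cell)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_landscape():
    """A tiny deterministic synthetic landscape shared across tests."""
    from tfclust.synthetic import LandscapeConfig, gen_tfbs_landscape

    cfg = LandscapeConfig(
        genome_length=2_000_000, n_cell_types=4, n_tfs=10, n_clusters=50,
        sites_per_cluster=(2, 6),
    )
    return gen_tfbs_landscape(cfg, seed=11)
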