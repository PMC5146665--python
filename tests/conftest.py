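import numpy as np
import pytest

from orthowindow.models import ExonModel, FilterConfig


@pytest.fixture
def config():
    return FilterConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_exon_model(rng, gene_id="g", chrom="chr1", n_exons=None, strand=None):
    """A random multi-exon model for coordinate-mapping tests."""
    n = int(n_exons if n_exons is not None else rng.integers(1, 6))
    pos = int(rng.integers(0, 5000))
    exons = []
    for _ in range(n):
        length = int(rng.integers(30, 400))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(50, 500))
    strand = strand if strand is not None else ("+" if rng.random() < 0.5 else "-")
    return ExonModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=tuple(exons))
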