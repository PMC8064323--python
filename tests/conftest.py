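import numpy as np
import pandas as pd
import pytest

from h3k4pipe.genome import GenomeLayout, GeneModel, TagSet


def make_tagset(frags, sample_id="s1", group="A") -> TagSet:
    """TagSet from a list of (chrom, start, end) tuples."""
    df = pd.DataFrame(frags, columns=["chrom", "start", "end"])
    return TagSet(sample_id, group, df)


@pytest.fixture
def small_layout() -> GenomeLayout:
    return GenomeLayout(("chr1",), (1_000_000,))


@pytest.fixture
def two_chrom_layout() -> GenomeLayout:
    return GenomeLayout(("chr1", "chr2"), (500_000, 300_000))


@pytest.fixture
def plus_gene() -> GeneModel:
    return GeneModel("gP", "chr1", "+", 10_000, 20_000, ((10_000, 20_000),))


@pytest.fixture
def minus_gene() -> GeneModel:
    return GeneModel("gM", "chr1", "-", 50_000, 40_000, ((40_000, 50_000),))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
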