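import numpy as np
import pytest

from promoarch.features import FeatureDescriptor
from promoarch.motifs import MotifOccurrence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def occ(motif, start, strand, gene="g", length=8, score=10.0):
    """Shorthand occurrence constructor used across the feature/scoring tests."""
    return MotifOccurrence(motif=motif, gene_id=gene, start=start,
                           end=start + length, strand=strand, score=score)


@pytest.fixture
def occ_factory():
    return occ


@pytest.fixture
def desc():
    return FeatureDescriptor
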