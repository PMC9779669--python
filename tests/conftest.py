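import numpy as np
import pytest

from tfnoise.motifs import Motif
from tfnoise.synthetic import (
    SyntheticFeatureSpec,
    SyntheticNoiseSpec,
    SyntheticPromoterSpec,
    gen_expression_matrix,
    gen_feature_table,
    gen_promoters,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_expression():
    spec = SyntheticNoiseSpec(n_genes=200, n_cells=100, seed=11)
    return gen_expression_matrix(spec)


@pytest.fixture
def planted_promoters():
    # the two consensi agree on the 3-bp overlap (TATA_AAA_CCCG), so both
    # planted instances survive intact
    library = {"TBP": "TATAAA", "REB1": "AAACCCG"}
    layout = {
        0: [("TBP", 100, "+", 0), ("REB1", 103, "+", 0)],  # overlap of 3 bp
        1: [("TBP", 500, "-", 1)],
        2: [],
    }
    spec = SyntheticPromoterSpec(
        n_promoters=3, motif_library=library, planted_sites=layout, seed=5
    )
    return gen_promoters(spec), library


@pytest.fixture
def feature_data():
    spec = SyntheticFeatureSpec(n_genes=500, n_features=10, noise_sd=0.5, seed=21)
    return gen_feature_table(spec)


@pytest.fixture
def tata():
    return Motif.from_consensus("TBP", "TATAAA")
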