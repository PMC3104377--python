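import numpy as np
import pandas as pd
import pytest

from xbias import ExpressionAtlas, GeneCatalog, SimConfig


@pytest.fixture
def tiny_catalog() -> GeneCatalog:
    """Ten genes: two X-linked, eight autosomal."""
    frame = pd.DataFrame(
        {
            "arm": ["X", "X", "2L", "2L", "2R", "3L", "3L", "3R", "3R", "4"],
        },
        index=pd.Index([f"g{i}" for i in range(10)], name="gene_id"),
    )
    return GeneCatalog(frame)


@pytest.fixture
def toy_atlas() -> ExpressionAtlas:
    """Three genes × four tissues; g0 is strongly testis-biased."""
    frame = pd.DataFrame(
        {
            "testis": [100.0, 10.0, 5.0],
            "midgut": [10.0, 10.0, 5.0],
            "head": [5.0, 10.0, 5.0],
            "ovary": [20.0, 10.0, 5.0],
        },
        index=pd.Index(["g0", "g1", "g2"], name="gene_id"),
    )
    return ExpressionAtlas(frame)


@pytest.fixture
def small_sim() -> SimConfig:
    """Genome-shaped but small config for fast generator tests."""
    return SimConfig(n_genes=2000, seed=7)
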