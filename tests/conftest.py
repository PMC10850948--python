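import numpy as np
import pandas as pd
import pytest

from rrdkit.nanostring import HOUSEKEEPING_GENES, PanelCountMatrix
from rrdkit.signatures import load_signature_matrix
from rrdkit.synthetic import SimulationConfig


@pytest.fixture(scope="session")
def signature_matrix():
    return load_signature_matrix()


@pytest.fixture
def default_config():
    return SimulationConfig(seed=7)


def build_panel(counts_by_sample: dict[str, list[float]],
                pos=("POS_A", "POS_B"),
                endo=("GENE1",)) -> PanelCountMatrix:
    """Small panel matrix: rows are pos controls, the 4 housekeeping genes,
    then endogenous genes, in that order, from per-sample count vectors."""
    genes = list(pos) + list(HOUSEKEEPING_GENES) + list(endo)
    classes = (
        ["positive_control"] * len(pos)
        + ["housekeeping"] * len(HOUSEKEEPING_GENES)
        + ["endogenous"] * len(endo)
    )
    df = pd.DataFrame(counts_by_sample, index=genes, dtype=float)
    return PanelCountMatrix(counts=df, gene_class=pd.Series(classes, index=genes))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
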