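import numpy as np
import pytest

from nbspanel.data_io import BinaryMutationMatrix, GenePanel
from nbspanel.network_ops import GeneNetwork


@pytest.fixture
def toy_mutation_tsv(tmp_path):
    """Three-record MAF-like file (two functional, one silent)."""
    path = tmp_path / "mutations.tsv"
    path.write_text(
        "Tumor_Sample_Barcode\tHugo_Symbol\tVariant_Classification\n"
        "S1\tTP53\tMissense_Mutation\n"
        "S1\tKRAS\tSilent\n"
        "S2\tBRAF\tNonsense_Mutation\n"
    )
    return path


@pytest.fixture
def toy_network_tsv(tmp_path):
    path = tmp_path / "network.tsv"
    path.write_text(
        "# gene1\tgene2\tweight\n"
        "TP53\tKRAS\t0.9\n"
        "KRAS\tTP53\t0.7\n"
        "KRAS\tBRAF\t0.5\n"
        "BRAF\tBRAF\t1.0\n"
    )
    return path


@pytest.fixture
def small_matrix():
    values = np.array(
        [
            [1, 0, 1],
            [1, 1, 0],
            [0, 1, 0],
            [1, 0, 0],
        ],
        dtype=np.int8,
    )
    return BinaryMutationMatrix(values=values, genes=["A", "B", "C", "D"], samples=["S1", "S2", "S3"])


@pytest.fixture
def small_panel():
    return GenePanel(name="toy", genes=frozenset({"A", "C"}))


def random_network(m: int, seed: int, density: float = 0.2) -> GeneNetwork:
    """Random symmetric weighted network helper used across test modules."""
    rng = np.random.default_rng(seed)
    upper = np.triu((rng.random((m, m)) < density) * rng.random((m, m)), 1)
    weights = upper + upper.T
    return GeneNetwork(genes=[f"G{i}" for i in range(m)], weights=weights)
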