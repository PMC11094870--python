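import numpy as np
import pandas as pd
import pytest

from mrggi import simulate_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def three_edge_network():
    """10-gene synthetic dataset with three strong directed edges."""
    edges = [(0, 1, 0.8), (2, 3, 0.8), (4, 5, -0.8)]
    return simulate_network(edges, n_genes=10, n_samples=1000, seed=0)


def write_network_files(data: dict, directory) -> dict:
    """Write a simulate_network bundle as the pipeline's input TSVs."""
    paths = {
        "expression": directory / "expression.tsv",
        "genotypes": directory / "genotypes.tsv",
        "annotation": directory / "annotation.tsv",
        "variants": directory / "variants.tsv",
    }
    data["expression"].to_csv(paths["expression"], sep="\t", float_format="%.10g")
    data["genotypes"].to_csv(paths["genotypes"], sep="\t")
    data["annotation"].to_csv(paths["annotation"], sep="\t", index=False)
    data["variant_positions"].to_csv(paths["variants"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
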