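import numpy as np
import pandas as pd
import pytest

from coexpnet import ExpressionMatrix
from coexpnet.network import Network
from coexpnet.synthetic import CompendiumSpec, simulate_compendium


def make_matrix(values: np.ndarray, projects: dict[str, str] | None = None) -> ExpressionMatrix:
    genes = [f"g{i:03d}" for i in range(values.shape[0])]
    samples = [f"s{i:03d}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    meta = pd.Series({s: projects.get(s, "P0") for s in samples}) if projects is not None else None
    return ExpressionMatrix(df, meta)


def make_network(pairs, n_target=None, source="test") -> Network:
    """Build a Network from (gene_a, gene_b, hrr[, cooc]) tuples."""
    rows = []
    for p in pairs:
        a, b, hrr = p[0], p[1], p[2]
        cooc = p[3] if len(p) > 3 else 1
        rows.append({"gene_a": a, "gene_b": b, "hrr": hrr, "cooc": cooc})
    edges = pd.DataFrame(rows)
    return Network(edges=edges, n_target=n_target or len(edges), source=source)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_compendium():
    """60 genes in 4 modules of 10 (20 background), 80 samples, 4 projects."""
    spec = CompendiumSpec(n_genes=60, n_samples=80, n_modules=4,
                          module_sizes=[10, 10, 10, 10], n_projects=4,
                          factor_sd=1.0, noise_sd=0.5, project_effect_sd=0.3,
                          seed=7)
    return simulate_compendium(spec)
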