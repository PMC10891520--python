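import numpy as np
import pandas as pd
import pytest

from ip6kqsar.dataset import CompoundRecord, Dataset, standardize_structure
from ip6kqsar.molgraph import MoleculeGraph
from ip6kqsar.simulate import make_fixture_set


@pytest.fixture(scope="session")
def fixture_set():
    return make_fixture_set()


@pytest.fixture(scope="session")
def fixture_graphs(fixture_set):
    """Standardized MoleculeGraphs for every fixture molecule, by name."""
    return {
        f.name: MoleculeGraph.from_smiles(standardize_structure(f.smiles))
        for f in fixture_set
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240263)


def make_activity_dataset(pic50_values, ids=None):
    ids = ids or [f"c{i + 1:02d}" for i in range(len(pic50_values))]
    return Dataset(
        [CompoundRecord(id=i, smiles="C", pic50=float(v)) for i, v in zip(ids, pic50_values)]
    )


@pytest.fixture()
def random_regression():
    """Factory for small random OLS problems."""

    def _make(n=20, p=4, sigma=0.3, seed=0):
        r = np.random.default_rng(seed)
        X = pd.DataFrame(
            r.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)]
        )
        beta = r.normal(size=p)
        y = pd.Series(1.0 + X.to_numpy() @ beta + sigma * r.normal(size=n), name="y")
        return X, y

    return _make
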