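"""Synthetic inputs: fixture molecules with hand-verified descriptor
values, and simulated descriptor/activity tables with planted structure.

The fixture set spans the chemistry every descriptor rule must handle
(alkanes, aromatics, amides including N-aryl, heteroatom-rich molecules,
salts); each expected value carries a provenance tag and the test suite
re-derives all pair counts with the independent brute-force oracle.

The simulator emulates the shape of the study data: ~36 compounds, mixed
count/binary descriptors, pIC50 roughly in the 4.5-7.6 window, generated
as a sparse linear model (by default the published interpretable-model
coefficients) plus Gaussian noise.  Activities stay positive so that the
Poisson/gamma deviance scorers are applicable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FixtureMolecule",
    "make_fixture_set",
    "Marginal",
    "SimSpec",
    "simulate_dataset",
    "simulate_selection_problem",
    "M09_PLANTED",
]

#: planted truth used by default: published interpretable-model equation
M09_PLANTED = {
    "F04[C-C]": 0.169,
    "CMC-50": -0.447,
    "nRCONHR": -0.378,
    "H-047": -0.275,
    "CATS2D_01_LL": 0.100,
}
M09_INTERCEPT = 5.125


@dataclass(frozen=True)
class FixtureMolecule:
    """A named molecule with expected descriptor values.

    ``expected`` maps descriptor name to value; ``provenance`` maps the
    same names to how the value was obtained ("hand" for values derived
    by applying the rules on paper, "oracle" for values frozen from the
    brute-force enumeration routine).
    """

    name: str
    smiles: str
    expected: dict[str, float]
    provenance: dict[str, str]
    tags: tuple[str, ...] = ()


def make_fixture_set() -> list[FixtureMolecule]:
    """Fixture molecules covering every descriptor rule.

    All pair counts, H-047 and nRCONHR values were derived by hand from
    the graph rules (shortest paths counted on paper); the test suite
    re-verifies each against the exhaustive-enumeration oracle.
    """

    def hand(**kw):
        return dict(kw), {k: "hand" for k in kw}

    fixtures = []
    e, p = hand(**{"F04[C-C]": 0, "H-047": 0, "nRCONHR": 0, "CATS2D_01_LL": 0, "CMC-50": 0})
    fixtures.append(FixtureMolecule("methane", "C", e, p, ("alkane",)))
    e, p = hand(**{"F04[C-C]": 0, "H-047": 0, "nRCONHR": 0, "CATS2D_01_LL": 1})
    fixtures.append(FixtureMolecule("ethane", "CC", e, p, ("alkane",)))
    e, p = hand(**{"F04[C-C]": 0, "H-047": 0, "CATS2D_01_LL": 2})
    fixtures.append(FixtureMolecule("propane", "CCC", e, p, ("alkane",)))
    # pentane: the single C-C pair at distance 4 is C1..C5
    e, p = hand(**{"F04[C-C]": 1, "H-047": 0, "nRCONHR": 0, "CATS2D_01_LL": 4})
    fixtures.append(FixtureMolecule("n-pentane", "CCCCC", e, p, ("alkane",)))
    e, p = hand(**{"F04[C-C]": 3, "CATS2D_01_LL": 6})
    fixtures.append(FixtureMolecule("n-heptane", "CCCCCCC", e, p, ("alkane",)))
    # benzene: all six CH are H on C0(sp2); six aromatic bonds = six L-L pairs
    e, p = hand(**{"F04[C-C]": 0, "H-047": 6, "nRCONHR": 0, "CATS2D_01_LL": 6, "CMC-50": 0})
    fixtures.append(FixtureMolecule("benzene", "c1ccccc1", e, p, ("aromatic",)))
    # toluene: methyl-para pair is the only distance-4 C-C pair; ipso H absent
    e, p = hand(**{"F04[C-C]": 1, "H-047": 5, "CATS2D_01_LL": 7})
    fixtures.append(FixtureMolecule("toluene", "Cc1ccccc1", e, p, ("aromatic",)))
    # methanol: three H on C1(sp3); hydroxyl H is on O, never counted
    e, p = hand(**{"H-047": 3, "CATS2D_01_LL": 0, "nRCONHR": 0})
    fixtures.append(FixtureMolecule("methanol", "CO", e, p, ("heteroatom",)))
    e, p = hand(**{"H-047": 2, "CATS2D_01_LL": 0})
    fixtures.append(FixtureMolecule("ethanol", "CCO", e, p, ("heteroatom",)))
    # halogen attached to sp3 carbon counts as its one heteroatom
    e, p = hand(**{"H-047": 3, "CATS2D_01_LL": 0})
    fixtures.append(FixtureMolecule("chloromethane", "CCl", e, p, ("heteroatom", "halogen")))
    e, p = hand(**{"nRCONHR": 1, "H-047": 3, "F04[C-C]": 0})
    fixtures.append(FixtureMolecule("N-methylacetamide", "CC(=O)NC", e, p, ("amide",)))
    e, p = hand(**{"nRCONHR": 0, "H-047": 0})
    fixtures.append(FixtureMolecule("acetamide", "CC(=O)N", e, p, ("amide",)))
    # N-aryl amide: R' aromatic, so not an aliphatic secondary amide
    e, p = hand(**{"nRCONHR": 0, "H-047": 5, "F04[C-C]": 4, "CATS2D_01_LL": 4})
    fixtures.append(FixtureMolecule("acetanilide", "CC(=O)Nc1ccccc1", e, p, ("amide", "aromatic")))
    e, p = hand(**{"nRCONHR": 1, "H-047": 2, "F04[C-C]": 2, "CATS2D_01_LL": 1})
    fixtures.append(FixtureMolecule("N-ethylpropanamide", "CCC(=O)NCC", e, p, ("amide",)))
    # ring nitrogen blocks H-047 and L on its two neighbors
    e, p = hand(**{"H-047": 3, "CATS2D_01_LL": 2, "F04[C-C]": 0})
    fixtures.append(FixtureMolecule("pyridine", "c1ccncc1", e, p, ("aromatic", "heteroatom")))
    e, p = hand(**{"H-047": 5, "CATS2D_01_LL": 4})
    fixtures.append(FixtureMolecule("phenol", "Oc1ccccc1", e, p, ("aromatic", "heteroatom")))
    # disconnected salt: standardization keeps the neutral acid
    e, p = hand(**{"nRCONHR": 0, "H-047": 0, "CATS2D_01_LL": 0})
    fixtures.append(FixtureMolecule("sodium acetate", "CC(=O)[O-].[Na+]", e, p, ("salt",)))
    e, p = hand(**{"H-047": 9, "CATS2D_01_LL": 0})
    fixtures.append(FixtureMolecule("trimethylamine", "CN(C)C", e, p, ("heteroatom", "basic")))
    e, p = hand(**{"H-047": 12, "CATS2D_01_LL": 0})
    fixtures.append(FixtureMolecule("tetramethylammonium", "C[N+](C)(C)C", e, p, ("charged",)))
    # core heterocycle of the modeled series; counts frozen from the oracle
    fixtures.append(
        FixtureMolecule(
            "1,2-benzisoxazole",
            "c1ccc2oncc2c1",
            {"F04[C-C]": 1, "H-047": 4, "nRCONHR": 0, "CATS2D_01_LL": 4, "CMC-50": 0},
            {k: "oracle" for k in ("F04[C-C]", "H-047", "nRCONHR", "CATS2D_01_LL", "CMC-50")},
            ("aromatic", "heteroatom", "benzisoxazole"),
        )
    )
    return fixtures


def export_fixture_set(sdf_path, csv_path) -> None:
    """Write the fixture molecules as an SDF plus an expected-value CSV."""
    import pandas as pd
    from rdkit import Chem

    from .dataset import standardize_structure

    fixtures = make_fixture_set()
    writer = Chem.SDWriter(str(sdf_path))
    rows = []
    try:
        for f in fixtures:
            mol = Chem.MolFromSmiles(standardize_structure(f.smiles))
            mol.SetProp("_Name", f.name)
            writer.write(mol)
            rows.append(
                {"id": f.name, "smiles": f.smiles, "tags": ";".join(f.tags), **f.expected}
            )
    finally:
        writer.close()
    pd.DataFrame(rows).to_csv(csv_path, index=False)


# ---------------------------------------------------------------------- #
# simulated descriptor/activity tables
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class Marginal:
    """Marginal distribution of one descriptor column."""

    kind: str  # "poisson" | "bernoulli" | "normal"
    param: tuple[float, ...]  # (lam,) | (p,) | (mean, sd)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "poisson":
            return rng.poisson(self.param[0], size=n).astype(float)
        if self.kind == "bernoulli":
            return (rng.random(n) < self.param[0]).astype(float)
        if self.kind == "normal":
            return rng.normal(self.param[0], self.param[1], size=n)
        raise ValueError(f"unknown marginal kind {self.kind!r}")


#: study-shaped marginals for the five interpretable descriptors, chosen so
#: simulated activities land roughly in the observed 4.5-7.6 pIC50 window
DEFAULT_MARGINALS = {
    "F04[C-C]": Marginal("poisson", (8.0,)),
    "CMC-50": Marginal("bernoulli", (0.4,)),
    "nRCONHR": Marginal("poisson", (0.3,)),
    "H-047": Marginal("poisson", (4.0,)),
    "CATS2D_01_LL": Marginal("poisson", (6.0,)),
}


@dataclass
class SimSpec:
    """Specification of one simulated descriptor/activity dataset."""

    n: int = 36
    beta: dict[str, float] = field(default_factory=lambda: dict(M09_PLANTED))
    intercept: float = M09_INTERCEPT
    sigma: float = 0.2
    marginals: dict[str, Marginal] = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    n_noise: int = 0  # extra inactive candidate columns
    noise_marginal: Marginal = Marginal("poisson", (5.0,))
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        missing = [k for k in self.beta if k not in self.marginals]
        if missing:
            raise ValueError(f"planted support outside the column set: {missing}")


def simulate_dataset(spec: SimSpec) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Draw (X, y, truth) for a SimSpec; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    cols = {}
    for name, marg in spec.marginals.items():
        cols[name] = marg.sample(rng, spec.n)
    for j in range(spec.n_noise):
        cols[f"noise_{j:02d}"] = spec.noise_marginal.sample(rng, spec.n)
    X = pd.DataFrame(cols, index=[f"sim_{i + 1:03d}" for i in range(spec.n)])
    signal = spec.intercept + sum(b * X[name].to_numpy() for name, b in spec.beta.items())
    y = pd.Series(
        signal + rng.normal(0.0, spec.sigma, size=spec.n), index=X.index, name="pic50"
    )
    truth = {
        "beta": dict(spec.beta),
        "intercept": spec.intercept,
        "sigma": spec.sigma,
        "seed": spec.seed,
        "support": sorted(spec.beta),
    }
    return X, y, truth


def simulate_selection_problem(
    n: int = 30,
    n_candidates: int = 50,
    n_signal: int = 3,
    sigma: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Planted-signal problem for exercising the feature selectors.

    ``n_signal`` standard-normal columns carry unit-scale coefficients
    (alternating sign); the remaining candidates are inert.  Returns
    (X, y, planted column names).
    """
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, n_candidates)),
        columns=[f"d{j:02d}" for j in range(n_candidates)],
        index=[f"sim_{i + 1:03d}" for i in range(n)],
    )
    planted = list(X.columns[:n_signal])
    beta = np.array([1.0 if j % 2 == 0 else -0.8 for j in range(n_signal)])
    # positive baseline keeps all four scoring functions applicable
    y = pd.Series(
        6.0 + X[planted].to_numpy() @ beta + rng.normal(0.0, sigma, size=n),
        index=X.index,
        name="pic50",
    )
    return X, y, planted
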