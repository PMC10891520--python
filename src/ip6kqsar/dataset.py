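"""Compound tables: loading, standardization, pIC50 transform, data split.

The dataset layer works on small tables of (id, SMILES, activity).
Activities enter either as IC50 in micromolar or directly as pIC50 =
-log10(IC50 [M]); exactly one of the two must be present per record.
Structures are standardized once at load time (aromatic perception,
neutralization, salt stripping) so that every downstream descriptor sees
the same canonical parent structure.

The training/test split is the activity-sorted systematic split: sort by
pIC50 descending and send every ``every``-th compound (1-based, starting
at ``start``) to the test set.  For 36 compounds with the defaults this
yields 29 training and 7 test compounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd
from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .molgraph import MoleculeError

__all__ = [
    "CompoundRecord",
    "Dataset",
    "standardize_structure",
    "to_pic50",
    "from_pic50",
    "activity_sorted_split",
    "expected_test_size",
]


def standardize_structure(raw: str) -> str:
    """Canonicalize a SMILES string for descriptor computation.

    Applies, in order: structure cleanup (includes aromatic perception),
    salt stripping (keep the largest organic fragment; RDKit breaks
    heavy-atom-count ties toward the default canonical choice), and charge
    neutralization.  The result is the canonical SMILES of the neutral
    parent; standardizing twice gives the same string.

    Raises
    ------
    MoleculeError
        If the input cannot be parsed or nothing is left after stripping.
    """
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise MoleculeError(f"unparseable SMILES: {raw!r}")
    params = rdMolStandardize.CleanupParameters()
    params.preferOrganic = True
    # largest fragment judged on heavy atoms, ties broken by molecular weight
    params.largestFragmentChooserCountHeavyAtomsOnly = True
    mol = rdMolStandardize.Cleanup(mol, params)
    chooser = rdMolStandardize.LargestFragmentChooser(params)
    mol = chooser.choose(mol)
    if mol is None or mol.GetNumAtoms() == 0:
        raise MoleculeError(f"nothing left after salt stripping: {raw!r}")
    mol = rdMolStandardize.Uncharger().uncharge(mol)
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def to_pic50(ic50_um: float) -> float:
    """pIC50 from an IC50 in micromolar: ``-log10(ic50_um / 1e6)``."""
    if not ic50_um > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_um}")
    return -math.log10(ic50_um / 1.0e6)


def from_pic50(pic50: float) -> float:
    """Inverse of :func:`to_pic50`: IC50 in micromolar."""
    return 10.0 ** (6.0 - pic50)


@dataclass
class CompoundRecord:
    id: str
    smiles: str
    pic50: float
    ic50_um: float | None = None
    split: str = "unassigned"  # train | test | unassigned

    def __post_init__(self):
        if not math.isfinite(self.pic50):
            raise ValueError(f"compound {self.id}: pIC50 must be finite")


@dataclass
class Dataset:
    """Ordered collection of compounds with optional split labels."""

    records: list[CompoundRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate compound ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def n_train(self) -> int:
        return sum(r.split == "train" for r in self.records)

    @property
    def n_test(self) -> int:
        return sum(r.split == "test" for r in self.records)

    def activities(self) -> pd.Series:
        return pd.Series([r.pic50 for r in self.records], index=self.ids, name="pic50")

    def subset(self, split: str) -> "Dataset":
        return Dataset([replace(r) for r in self.records if r.split == split])

    # ------------------------------------------------------------------ #
    # I/O
    # ------------------------------------------------------------------ #
    @classmethod
    def from_frame(cls, df: pd.DataFrame, standardize: bool = True) -> "Dataset":
        cols = set(df.columns)
        if "id" not in cols or "smiles" not in cols:
            raise ValueError("compound table needs 'id' and 'smiles' columns")
        has_ic50 = "ic50_um" in cols
        has_pic50 = "pic50" in cols
        if not (has_ic50 or has_pic50):
            raise ValueError("compound table needs one of 'ic50_um' or 'pic50'")
        records = []
        for _, row in df.iterrows():
            ic50 = None
            if has_pic50 and pd.notna(row.get("pic50")):
                pic50 = float(row["pic50"])
                if has_ic50 and pd.notna(row.get("ic50_um")):
                    raise ValueError(
                        f"compound {row['id']}: give ic50_um or pic50, not both"
                    )
            elif has_ic50 and pd.notna(row.get("ic50_um")):
                ic50 = float(row["ic50_um"])
                pic50 = to_pic50(ic50)
            else:
                raise ValueError(f"compound {row['id']}: no activity value")
            smiles = standardize_structure(row["smiles"]) if standardize else row["smiles"]
            records.append(
                CompoundRecord(
                    id=str(row["id"]),
                    smiles=smiles,
                    pic50=pic50,
                    ic50_um=ic50,
                    split=str(row["split"]) if "split" in cols and pd.notna(row.get("split")) else "unassigned",
                )
            )
        return cls(records)

    @classmethod
    def from_csv(cls, path, standardize: bool = True) -> "Dataset":
        return cls.from_frame(pd.read_csv(path), standardize=standardize)

    @classmethod
    def from_sdf(cls, sdf_path, activity_csv, standardize: bool = True) -> "Dataset":
        """Structures from an SDF paired with an activity table.

        Molecule titles (the ``_Name`` field) must match the ``id``
        column of the CSV, which carries ``ic50_um`` or ``pic50``.
        """
        from rdkit import Chem

        smiles = {}
        for i, mol in enumerate(Chem.SDMolSupplier(str(sdf_path))):
            if mol is None:
                raise MoleculeError(f"unparseable SDF record #{i + 1} in {sdf_path}")
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            if not name:
                raise ValueError(f"SDF record #{i + 1} has no title to use as id")
            smiles[name] = Chem.MolToSmiles(mol)
        act = pd.read_csv(activity_csv)
        missing = [i for i in act["id"].astype(str) if i not in smiles]
        if missing:
            raise ValueError(f"activity ids absent from SDF: {missing}")
        act = act.assign(smiles=[smiles[str(i)] for i in act["id"]])
        return cls.from_frame(act, standardize=standardize)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "smiles": [r.smiles for r in self.records],
                "ic50_um": [r.ic50_um for r in self.records],
                "pic50": [r.pic50 for r in self.records],
                "split": [r.split for r in self.records],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def expected_test_size(n: int, every: int = 5, start: int = 2) -> int:
    """Size of the test set produced by the systematic split."""
    if n < start:
        return 0
    return (n - start) // every + 1


def activity_sorted_split(ds: Dataset, every: int = 5, start: int = 2) -> Dataset:
    """Label compounds train/test by the activity-sorted systematic rule.

    Compounds are ranked by pIC50 descending (ties broken by id, so the
    outcome is invariant to input row order); ranks ``start``,
    ``start + every``, ... (1-based) become the test set, the rest the
    training set.  Returns a new Dataset in the original record order.
    """
    if every < 2:
        raise ValueError("every must be >= 2")
    if not 1 <= start <= every:
        raise ValueError("start must satisfy 1 <= start <= every")
    order = sorted(range(len(ds.records)), key=lambda i: (-ds.records[i].pic50, ds.records[i].id))
    test_ranks = set(range(start - 1, len(order), every))  # 0-based over sorted order
    labels = {}
    for rank, i in enumerate(order):
        labels[i] = "test" if rank in test_ranks else "train"
    return Dataset(
        [replace(r, split=labels[i]) for i, r in enumerate(ds.records)]
    )
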