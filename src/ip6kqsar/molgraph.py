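"""Hydrogen-explicit molecular graphs for 2D descriptor computation.

All descriptors in this package are functions of the 2D molecular graph
only: element, hybridization, aromaticity, formal charge, connectivity and
bond orders.  :class:`MoleculeGraph` wraps an RDKit molecule kept in
hydrogen-explicit form and exposes the graph views the descriptor layer
needs (heavy-atom topological distance matrix, per-atom attributes).
Descriptor values must be invariant under any renumbering of the input
atoms; the distance matrix and every attribute exposed here are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdmolops

#: sentinel for the topological distance between disconnected fragments
INF_DISTANCE = np.inf

# RDKit encodes unreachable atom pairs with a large finite constant
_RDKIT_UNREACHABLE = 1.0e7


class MoleculeError(ValueError):
    """Raised for unparseable or chemically invalid structure input."""


@dataclass(frozen=True)
class AtomView:
    """Immutable snapshot of the atom attributes descriptors may depend on."""

    index: int
    element: str
    hybridization: str  # "sp3" | "sp2" | "sp" | "other"
    aromatic: bool
    formal_charge: int
    n_hydrogens: int  # total attached hydrogens (explicit + implicit)


_HYB_MAP = {
    Chem.HybridizationType.SP3: "sp3",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP: "sp",
}


class MoleculeGraph:
    """A molecule as a 2D graph, hydrogen-explicit on demand.

    Parameters
    ----------
    mol:
        A sanitized RDKit molecule.  Explicit hydrogens are added
        internally; callers may pass either form.
    """

    def __init__(self, mol: Chem.Mol):
        if mol is None:
            raise MoleculeError("cannot build a MoleculeGraph from None")
        # keep a hydrogen-explicit copy; descriptors that only need heavy
        # atoms use the heavy-atom view below
        self.mol = Chem.AddHs(mol)
        Chem.SanitizeMol(self.mol)

    @classmethod
    def from_smiles(cls, smiles: str) -> "MoleculeGraph":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise MoleculeError(f"unparseable SMILES: {smiles!r}")
        return cls(mol)

    # ------------------------------------------------------------------ #
    # views
    # ------------------------------------------------------------------ #
    @property
    def heavy_mol(self) -> Chem.Mol:
        """The molecule with hydrogens folded back into atom properties."""
        return Chem.RemoveHs(self.mol)

    def atoms(self, heavy_only: bool = False) -> list[AtomView]:
        mol = self.heavy_mol if heavy_only else self.mol
        out = []
        for a in mol.GetAtoms():
            # aromatic atoms are never sp3 in this perception model;
            # force sp2 so e.g. aromatic N reads consistently
            hyb = "sp2" if a.GetIsAromatic() else _HYB_MAP.get(a.GetHybridization(), "other")
            out.append(
                AtomView(
                    index=a.GetIdx(),
                    element=a.GetSymbol(),
                    hybridization=hyb,
                    aromatic=a.GetIsAromatic(),
                    formal_charge=a.GetFormalCharge(),
                    n_hydrogens=a.GetTotalNumHs(includeNeighbors=True),
                )
            )
        return out

    def n_atoms(self, heavy_only: bool = False) -> int:
        return (self.heavy_mol if heavy_only else self.mol).GetNumAtoms()

    def topological_distances(self, heavy_only: bool = True) -> np.ndarray:
        """Shortest-path bond counts between atoms.

        Symmetric with a zero diagonal; pairs in different fragments get
        :data:`INF_DISTANCE`.
        """
        mol = self.heavy_mol if heavy_only else self.mol
        if mol.GetNumAtoms() == 0:
            return np.zeros((0, 0))
        dm = np.array(rdmolops.GetDistanceMatrix(mol), dtype=float, copy=True)
        dm[dm >= _RDKIT_UNREACHABLE] = INF_DISTANCE
        return dm

    def renumbered(self, order: list[int]) -> "MoleculeGraph":
        """Return the same molecule with heavy atoms renumbered.

        ``order`` is a permutation of the heavy-atom indices; used by the
        invariance tests.
        """
        heavy = self.heavy_mol
        if sorted(order) != list(range(heavy.GetNumAtoms())):
            raise ValueError("order must be a permutation of heavy-atom indices")
        return MoleculeGraph(Chem.RenumberAtoms(heavy, list(order)))

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"MoleculeGraph({Chem.MolToSmiles(self.heavy_mol)!r})"
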