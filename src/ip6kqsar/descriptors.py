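"""Interpretable 2D descriptors: atom pairs, atom-centered fragments,
functional-group counts, drug-likeness, and CATS2D pharmacophore pairs.

These are the five descriptors of the interpretable IP6K1 inhibition model
(plus their constitutional building blocks):

``F04[C-C]``
    Number of unordered carbon-carbon pairs at topological distance 4.
``CMC-50``
    Binary Ghose-Viswanadhan-Wendoloski CMC 50% drug-likeness index:
    1 iff ALOGP in [1.3, 4.1], AMR in [70, 110], MW in [230, 390] and
    nAT in [30, 55] (closed intervals), else 0.
``nRCONHR``
    Count of aliphatic secondary amides R-C(=O)-N(H)-R' with both R and
    R' non-aromatic carbons.
``H-047``
    Count of hydrogens on sp3 carbons bearing exactly one heteroatom or
    on sp2 (incl. aromatic) carbons bearing none.
``CATS2D_01_LL``
    Number of lipophilic-lipophilic pharmacophore pairs at topological
    distance 1.

All descriptors are pure functions of the 2D molecular graph and are
invariant under atom renumbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as RDDescriptors
from rdkit.Chem import rdMolDescriptors

from .dataset import Dataset
from .molgraph import INF_DISTANCE, MoleculeGraph

__all__ = [
    "topological_distances",
    "f0x_pair_count",
    "ghose_crippen_type",
    "alogp_amr",
    "h047",
    "nrconhr",
    "cmc50",
    "cmc50_from_values",
    "cats2d_types",
    "cats2d_pair_count",
    "compute_descriptor",
    "descriptor_matrix",
    "DescriptorMatrix",
    "M09_DESCRIPTORS",
    "M15_DESCRIPTORS",
    "COMPUTABLE_DESCRIPTORS",
    "CMC50_RANGES",
]

#: closed qualifying intervals of the CMC 50% drug-likeness index
CMC50_RANGES = {
    "ALOGP": (1.3, 4.1),
    "AMR": (70.0, 110.0),
    "MW": (230.0, 390.0),
    "nAT": (30.0, 55.0),
}

M09_DESCRIPTORS = ["F04[C-C]", "CMC-50", "nRCONHR", "H-047", "CATS2D_01_LL"]
#: conformer/matrix-based descriptors of the all-descriptor model; these are
#: never computed here and must be imported from an external descriptor table
M15_DESCRIPTORS = ["VE3sign_B(s)", "MATS4m", "SpMax2_Bh(v)", "G3i", "R5e+"]


# ---------------------------------------------------------------------- #
# distances and atom pairs
# ---------------------------------------------------------------------- #
def topological_distances(m: MoleculeGraph, heavy_only: bool = True) -> np.ndarray:
    """Shortest-path bond-count matrix (inf between fragments)."""
    return m.topological_distances(heavy_only=heavy_only)


def f0x_pair_count(m: MoleculeGraph, elem_a: str, elem_b: str, lag: int) -> int:
    """Count unordered heavy-atom pairs of given elements at distance ``lag``.

    The 2D atom-pair descriptor family F0x[a-b]; each unordered pair is
    counted once, whatever the element order.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    atoms = m.atoms(heavy_only=True)
    dm = m.topological_distances(heavy_only=True)
    count = 0
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if dm[i, j] != lag:
                continue
            ei, ej = atoms[i].element, atoms[j].element
            if (ei == elem_a and ej == elem_b) or (ei == elem_b and ej == elem_a):
                count += 1
    return count


# ---------------------------------------------------------------------- #
# atom-centered fragments and Crippen contributions
# ---------------------------------------------------------------------- #
def ghose_crippen_type(m: MoleculeGraph) -> list[tuple[str, float, float]]:
    """Per-atom fragment class with (logP, MR) contributions.

    Returns one ``(class_label, logp_contribution, mr_contribution)``
    triple per atom of the hydrogen-explicit molecule, using the Crippen
    atom-contribution system as parameterized in RDKit.  Atoms that match
    no class are labelled ``"unclassified"``, contribute 0, and raise a
    warning.
    """
    mol = m.mol
    n = mol.GetNumAtoms()
    types = [0] * n
    labels = [""] * n
    contribs = rdMolDescriptors._CalcCrippenContribs(mol, True, types, labels)
    out = []
    for idx, ((logp, mr), label) in enumerate(zip(contribs, labels)):
        if not label or label in ("X",):
            warnings.warn(
                f"atom {idx} ({mol.GetAtomWithIdx(idx).GetSymbol()}) matches no "
                "Crippen class; contributes 0",
                stacklevel=2,
            )
            out.append(("unclassified", 0.0, 0.0))
        else:
            out.append((label, float(logp), float(mr)))
    return out


def alogp_amr(m: MoleculeGraph) -> tuple[float, float]:
    """Atom-contribution logP and molar refractivity (sums over classes)."""
    typed = ghose_crippen_type(m)
    return (sum(t[1] for t in typed), sum(t[2] for t in typed))


def _hetero_neighbor_count(atom: Chem.Atom) -> int:
    return sum(1 for nb in atom.GetNeighbors() if nb.GetSymbol() not in ("C", "H"))


def h047(m: MoleculeGraph) -> int:
    """Hydrogens on C1(sp3) or C0(sp2) carbons.

    The superscript counts attached heteroatoms (non-C, non-H): an sp3
    carbon qualifies with exactly one, an sp2 or aromatic carbon with
    none.  Hydrogens on heteroatoms never count.
    """
    count = 0
    for atom in m.mol.GetAtoms():
        if atom.GetSymbol() != "C":
            continue
        n_het = _hetero_neighbor_count(atom)
        if atom.GetIsAromatic() or atom.GetHybridization() == Chem.HybridizationType.SP2:
            if n_het == 0:
                count += atom.GetTotalNumHs(includeNeighbors=True)
        elif atom.GetHybridization() == Chem.HybridizationType.SP3:
            if n_het == 1:
                count += atom.GetTotalNumHs(includeNeighbors=True)
    return count


_SECONDARY_AMIDE = Chem.MolFromSmarts("[CX3](=[OX1])[NX3;H1]")


def nrconhr(m: MoleculeGraph) -> int:
    """Aliphatic secondary amides R-C(=O)-N(H)-R'.

    Both the carbonyl substituent R and the nitrogen substituent R' must
    be non-aromatic carbons; each amide group counts once.
    """
    mol = m.heavy_mol
    groups = set()
    for c_idx, o_idx, n_idx in mol.GetSubstructMatches(_SECONDARY_AMIDE):
        carbonyl = mol.GetAtomWithIdx(c_idx)
        nitrogen = mol.GetAtomWithIdx(n_idx)
        r_ok = any(
            nb.GetSymbol() == "C" and not nb.GetIsAromatic()
            for nb in carbonyl.GetNeighbors()
            if nb.GetIdx() not in (o_idx, n_idx)
        )
        rp_ok = any(
            nb.GetSymbol() == "C" and not nb.GetIsAromatic()
            for nb in nitrogen.GetNeighbors()
            if nb.GetIdx() != c_idx
        )
        if r_ok and rp_ok:
            groups.add((c_idx, n_idx))
    return len(groups)


def cmc50_from_values(alogp: float, amr: float, mw: float, nat: float) -> int:
    """CMC 50% drug-likeness flag from precomputed property values."""
    checks = {"ALOGP": alogp, "AMR": amr, "MW": mw, "nAT": nat}
    for name, value in checks.items():
        lo, hi = CMC50_RANGES[name]
        if not (lo <= value <= hi):
            return 0
    return 1


def cmc50(m: MoleculeGraph) -> int:
    """CMC 50% drug-likeness flag computed from the molecular graph."""
    alogp, amr = alogp_amr(m)
    mw = RDDescriptors.MolWt(m.mol)
    nat = m.n_atoms(heavy_only=False)
    return cmc50_from_values(alogp, amr, mw, nat)


# ---------------------------------------------------------------------- #
# CATS2D pharmacophore pairs
# ---------------------------------------------------------------------- #
_CARBONYL_LIKE = Chem.MolFromSmarts("[NX3][CX3]=[OX1,SX1]")
_ACIDIC_O = Chem.MolFromSmarts(
    "[OX2H1;$(O[CX3]=[OX1]),$(O[SX4](=[OX1])=[OX1]),$(O[PX4]=[OX1])]"
)


def cats2d_types(m: MoleculeGraph) -> list[frozenset[str]]:
    """Pharmacophore point types per heavy atom.

    Types follow the CATS scheme over five features:

    - ``D`` hydrogen-bond donor: O or N carrying at least one hydrogen;
    - ``A`` acceptor: any O, or an uncharged/anionic N that is not an
      amide-type nitrogen;
    - ``P`` positive: positively charged atom, or a basic amine nitrogen
      (aliphatic, not adjacent to a carbonyl/thiocarbonyl, not bonded to
      an aromatic ring atom);
    - ``N`` negative: negatively charged atom, or the hydroxyl oxygen of
      a carboxylic/sulfonic/phosphonic acid;
    - ``L`` lipophilic: Cl, Br, I, or a carbon all of whose neighbors
      are carbon or hydrogen.
    """
    mol = m.heavy_mol
    amide_n = {match[0] for match in mol.GetSubstructMatches(_CARBONYL_LIKE)}
    acidic_o = {match[0] for match in mol.GetSubstructMatches(_ACIDIC_O)}
    out = []
    for atom in mol.GetAtoms():
        types: set[str] = set()
        sym = atom.GetSymbol()
        charge = atom.GetFormalCharge()
        n_h = atom.GetTotalNumHs(includeNeighbors=True)
        idx = atom.GetIdx()
        if sym in ("O", "N") and n_h >= 1:
            types.add("D")
        if sym == "O" or (sym == "N" and charge <= 0 and idx not in amide_n):
            types.add("A")
        if charge > 0:
            types.add("P")
        elif (
            sym == "N"
            and not atom.GetIsAromatic()
            and idx not in amide_n
            and not any(nb.GetIsAromatic() for nb in atom.GetNeighbors())
        ):
            types.add("P")
        if charge < 0 or idx in acidic_o:
            types.add("N")
        if sym in ("Cl", "Br", "I"):
            types.add("L")
        elif sym == "C" and all(nb.GetSymbol() in ("C", "H") for nb in atom.GetNeighbors()):
            types.add("L")
        out.append(frozenset(types))
    return out


def cats2d_pair_count(m: MoleculeGraph, lag: int, t1: str, t2: str) -> int:
    """Count pharmacophore-type pairs at a topological distance.

    For ``lag >= 1``: unordered pairs of distinct heavy atoms {a, b} with
    ``t1`` among a's types and ``t2`` among b's (or swapped), at
    shortest-path distance ``lag``; each pair counts once.  For
    ``lag == 0``: atoms carrying both types simultaneously.
    """
    if not 0 <= lag <= 9:
        raise ValueError("lag must be in 0..9")
    types = cats2d_types(m)
    if lag == 0:
        return sum(1 for t in types if t1 in t and t2 in t)
    dm = m.topological_distances(heavy_only=True)
    count = 0
    for i in range(len(types)):
        for j in range(i + 1, len(types)):
            if dm[i, j] != lag:
                continue
            if (t1 in types[i] and t2 in types[j]) or (t2 in types[i] and t1 in types[j]):
                count += 1
    return count


# ---------------------------------------------------------------------- #
# descriptor matrix assembly
# ---------------------------------------------------------------------- #
def _nat(m: MoleculeGraph) -> int:
    return m.n_atoms(heavy_only=False)


COMPUTABLE_DESCRIPTORS: dict[str, Callable[[MoleculeGraph], float]] = {
    "F04[C-C]": lambda m: f0x_pair_count(m, "C", "C", 4),
    "CMC-50": cmc50,
    "nRCONHR": nrconhr,
    "H-047": h047,
    "CATS2D_01_LL": lambda m: cats2d_pair_count(m, 1, "L", "L"),
    "ALOGP": lambda m: alogp_amr(m)[0],
    "AMR": lambda m: alogp_amr(m)[1],
    "MW": lambda m: RDDescriptors.MolWt(m.mol),
    "nAT": _nat,
}


@dataclass
class DescriptorMatrix:
    """Named descriptor columns per compound, with provenance per column."""

    values: pd.DataFrame  # index: compound id
    provenance: dict[str, str]  # column -> "computed" | "imported"
    failed_ids: list[str]

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path) -> None:
        self.values.rename_axis("id").to_csv(path)

    def __post_init__(self):
        self.values = self.values.rename_axis("id")

    @classmethod
    def from_csv(cls, path, provenance: str = "imported") -> "DescriptorMatrix":
        df = pd.read_csv(path).set_index("id")
        return cls(values=df, provenance={c: provenance for c in df.columns}, failed_ids=[])


def compute_descriptor(m: MoleculeGraph, name: str) -> float:
    try:
        fn = COMPUTABLE_DESCRIPTORS[name]
    except KeyError:
        raise KeyError(f"descriptor {name!r} is not computable here") from None
    return fn(m)


def descriptor_matrix(
    ds: Dataset,
    which: Iterable[str],
    imported: pd.DataFrame | None = None,
) -> DescriptorMatrix:
    """Build a compound x descriptor matrix.

    Computable descriptor names are evaluated from the structures;
    anything else must be present in ``imported`` (indexed by compound
    id).  Missing imported columns raise with the full list of what is
    missing; compounds whose structure fails to parse are flagged in
    ``failed_ids`` with NaN rows rather than dropped.
    """
    which = list(which)
    missing = [
        name
        for name in which
        if name not in COMPUTABLE_DESCRIPTORS
        and (imported is None or name not in imported.columns)
    ]
    if missing:
        raise KeyError(
            "descriptors not computable and absent from the imported matrix: "
            + ", ".join(missing)
        )
    rows: dict[str, dict[str, float]] = {}
    failed: list[str] = []
    graphs: dict[str, MoleculeGraph | None] = {}
    for rec in ds:
        try:
            graphs[rec.id] = MoleculeGraph.from_smiles(rec.smiles)
        except Exception:
            graphs[rec.id] = None
            failed.append(rec.id)
    provenance: dict[str, str] = {}
    for name in which:
        if name in COMPUTABLE_DESCRIPTORS:
            provenance[name] = "computed"
        else:
            provenance[name] = "imported"
    for rec in ds:
        row: dict[str, float] = {}
        for name in which:
            if provenance[name] == "computed":
                g = graphs[rec.id]
                row[name] = float(compute_descriptor(g, name)) if g is not None else np.nan
            else:
                try:
                    row[name] = float(imported.loc[rec.id, name])
                except KeyError:
                    row[name] = np.nan
        rows[rec.id] = row
    values = pd.DataFrame.from_dict(rows, orient="index").reindex(ds.ids)
    values = values[which] if which else pd.DataFrame(index=ds.ids)
    return DescriptorMatrix(
        values=values.rename_axis("id"), provenance=provenance, failed_ids=failed
    )
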