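"""Independent brute-force oracles for the pair-count descriptors.

Everything here deliberately avoids the implementation paths of
:mod:`ip6kqsar.descriptors`: shortest paths come from networkx BFS over
an explicitly constructed bond graph (not the RDKit distance matrix) and
counting is naive enumeration over all atom pairs.  The test suite uses
these routines to re-derive every expected pair-count value.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .descriptors import cats2d_types
from .molgraph import INF_DISTANCE, MoleculeGraph

__all__ = [
    "bond_graph",
    "brute_force_distances",
    "brute_force_f0x",
    "brute_force_cats_pairs",
    "brute_force_loo",
]


def bond_graph(m: MoleculeGraph, heavy_only: bool = True) -> nx.Graph:
    mol = m.heavy_mol if heavy_only else m.mol
    g = nx.Graph()
    g.add_nodes_from(
        (a.GetIdx(), {"element": a.GetSymbol()}) for a in mol.GetAtoms()
    )
    g.add_edges_from((b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds())
    return g


def brute_force_distances(m: MoleculeGraph, heavy_only: bool = True) -> np.ndarray:
    """All-pairs shortest paths by per-node BFS."""
    g = bond_graph(m, heavy_only=heavy_only)
    n = g.number_of_nodes()
    dm = np.full((n, n), INF_DISTANCE)
    for src in g.nodes:
        dm[src, src] = 0.0
        for dst, d in nx.single_source_shortest_path_length(g, src).items():
            dm[src, dst] = float(d)
    return dm


def brute_force_f0x(m: MoleculeGraph, elem_a: str, elem_b: str, lag: int) -> int:
    g = bond_graph(m, heavy_only=True)
    dm = brute_force_distances(m, heavy_only=True)
    count = 0
    nodes = sorted(g.nodes)
    for i in nodes:
        for j in nodes:
            if i >= j or dm[i, j] != lag:
                continue
            pair = {g.nodes[i]["element"], g.nodes[j]["element"]}
            if pair == {elem_a, elem_b} or (elem_a == elem_b and pair == {elem_a}):
                count += 1
    return count


def brute_force_cats_pairs(m: MoleculeGraph, lag: int, t1: str, t2: str) -> int:
    """CATS pair count by naive enumeration (typing shared, paths not)."""
    types = cats2d_types(m)
    if lag == 0:
        return sum(1 for t in types if t1 in t and t2 in t)
    dm = brute_force_distances(m, heavy_only=True)
    count = 0
    for i in range(len(types)):
        for j in range(i + 1, len(types)):
            if dm[i, j] != lag:
                continue
            if (t1 in types[i] and t2 in types[j]) or (t2 in types[i] and t1 in types[j]):
                count += 1
    return count


def brute_force_loo(X, y) -> np.ndarray:
    """Leave-one-out predictions by n explicit refits (no hat-matrix shortcut)."""
    X = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    A = np.column_stack([np.ones(n), X])
    out = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        beta, *_ = np.linalg.lstsq(A[mask], yv[mask], rcond=None)
        out[i] = A[i] @ beta
    return out
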