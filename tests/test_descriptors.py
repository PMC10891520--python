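"""Descriptor rules: distances, atom pairs, atom-centered fragments,
CATS typing, drug-likeness flag, and matrix assembly."""

import numpy as np
import pandas as pd
import pytest

from ip6kqsar import descriptors as D
from ip6kqsar import oracle
from ip6kqsar.dataset import CompoundRecord, Dataset
from ip6kqsar.descriptors import (
    M09_DESCRIPTORS,
    cats2d_pair_count,
    cats2d_types,
    cmc50_from_values,
    descriptor_matrix,
    f0x_pair_count,
    ghose_crippen_type,
    h047,
    nrconhr,
)
from ip6kqsar.molgraph import MoleculeGraph


def graph(smi):
    return MoleculeGraph.from_smiles(smi)


class TestTopologicalDistances:
    def test_pentane_chain_ends(self):
        dm = graph("CCCCC").topological_distances()
        assert dm[0, 4] == 4

    def test_benzene_ring_diameter(self):
        dm = graph("c1ccccc1").topological_distances()
        assert dm.max() == 3

    def test_disconnected_fragments_infinite(self):
        dm = graph("CC.O").topological_distances()
        assert np.isinf(dm[0, 2])

    def test_metric_properties(self):
        dm = graph("CC(C)Cc1ccccc1O").topological_distances()
        assert np.allclose(dm, dm.T)
        assert np.all(np.diag(dm) == 0)
        n = dm.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert dm[i, j] <= dm[i, k] + dm[k, j]


class TestAtomPairs:
    @pytest.mark.parametrize(
        "smi,lag,expected",
        [("CCCCC", 4, 1), ("c1ccccc1", 4, 0), ("C", 1, 0), ("C", 4, 0)],
    )
    def test_cc_pair_counts(self, smi, lag, expected):
        assert f0x_pair_count(graph(smi), "C", "C", lag) == expected

    def test_pair_conservation_for_pure_carbon(self):
        # summing over all lags recovers the number of heavy-atom pairs
        for smi in ["CCCCC", "c1ccccc1", "CC(C)CC", "C1CCCCC1CC"]:
            m = graph(smi)
            n = m.n_atoms(heavy_only=True)
            diameter = int(m.topological_distances().max())
            total = sum(f0x_pair_count(m, "C", "C", lag) for lag in range(1, diameter + 1))
            assert total == n * (n - 1) // 2

    def test_element_order_symmetric(self):
        m = graph("CCO")
        assert f0x_pair_count(m, "C", "O", 2) == f0x_pair_count(m, "O", "C", 2) == 1


class TestAtomCenteredFragments:
    @pytest.mark.parametrize(
        "smi,expected",
        [
            ("c1ccccc1", 6),  # all H on C0(sp2)
            ("CC", 0),  # H on C0(sp3) is a different fragment class
            ("CO", 3),  # H on C1(sp3); the O-H hydrogen never counts
            ("CCl", 3),  # halogen is the single heteroatom
            ("C=C", 4),  # vinyl H on C0(sp2)
        ],
    )
    def test_h047_rule(self, smi, expected):
        assert h047(graph(smi)) == expected

    def test_h047_bounded_by_h_count(self, fixture_graphs):
        for m in fixture_graphs.values():
            n_h = m.n_atoms() - m.n_atoms(heavy_only=True)
            assert 0 <= h047(m) <= n_h

    def test_crippen_classes_cover_every_atom(self):
        m = graph("CC(=O)Nc1ccc(O)cc1")
        typed = ghose_crippen_type(m)
        assert len(typed) == m.n_atoms()
        assert all(label != "unclassified" for label, _, _ in typed)

    def test_ethane_class_sums(self):
        # two equivalent CH3 carbons and six equivalent hydrogens: the
        # molecule totals are 2x and 6x the per-class contributions
        typed = ghose_crippen_type(graph("CC"))
        carbons = [t for t in typed if t[0].startswith("C")]
        hydrogens = [t for t in typed if t[0].startswith("H")]
        assert len(carbons) == 2 and len(hydrogens) == 6
        assert len({t[0] for t in carbons}) == 1 and len({t[0] for t in hydrogens}) == 1
        alogp, amr = D.alogp_amr(graph("CC"))
        assert alogp == pytest.approx(2 * carbons[0][1] + 6 * hydrogens[0][1])
        assert amr == pytest.approx(2 * carbons[0][2] + 6 * hydrogens[0][2])

    def test_benzene_class_sums(self):
        typed = ghose_crippen_type(graph("c1ccccc1"))
        c_label, c_logp, _ = next(t for t in typed if t[0].startswith("C"))
        h_label, h_logp, _ = next(t for t in typed if t[0].startswith("H"))
        alogp, _ = D.alogp_amr(graph("c1ccccc1"))
        assert alogp == pytest.approx(6 * (c_logp + h_logp))


class TestSecondaryAmides:
    @pytest.mark.parametrize(
        "smi,expected",
        [
            ("CC(=O)NC", 1),  # N-methylacetamide
            ("CC(=O)Nc1ccccc1", 0),  # N-aryl
            ("CC(=O)N", 0),  # primary
            ("O=CNC", 0),  # formamide-type: R is H, not carbon
            ("CCC(=O)NCC", 1),
            ("CC(=O)NCCNC(C)=O", 2),  # two independent amide groups
        ],
    )
    def test_counts(self, smi, expected):
        assert nrconhr(graph(smi)) == expected

    def test_bounded_by_amide_bonds(self, fixture_graphs):
        from rdkit import Chem

        amide = Chem.MolFromSmarts("[CX3](=[OX1])[NX3]")
        for m in fixture_graphs.values():
            assert nrconhr(m) <= len(m.heavy_mol.GetSubstructMatches(amide))


class TestCMC50:
    def test_inside_all_windows(self):
        assert cmc50_from_values(2.0, 90, 300, 40) == 1

    def test_one_property_outside(self):
        assert cmc50_from_values(5.0, 90, 300, 40) == 0

    def test_boundaries_inclusive(self):
        assert cmc50_from_values(1.3, 70, 230, 30) == 1
        assert cmc50_from_values(4.1, 110, 390, 55) == 1

    def test_small_molecule_flagged_zero(self):
        assert D.cmc50(graph("C")) == 0


class TestCATS:
    def test_ethane_both_lipophilic(self):
        assert [set(t) for t in cats2d_types(graph("CC"))] == [{"L"}, {"L"}]

    def test_methanol_donor_acceptor(self):
        types = cats2d_types(graph("CO"))
        c, o = types
        assert set(o) == {"D", "A"}
        assert "L" not in c  # carbon with an O neighbor is not lipophilic

    def test_chloromethane(self):
        c, cl = cats2d_types(graph("CCl"))
        assert set(cl) == {"L"} and set(c) == set()

    def test_amide_nitrogen_donor_not_acceptor(self):
        types = cats2d_types(graph("CC(=O)NC"))
        n_types = types[3]  # the amide nitrogen
        assert "D" in n_types and "A" not in n_types

    def test_carboxylic_acid_oxygen_negative(self):
        types = cats2d_types(graph("CC(=O)O"))
        assert "N" in types[3]

    def test_basic_and_quaternary_nitrogen_positive(self):
        assert "P" in cats2d_types(graph("CN(C)C"))[1]
        assert "P" in cats2d_types(graph("C[N+](C)(C)C"))[1]

    @pytest.mark.parametrize(
        "smi,lag,expected", [("CC", 1, 1), ("CCC", 1, 2), ("C", 1, 0)]
    )
    def test_ll_pair_counts(self, smi, lag, expected):
        assert cats2d_pair_count(graph(smi), lag, "L", "L") == expected

    def test_lag_zero_counts_atoms_with_both_types(self):
        # hydroxyl O of an alcohol is both donor and acceptor
        assert cats2d_pair_count(graph("CO"), 0, "D", "A") == 1
        assert cats2d_pair_count(graph("CC"), 0, "L", "L") == 2

    def test_lag_out_of_range(self):
        with pytest.raises(ValueError):
            cats2d_pair_count(graph("CC"), 10, "L", "L")


class TestDescriptorMatrix:
    def _dataset(self, fixture_set):
        return Dataset(
            [CompoundRecord(id=f.name, smiles=f.smiles, pic50=5.0) for f in fixture_set]
        )

    def test_m09_columns_computed(self, fixture_set):
        dm = descriptor_matrix(self._dataset(fixture_set), M09_DESCRIPTORS)
        assert dm.values.shape == (len(fixture_set), 5)
        assert all(dm.provenance[c] == "computed" for c in M09_DESCRIPTORS)
        assert not dm.failed_ids

    def test_empty_request_valid(self, fixture_set):
        dm = descriptor_matrix(self._dataset(fixture_set), [])
        assert dm.values.shape == (len(fixture_set), 0)

    def test_missing_imported_columns_listed(self, fixture_set):
        with pytest.raises(KeyError, match="MATS4m"):
            descriptor_matrix(self._dataset(fixture_set), ["MATS4m", "G3i"])

    def test_imported_columns_merged(self, fixture_set):
        ds = self._dataset(fixture_set)
        imported = pd.DataFrame(
            {"MATS4m": np.linspace(0, 1, len(ds))}, index=ds.ids
        )
        dm = descriptor_matrix(ds, ["H-047", "MATS4m"], imported=imported)
        assert dm.provenance == {"H-047": "computed", "MATS4m": "imported"}
        assert dm.values["MATS4m"].tolist() == pytest.approx(np.linspace(0, 1, len(ds)))

    def test_csv_round_trip(self, fixture_set, tmp_path):
        dm = descriptor_matrix(self._dataset(fixture_set), M09_DESCRIPTORS)
        path = tmp_path / "dm.csv"
        dm.to_csv(path)
        back = D.DescriptorMatrix.from_csv(path)
        pd.testing.assert_frame_equal(back.values, dm.values)


class TestOracleAgreement:
    """The naive all-pairs enumeration reproduces every pair count."""

    def test_distances_match(self, fixture_graphs):
        for m in fixture_graphs.values():
            assert np.array_equal(
                oracle.brute_force_distances(m), m.topological_distances()
            )

    def test_f0x_matches(self, fixture_graphs):
        for m in fixture_graphs.values():
            for lag in range(1, 7):
                assert oracle.brute_force_f0x(m, "C", "C", lag) == f0x_pair_count(
                    m, "C", "C", lag
                )

    def test_cats_matches(self, fixture_graphs):
        for m in fixture_graphs.values():
            for lag in range(0, 6):
                for t1, t2 in [("L", "L"), ("D", "A"), ("A", "A"), ("D", "L")]:
                    assert oracle.brute_force_cats_pairs(
                        m, lag, t1, t2
                    ) == cats2d_pair_count(m, lag, t1, t2)
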