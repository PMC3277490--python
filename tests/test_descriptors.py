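"""Fingerprints, the 2D descriptor registry and matrix preprocessing.

Registry descriptors are cross-checked against independent slow
re-implementations (path enumeration, networkx distance matrices, hand
formulas) on both hand-picked and generated molecules.
"""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from ameskit.descriptors import (
    BONDI_RADII,
    DESCRIPTOR_REGISTRY,
    DescriptorPreprocessor,
    descriptor_matrix,
    descriptor_vector,
    ecfp_counts,
    preprocess,
)


class TestEcfpCounts:
    def test_invariant_to_atom_ordering(self):
        a = ecfp_counts("c1ccccc1CCN")
        b = ecfp_counts("NCCc1ccccc1")
        assert np.array_equal(a, b)

    def test_methane_radius0_single_environment(self):
        v = ecfp_counts("C", radius=0)
        assert v.sum() == 1 and (v > 0).sum() == 1

    def test_ethanol_radius1_environment_count(self):
        # 3 heavy atoms x radii {0, 1} = 6 environments; hashing cannot
        # change the total count.
        assert ecfp_counts("CCO", radius=1).sum() == 6

    def test_deterministic_across_calls(self):
        assert np.array_equal(ecfp_counts("CC(=O)Nc1ccccc1"), ecfp_counts("CC(=O)Nc1ccccc1"))

    def test_counts_nonnegative_integers(self):
        v = ecfp_counts("O=[N+]([O-])c1ccc2ccccc2c1")
        assert v.dtype.kind == "i" and (v >= 0).all()


# -- slow independent oracles -------------------------------------------------


def _graph(mol):
    g = nx.Graph()
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    return g


def slow_balaban_j(smiles):
    """Balaban's distance connectivity index via networkx shortest paths:
    J = m/(mu+1) * sum over edges 1/sqrt(s_i * s_j), s_i = distance sum."""
    mol = Chem.MolFromSmiles(smiles)
    g = _graph(mol)
    n, m = g.number_of_nodes(), g.number_of_edges()
    mu = m - n + 1
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    # bond-order weighted distances as in the RDKit implementation:
    # aromatic 1.5, double 2, triple 3 contribute shorter steps
    w = {}
    for b in mol.GetBonds():
        order = {Chem.BondType.SINGLE: 1.0, Chem.BondType.DOUBLE: 2.0,
                 Chem.BondType.TRIPLE: 3.0, Chem.BondType.AROMATIC: 1.5}[b.GetBondType()]
        w[(b.GetBeginAtomIdx(), b.GetEndAtomIdx())] = 1.0 / order
        w[(b.GetEndAtomIdx(), b.GetBeginAtomIdx())] = 1.0 / order
    wg = nx.Graph()
    for (i, j), weight in w.items():
        wg.add_edge(i, j, weight=weight)
    dist = dict(nx.all_pairs_dijkstra_path_length(wg))
    s = {i: sum(dist[i].values()) for i in g.nodes}
    total = sum(1.0 / math.sqrt(s[i] * s[j]) for i, j in g.edges)
    return m / (mu + 1.0) * total


def slow_chi0v_c(smiles):
    mol = Chem.MolFromSmiles(smiles)
    total = 0.0
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "C":
            dv = 4 - atom.GetTotalNumHs()
            total += 0.0 if dv <= 0 else dv ** -0.5
    return total


def slow_kier_flex(smiles):
    from rdkit.Chem import rdMolDescriptors

    mol = Chem.MolFromSmiles(smiles)
    g = _graph(mol)
    A = mol.GetNumHeavyAtoms()
    alpha = rdMolDescriptors.CalcHallKierAlpha(mol)
    p1 = g.number_of_edges()
    p2 = sum(1 for i in g for a in g[i] for b in g[i] if a < b)  # paths of length 2
    ka1 = (A + alpha) * (A + alpha - 1) ** 2 / (p1 + alpha) ** 2
    ka2 = (A + alpha - 1) * (A + alpha - 2) ** 2 / (p2 + alpha) ** 2
    return ka1 * ka2 / A


ORACLE_MOLECULES = [
    "CCCCCC", "c1ccccc1", "Nc1ccccc1", "CC(=O)Nc1ccc(Cl)cc1",
    "O=[N+]([O-])c1ccc2ccccc2c1", "CN(C)c1ccc(OC)cc1", "CCOC(=O)c1cccnc1",
    "c1ccc(-c2ccccc2)cc1", "CS(=O)(=O)Nc1ccccc1", "OCCOCCOc1ccccc1",
]


class TestRegistry:
    def test_benzene_bookkeeping(self):
        d = dict(zip(DESCRIPTOR_REGISTRY, descriptor_vector("c1ccccc1")))
        assert d["a_count"] == 12 and d["a_nH"] == 6 and d["a_nC"] == 6
        assert d["a_nO"] == 0 and d["b_rotN"] == 0

    def test_methane_density_from_pinned_volume_table(self):
        vol = 4 / 3 * math.pi * (BONDI_RADII["C"] ** 3 + 4 * BONDI_RADII["H"] ** 3)
        d = dict(zip(DESCRIPTOR_REGISTRY, descriptor_vector("C")))
        assert d["a_count"] == 5
        assert d["density"] == pytest.approx(16.043 / vol, rel=1e-3)

    def test_hexane_balaban_j_published_value(self):
        # worked value of Balaban's J for n-hexane is 2.339
        assert descriptor_vector("CCCCCC", ["balabanJ"])[0] == pytest.approx(2.339, abs=1e-3)

    @pytest.mark.parametrize("smiles", ORACLE_MOLECULES)
    def test_balaban_j_matches_slow_oracle(self, smiles):
        assert descriptor_vector(smiles, ["balabanJ"])[0] == pytest.approx(
            slow_balaban_j(smiles), rel=1e-6)

    @pytest.mark.parametrize("smiles", ORACLE_MOLECULES)
    def test_chi0v_c_matches_hand_formula(self, smiles):
        assert descriptor_vector(smiles, ["chi0v_C"])[0] == pytest.approx(
            slow_chi0v_c(smiles), rel=1e-9)

    @pytest.mark.parametrize("smiles", ORACLE_MOLECULES)
    def test_kier_flexibility_matches_path_enumeration(self, smiles):
        assert descriptor_vector(smiles, ["KierFlex"])[0] == pytest.approx(
            slow_kier_flex(smiles), rel=1e-9)

    def test_generated_molecules_match_counting_oracles(self, literature_set):
        ds, _ = literature_set
        for rec in ds.records[:20]:
            mol = Chem.AddHs(rec.mol())
            expected = {
                "a_count": mol.GetNumAtoms(),
                "a_nH": sum(a.GetSymbol() == "H" for a in mol.GetAtoms()),
                "a_nC": sum(a.GetSymbol() == "C" for a in mol.GetAtoms()),
                "a_nO": sum(a.GetSymbol() == "O" for a in mol.GetAtoms()),
            }
            got = dict(zip(expected, descriptor_vector(rec, list(expected))))
            assert got == expected

    def test_unknown_descriptor_errors(self):
        with pytest.raises(KeyError):
            descriptor_vector("CCO", ["no_such_descriptor"])

    def test_eigen_descriptors_finite_and_deterministic(self, literature_set):
        ds, _ = literature_set
        X1 = descriptor_matrix(ds, ["GCUT_SLOGP_3", "BCUT_SMR_3", "Q_VSA_POS"])
        X2 = descriptor_matrix(ds, ["GCUT_SLOGP_3", "BCUT_SMR_3", "Q_VSA_POS"])
        assert np.isfinite(X1.to_numpy()).all()
        pd.testing.assert_frame_equal(X1, X2)


class TestPreprocessor:
    def test_constant_column_removed(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        prep = DescriptorPreprocessor().fit(X)
        assert prep.removed_cols_ == ["b"]
        out = prep.transform(X)
        assert list(out.columns) == ["a"]

    def test_fit_columns_standardized(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out = DescriptorPreprocessor().fit(X).transform(X)
        assert out["a"].mean() == pytest.approx(0.0, abs=1e-8)
        assert out["a"].std(ddof=1) == pytest.approx(1.0, abs=1e-8)

    def test_test_rows_use_training_statistics(self):
        X = pd.DataFrame({"a": [0.0, 2.0, 10.0, 12.0]}, index=["t1", "t2", "e1", "e2"])
        out, prep = preprocess(X, fit_rows=["t1", "t2"])
        # training mean 1, sample sd sqrt(2) -> test rows transform with
        # those statistics, not their own standardization
        assert out.loc["e1", "a"] == pytest.approx(9.0 / math.sqrt(2))
        assert out.loc["e2", "a"] == pytest.approx(11.0 / math.sqrt(2))

    def test_idempotent_on_retained_columns(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        once = DescriptorPreprocessor().fit(X).transform(X)
        twice = DescriptorPreprocessor().fit(once).transform(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_all_columns_removed_errors(self):
        X = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(ValueError, match="all columns removed"):
            DescriptorPreprocessor().fit(X)

    def test_near_zero_variance_screen(self):
        col = np.ones(100)
        col[0] = 2.0  # freq ratio 99, unique pct 2 -> near-zero variance
        X = pd.DataFrame({"nzv": col, "ok": np.arange(100.0)})
        prep = DescriptorPreprocessor(near_zero=True).fit(X)
        assert prep.removed_cols_ == ["nzv"]
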