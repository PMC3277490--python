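"""ECFP count fingerprints and the 2D descriptor registry.

The registry implements a small set of classical 2D descriptors under
their customary names (atom counts, rotatable bonds, Balaban J, Kier-Hall
carbon valence connectivity, Kier flexibility, positive-charge van der
Waals surface area, Burden/graph-distance eigenvalue descriptors and
packing density).  Formulas are pinned to the original literature
definitions with explicit atomic-contribution tables; models built on
them are always retrained, so numeric parity with any particular vendor
implementation is not a goal.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, GraphDescriptors, rdFingerprintGenerator, rdMolDescriptors, rdPartialCharges
from sklearn.base import BaseEstimator, TransformerMixin

from .io import DataSet, MoleculeRecord

#: Bondi van der Waals radii (angstrom) for the packing-density volume.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}

_BOND_ORDER_WEIGHT = {
    Chem.BondType.SINGLE: 0.1,
    Chem.BondType.DOUBLE: 0.2,
    Chem.BondType.TRIPLE: 0.3,
    Chem.BondType.AROMATIC: 0.15,
}


def _as_mol(m) -> Chem.Mol:
    if isinstance(m, MoleculeRecord):
        return m.mol()
    if isinstance(m, str):
        mol = Chem.MolFromSmiles(m)
        if mol is None:
            raise ValueError(f"unparseable SMILES {m!r}")
        return mol
    return m


# ---------------------------------------------------------------------------
# Morgan count fingerprints


def ecfp_counts(m, radius: int = 3, n_slots: int = 1024, features: bool = False) -> np.ndarray:
    """Hashed circular Morgan count fingerprint (radius in bonds).

    Defaults give the ECFP6-style 1024-slot count vector used for the
    statistical models; ``features=True`` switches to functional-class
    atom invariants (FCFP-style), the variant used for chemical-space
    maps at radius 2.  Slot = environment hash mod ``n_slots``; collisions
    are accepted.  Invariant to input atom ordering.
    """
    mol = _as_mol(m)
    kwargs = {"radius": radius, "fpSize": n_slots}
    if features:
        kwargs["atomInvariantsGenerator"] = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
    gen = rdFingerprintGenerator.GetMorganGenerator(**kwargs)
    fp = gen.GetCountFingerprint(mol)
    vec = np.zeros(n_slots, dtype=np.int64)
    for slot, count in fp.GetNonzeroElements().items():
        vec[slot] = count
    return vec


def fingerprint_matrix(ds: DataSet, radius: int = 3, n_slots: int = 1024, features: bool = False) -> pd.DataFrame:
    rows = [ecfp_counts(r, radius, n_slots, features) for r in ds.records]
    cols = [f"Morgan{i:04d}" for i in range(n_slots)]
    return pd.DataFrame(np.asarray(rows), index=[r.id for r in ds.records], columns=cols)


# ---------------------------------------------------------------------------
# 2D descriptor registry


def _vdw_volume(mol_h: Chem.Mol) -> float:
    vol = 0.0
    for atom in mol_h.GetAtoms():
        r = BONDI_RADII.get(atom.GetSymbol())
        if r is None:
            raise ValueError(f"no van der Waals radius for {atom.GetSymbol()}")
        vol += 4.0 / 3.0 * math.pi * r**3
    return vol


def _a_count(mol):
    return Chem.AddHs(mol).GetNumAtoms()


def _element_count(mol, symbol):
    return sum(a.GetSymbol() == symbol for a in Chem.AddHs(mol).GetAtoms())


def _a_hyd(mol):
    """Hydrophobic atom count: carbons with no N/O/S/P neighbour, plus
    halogens (pinned definition)."""
    n = 0
    for atom in mol.GetAtoms():
        if atom.GetSymbol() in ("F", "Cl", "Br", "I"):
            n += 1
        elif atom.GetSymbol() == "C":
            if not any(nb.GetSymbol() in ("N", "O", "S", "P") for nb in atom.GetNeighbors()):
                n += 1
    return n


def _chi0v_C(mol):
    """Kier-Hall 0th-order valence connectivity restricted to carbon:
    sum over C atoms of 1/sqrt(delta_v), delta_v = 4 - n_H."""
    total = 0.0
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C":
            continue
        dv = 4 - atom.GetTotalNumHs()
        if dv > 0:
            total += 1.0 / math.sqrt(dv)
    return total


def _path2_count(mol) -> int:
    return sum(math.comb(a.GetDegree(), 2) for a in mol.GetAtoms())


def _kier_flex(mol):
    """Kier molecular flexibility: kappa_alpha1 * kappa_alpha2 / A."""
    A = mol.GetNumHeavyAtoms()
    if A < 3:
        return 0.0
    alpha = rdMolDescriptors.CalcHallKierAlpha(mol)
    p1 = mol.GetNumBonds()
    p2 = _path2_count(mol)
    if p1 == 0 or p2 == 0:
        return 0.0
    ka1 = (A + alpha) * (A + alpha - 1) ** 2 / (p1 + alpha) ** 2
    ka2 = (A + alpha - 1) * (A + alpha - 2) ** 2 / (p2 + alpha) ** 2
    return ka1 * ka2 / A


def _q_vsa_pos(mol):
    """Sum of Labute approximate-VSA atomic contributions over atoms with
    positive Gasteiger partial charge (hydrogens included)."""
    mol_h = Chem.AddHs(mol)
    rdPartialCharges.ComputeGasteigerCharges(mol_h)
    contribs, _ = rdMolDescriptors._CalcLabuteASAContribs(mol_h, includeHs=True)
    total = 0.0
    for atom, v in zip(mol_h.GetAtoms(), contribs):
        q = atom.GetDoubleProp("_GasteigerCharge")
        if np.isfinite(q) and q > 0:
            total += v
    return total


def _crippen_heavy_contribs(mol) -> tuple[np.ndarray, np.ndarray]:
    """Per-heavy-atom Crippen logP and molar-refractivity contributions,
    hydrogen contributions folded into the attached heavy atom."""
    mol_h = Chem.AddHs(mol)
    contribs = rdMolDescriptors._CalcCrippenContribs(mol_h)
    n_heavy = mol.GetNumHeavyAtoms()
    logp = np.zeros(n_heavy)
    mr = np.zeros(n_heavy)
    for atom, (lp, m) in zip(mol_h.GetAtoms(), contribs):
        if atom.GetAtomicNum() == 1:
            heavy = atom.GetNeighbors()[0].GetIdx()
            logp[heavy] += lp
            mr[heavy] += m
        else:
            logp[atom.GetIdx()] += lp
            mr[atom.GetIdx()] += m
    return logp, mr


def _gcut_slogp(mol, which: int = 3):
    """Eigenvalue descriptor of the modified graph-distance matrix:
    diagonal = Crippen logP atom contributions, off-diagonal = 1/d^2 for
    topological distance d.  ``which`` in 0..3 selects the ascending
    quartile eigenvalue (3 = largest)."""
    logp, _ = _crippen_heavy_contribs(mol)
    n = len(logp)
    if n == 1:
        return float(logp[0])
    d = Chem.GetDistanceMatrix(mol)
    with np.errstate(divide="ignore"):
        m = np.where(d > 0, 1.0 / np.maximum(d, 1.0) ** 2, 0.0)
    np.fill_diagonal(m, logp)
    eig = np.linalg.eigvalsh(m)
    idx = [0, max(0, round(n / 3) - 1), max(0, round(2 * n / 3) - 1), n - 1][which]
    return float(eig[idx])


def _bcut_smr(mol, which: int = 3):
    """Burden-matrix eigenvalue descriptor: diagonal = Crippen molar
    refractivity contributions, bonded off-diagonals = 0.1 x bond order
    (aromatic 1.5), all other entries 0.001."""
    _, mr = _crippen_heavy_contribs(mol)
    n = len(mr)
    if n == 1:
        return float(mr[0])
    m = np.full((n, n), 0.001)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        w = _BOND_ORDER_WEIGHT.get(bond.GetBondType(), 0.1)
        m[i, j] = m[j, i] = w
    np.fill_diagonal(m, mr)
    eig = np.linalg.eigvalsh(m)
    idx = [0, max(0, round(n / 3) - 1), max(0, round(2 * n / 3) - 1), n - 1][which]
    return float(eig[idx])


DESCRIPTOR_REGISTRY = {
    "a_count": _a_count,
    "a_nH": lambda mol: _element_count(mol, "H"),
    "a_nC": lambda mol: _element_count(mol, "C"),
    "a_nO": lambda mol: _element_count(mol, "O"),
    "a_hyd": _a_hyd,
    "b_rotN": lambda mol: rdMolDescriptors.CalcNumRotatableBonds(
        mol, rdMolDescriptors.NumRotatableBondsOptions.NonStrict
    ),
    "b_1rotN": lambda mol: rdMolDescriptors.CalcNumRotatableBonds(
        mol, rdMolDescriptors.NumRotatableBondsOptions.Strict
    ),
    "density": lambda mol: Descriptors.MolWt(mol) / _vdw_volume(Chem.AddHs(mol)),
    "balabanJ": GraphDescriptors.BalabanJ,
    "chi0v_C": _chi0v_C,
    "KierFlex": _kier_flex,
    "Q_VSA_POS": _q_vsa_pos,
    "GCUT_SLOGP_3": _gcut_slogp,
    "BCUT_SMR_3": _bcut_smr,
}

#: The compact subset carried into the reduced models (first-component
#: variables plus density and Balaban J); the planted reaction energy is
#: appended separately when available.
CORE_REGISTRY = (
    "chi0v_C", "GCUT_SLOGP_3", "a_count", "balabanJ", "a_nH",
    "density", "Q_VSA_POS", "BCUT_SMR_3",
)


def descriptor_vector(m, registry=None) -> np.ndarray:
    """Registry descriptor values for one molecule, in registry order."""
    mol = _as_mol(m)
    names = list(registry or DESCRIPTOR_REGISTRY)
    values = []
    for name in names:
        if name not in DESCRIPTOR_REGISTRY:
            raise KeyError(f"unknown descriptor {name!r}")
        values.append(float(DESCRIPTOR_REGISTRY[name](mol)))
    return np.asarray(values)


def descriptor_matrix(ds: DataSet, registry=None) -> pd.DataFrame:
    names = list(registry or DESCRIPTOR_REGISTRY)
    rows = [descriptor_vector(r, names) for r in ds.records]
    return pd.DataFrame(rows, index=[r.id for r in ds.records], columns=names)


# ---------------------------------------------------------------------------
# Preprocessing


class DescriptorPreprocessor(BaseEstimator, TransformerMixin):
    """Zero-variance column removal plus center/scale, fit on training
    rows only and applied unchanged to new rows.

    Parameters
    ----------
    near_zero : bool
        If true, additionally remove near-zero-variance columns using
        frequency-ratio / unique-percentage screens (``freq_ratio``,
        ``unique_pct``); default is strict zero variance only.
    """

    def __init__(self, near_zero: bool = False, freq_ratio: float = 95 / 5, unique_pct: float = 10.0):
        self.near_zero = near_zero
        self.freq_ratio = freq_ratio
        self.unique_pct = unique_pct

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray(X.columns)
        values = X.to_numpy(dtype=float)
        if not len(values):
            raise ValueError("no fit rows")
        sds = values.std(axis=0, ddof=0)
        drop = sds == 0.0
        if self.near_zero:
            for j in range(values.shape[1]):
                col = values[:, j]
                uniq, counts = np.unique(col, return_counts=True)
                if len(uniq) == 1:
                    continue  # already dropped
                counts = np.sort(counts)[::-1]
                ratio = counts[0] / counts[1]
                pct_unique = 100.0 * len(uniq) / len(col)
                if ratio > self.freq_ratio and pct_unique < self.unique_pct:
                    drop[j] = True
        if drop.all():
            raise ValueError("all columns removed by variance screen")
        self.removed_cols_ = list(np.asarray(X.columns)[drop])
        keep = ~drop
        self.kept_cols_ = list(np.asarray(X.columns)[keep])
        kept_values = values[:, keep]
        self.means_ = kept_values.mean(axis=0)
        self.sds_ = kept_values.std(axis=0, ddof=1)
        self.sds_[self.sds_ == 0.0] = 1.0  # single fit row: center only
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        missing = [c for c in self.kept_cols_ if c not in X.columns]
        if missing:
            raise ValueError(f"columns missing from input: {missing[:5]}")
        values = X[self.kept_cols_].to_numpy(dtype=float)
        out = (values - self.means_) / self.sds_
        return pd.DataFrame(out, index=X.index, columns=self.kept_cols_)


def preprocess(X, fit_rows, **kwargs) -> tuple[pd.DataFrame, DescriptorPreprocessor]:
    """Fit the variance screen and scaler on ``fit_rows`` (index labels)
    and transform the full matrix; returns (transformed, fitted
    preprocessor)."""
    X = pd.DataFrame(X)
    prep = DescriptorPreprocessor(**kwargs).fit(X.loc[fit_rows])
    return prep.transform(X), prep
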