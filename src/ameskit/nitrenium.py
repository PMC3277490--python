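"""Reactive-intermediate species generation and reaction-energy scoring
for aryl-amines.

The mutagenic activation of an aryl-amine proceeds through the
DNA-reactive nitrenium ion (ArNH:+).  Five bookkeeping reactions are
supported:

1. ArNH2          -> ArNH:+ + H-        (hydride loss)
2. ArNHOAc        -> ArNH:+ + AcO-      (N-acetoxy leaving group)
3. ArNHOH + H3O+  -> ArNH:+ + 2 H2O     (N-hydroxy, acid-promoted)
4. ArNH2          -> ArNH. + H.         (aminyl radical)
5. ArNH2 + H2O    -> ArNH- + H3O+       (amide anion)

Electronic-structure energies are never computed here: a pluggable
backend supplies ``energy(molecule_id, role, conformer_id)`` in hartree
and the conformer list per species; the module enforces atom/charge
balance and the lowest-conformer-wins rule, converts to kcal/mol, and
reports energies relative to aniline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .evaluation import RocCurve, auc as _auc, roc_curve as _roc

KCAL_PER_HARTREE = 627.509

ARYLAMINE_SITE = "[NX3;H2:1][c]"

#: Fixed reference structures for the small species in each equation.
REFERENCE_SPECIES = {
    "hydride": ("[H-]", -1, "singlet"),
    "h_atom": ("[H]", 0, "doublet"),
    "water": ("O", 0, "singlet"),
    "hydronium": ("[OH3+]", +1, "singlet"),
    "acetate": ("CC(=O)[O-]", -1, "singlet"),
}


@dataclass(frozen=True)
class Species:
    role: str
    smiles: str
    charge: int
    multiplicity: str  # lowest of the evaluated spin states is kept


@dataclass(frozen=True)
class ReactionEquation:
    id: int
    reactants: tuple
    products: tuple


EQUATIONS = {
    1: ReactionEquation(1, ("amine",), ("nitrenium", "hydride")),
    2: ReactionEquation(2, ("n_acetoxy",), ("nitrenium", "acetate")),
    3: ReactionEquation(3, ("n_hydroxy", "hydronium"), ("nitrenium", "water", "water")),
    4: ReactionEquation(4, ("amine",), ("aminyl_radical", "h_atom")),
    5: ReactionEquation(5, ("amine", "water"), ("amide_anion", "hydronium")),
}


@dataclass
class SpeciesSet:
    """An aryl-amine with its generated nitrenium/anion/radical species
    (reference small species included)."""

    parent_smiles: str
    site: int  # atom index of the amine nitrogen in the parent
    species: dict  # role -> Species


@dataclass
class ReactionEnergyRecord:
    molecule_id: str
    eq_id: int
    delta_e_abs: float  # kcal/mol
    delta_e_rel_aniline: float = float("nan")  # kcal/mol


def find_arylamine_sites(mol: Chem.Mol) -> list:
    """Atom indices of primary-aromatic-amine nitrogens."""
    patt = Chem.MolFromSmarts("[NX3;H2][c]")
    return sorted({m[0] for m in mol.GetSubstructMatches(patt)})


def _edit_amine(mol: Chem.Mol, site: int, charge: int, n_h: int, radicals: int = 0,
                attach: str | None = None) -> str:
    """Return SMILES of the parent with the amine nitrogen at ``site``
    edited (one H removed; optionally a leaving-group fragment attached)."""
    rw = Chem.RWMol(mol)
    n = rw.GetAtomWithIdx(site)
    n.SetNumExplicitHs(n_h)
    n.SetNoImplicit(True)
    n.SetFormalCharge(charge)
    n.SetNumRadicalElectrons(radicals)
    if attach is not None:
        frag = Chem.MolFromSmiles(attach)
        amap = {}
        combined = Chem.RWMol(rw)
        for atom in frag.GetAtoms():
            amap[atom.GetIdx()] = combined.AddAtom(atom)
        for bond in frag.GetBonds():
            combined.AddBond(amap[bond.GetBeginAtomIdx()], amap[bond.GetEndAtomIdx()], bond.GetBondType())
        combined.AddBond(site, amap[0], Chem.BondType.SINGLE)
        rw = combined
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def generate_species(parent, site: int | None = None) -> SpeciesSet:
    """Generate every species role for one designated amine site.

    With more than one primary aromatic amine and no ``site`` directive
    this raises; enumerate sites with :func:`enumerate_species_sets` and
    take the minimum formation energy (most reactive site).
    """
    mol = Chem.MolFromSmiles(parent) if isinstance(parent, str) else Chem.Mol(parent)
    if mol is None:
        raise ValueError("unparseable parent structure")
    sites = find_arylamine_sites(mol)
    if not sites:
        raise ValueError("no primary aromatic amine site in parent")
    if site is None:
        if len(sites) > 1:
            raise ValueError(
                f"multiple aryl-amine sites {sites}; pass site= or use enumerate_species_sets"
            )
        site = sites[0]
    elif site not in sites:
        raise ValueError(f"atom {site} is not an aryl-amine nitrogen (sites: {sites})")
    parent_smiles = Chem.MolToSmiles(mol)
    species = {
        "amine": Species("amine", parent_smiles, 0, "singlet"),
        # nitrenium is evaluated in both singlet and triplet states by the
        # backend; the lowest is kept (declared via multiplicity here).
        "nitrenium": Species("nitrenium", _edit_amine(mol, site, +1, 1), +1, "singlet|triplet"),
        "aminyl_radical": Species("aminyl_radical", _edit_amine(mol, site, 0, 1, radicals=1), 0, "doublet"),
        "amide_anion": Species("amide_anion", _edit_amine(mol, site, -1, 1), -1, "singlet"),
        "n_hydroxy": Species("n_hydroxy", _edit_amine(mol, site, 0, 1, attach="O"), 0, "singlet"),
        "n_acetoxy": Species("n_acetoxy", _edit_amine(mol, site, 0, 1, attach="OC(C)=O"), 0, "singlet"),
    }
    for role, (smi, charge, mult) in REFERENCE_SPECIES.items():
        species[role] = Species(role, smi, charge, mult)
    return SpeciesSet(parent_smiles=parent_smiles, site=site, species=species)


def enumerate_species_sets(parent) -> list:
    mol = Chem.MolFromSmiles(parent) if isinstance(parent, str) else Chem.Mol(parent)
    return [generate_species(mol, site=s) for s in find_arylamine_sites(mol)]


def _element_counts(smiles: str) -> dict:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    counts: dict = {}
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
    return counts


def check_balance(s: SpeciesSet, eq: ReactionEquation) -> None:
    """Raise unless elemental composition and total charge balance."""
    def side(roles):
        atoms: dict = {}
        charge = 0
        for role in roles:
            sp = s.species[role]
            for el, n in _element_counts(sp.smiles).items():
                atoms[el] = atoms.get(el, 0) + n
            charge += sp.charge
        return atoms, charge

    ra, rc = side(eq.reactants)
    pa, pc = side(eq.products)
    if ra != pa or rc != pc:
        raise ValueError(
            f"equation {eq.id} unbalanced: reactants {ra} charge {rc} vs products {pa} charge {pc}"
        )


class TableBackend:
    """Energy backend reading a precomputed table: CSV with columns
    (molecule_id, role, conformer_id, energy_hartree).  Reference small
    species are stored under molecule_id ``__ref__``."""

    REF_ID = "__ref__"

    def __init__(self, table: pd.DataFrame):
        required = {"molecule_id", "role", "conformer_id", "energy_hartree"}
        if not required <= set(table.columns):
            raise ValueError(f"energy table must have columns {sorted(required)}")
        self._table = table

    @classmethod
    def from_csv(cls, path) -> "TableBackend":
        return cls(pd.read_csv(path, dtype={"molecule_id": str, "role": str, "conformer_id": str}))

    def _rows(self, molecule_id: str, role: str) -> pd.DataFrame:
        if role in REFERENCE_SPECIES:
            molecule_id = self.REF_ID
        rows = self._table[(self._table.molecule_id == molecule_id) & (self._table.role == role)]
        if rows.empty:
            raise KeyError(f"backend has no energy for ({molecule_id!r}, {role!r})")
        return rows

    def conformers(self, molecule_id: str, role: str) -> list:
        return list(self._rows(molecule_id, role).conformer_id)

    def energy(self, molecule_id: str, role: str, conformer_id) -> float:
        rows = self._rows(molecule_id, role)
        match = rows[rows.conformer_id == conformer_id]
        if match.empty:
            raise KeyError(f"no conformer {conformer_id!r} for ({molecule_id!r}, {role!r})")
        return float(match.energy_hartree.iloc[0])


def _lowest_energy(backend, molecule_id: str, role: str) -> float:
    confs = backend.conformers(molecule_id, role)
    if not confs:
        raise KeyError(f"backend lists no conformers for ({molecule_id!r}, {role!r})")
    return min(backend.energy(molecule_id, role, c) for c in confs)


def reaction_energy(molecule_id: str, eq: ReactionEquation | int, backend) -> float:
    """Absolute reaction energy in kcal/mol: sum of lowest-conformer
    product energies minus sum of lowest-conformer reactant energies."""
    eq = EQUATIONS[eq] if isinstance(eq, int) else eq
    e_products = sum(_lowest_energy(backend, molecule_id, r) for r in eq.products)
    e_reactants = sum(_lowest_energy(backend, molecule_id, r) for r in eq.reactants)
    return (e_products - e_reactants) * KCAL_PER_HARTREE


def reaction_energy_records(
    molecule_ids, eq: ReactionEquation | int, backend, aniline_id: str = "aniline"
) -> list:
    """Reaction energies for a batch, reported relative to aniline
    (aniline itself is 0 by construction)."""
    eq = EQUATIONS[eq] if isinstance(eq, int) else eq
    try:
        e_aniline = reaction_energy(aniline_id, eq, backend)
    except KeyError as exc:
        raise KeyError(f"missing aniline reference ({aniline_id!r}): {exc}") from exc
    return [
        ReactionEnergyRecord(m, eq.id, e_abs, e_abs - e_aniline)
        for m, e_abs in ((m, reaction_energy(m, eq, backend)) for m in molecule_ids)
    ]


def single_descriptor_roc(energies, labels, lower_is_positive: bool = True) -> tuple[RocCurve, float]:
    """ROC from sweeping a cutoff over formation energies.

    Orientation is declared, not auto-flipped: by default a *lower*
    formation energy predicts Ames+ (easier nitrenium formation)."""
    energies = np.asarray(
        [e.delta_e_rel_aniline if isinstance(e, ReactionEnergyRecord) else e for e in energies],
        dtype=float,
    )
    curve = _roc(energies, labels, higher_is_positive=not lower_is_positive)
    return curve, _auc(curve)


def qm_descriptor_correlation(table: pd.DataFrame, labels, orientations: dict | None = None):
    """Pearson correlation matrix of per-molecule QM descriptors plus the
    single-parameter ROC AUC of each.

    Zero-variance descriptors yield NaN correlations (reported missing).
    ``orientations`` maps descriptor name -> ``lower_is_positive`` flag
    (default: lower value predicts Ames+, the formation-energy
    convention)."""
    table = pd.DataFrame(table)
    if len(table) < 3 or table.shape[1] < 2:
        raise ValueError("need at least 3 molecules and 2 descriptors")
    corr = table.corr(method="pearson")
    orientations = orientations or {}
    aucs = {}
    for col in table.columns:
        if table[col].std(ddof=0) == 0:
            aucs[col] = float("nan")
            continue
        _, a = single_descriptor_roc(
            table[col].to_numpy(), labels, lower_is_positive=orientations.get(col, True)
        )
        aucs[col] = a
    return corr, pd.Series(aucs, name="AUC")
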