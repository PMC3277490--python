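"""Reading, standardizing, deduplicating and summarizing Ames data sets.

Structures arrive as SDF or SMILES tables with per-source mutagenicity
labels.  Every record is reduced to an achiral canonical-tautomer key so
that stereoisomers and declared tautomer pairs collapse to one entry, and
duplicate entries from different sources are merged under a consensus rule:
a structure is Ames-positive if any contributing source reports a positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE = 1, 0

#: Accepted spellings for Ames outcomes in input files.  Mappings are
#: declared, never guessed: an unrecognized token raises.
LABEL_DIALECTS = {
    "01": {"1": POSITIVE, "0": NEGATIVE},
    "plusminus": {"+": POSITIVE, "-": NEGATIVE},
    "posneg": {"POS": POSITIVE, "NEG": NEGATIVE, "pos": POSITIVE, "neg": NEGATIVE},
}

#: SDF field layout of the public merged supplementary file: a membership
#: flag field per source and, when it is "1", a companion experimental
#: Ames field for that source.
SUPPLEMENTARY_FIELDS = {
    "hansen": ("Hansen", "HansenExpAmes"),
    "kazius": ("Kazius", "KaziusExpAmes"),
    "brambilla": ("BrambillaMarketedDrug", "BrambillaExpAmes"),
}


class StructureError(ValueError):
    """Raised when a structure cannot be sanitized or standardized."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One structure with per-source Ames labels.

    ``smiles`` is the achiral canonical-tautomer SMILES (the dedup key);
    ``labels`` maps a source name to 0/1; ``consensus`` is positive iff any
    source label is positive.
    """

    id: str
    smiles: str
    source_flags: frozenset = field(default_factory=frozenset)
    labels: dict = field(default_factory=dict)
    mw: float = 0.0

    @property
    def consensus(self) -> int:
        return POSITIVE if any(v == POSITIVE for v in self.labels.values()) else NEGATIVE

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:  # pragma: no cover - keys are produced by RDKit
            raise StructureError(f"stored key no longer parses: {self.smiles}")
        return m


@dataclass
class DataSet:
    name: str
    records: list
    dedup_applied: bool = False
    n_rejected: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def positives(self) -> int:
        return sum(r.consensus == POSITIVE for r in self.records)


@dataclass
class WeightSummary:
    n: int
    median_mw: float
    counts_in_ranges: dict
    iqr: float


_TAUTOMER_ENUMERATOR = None


def _tautomer_enumerator() -> rdMolStandardize.TautomerEnumerator:
    global _TAUTOMER_ENUMERATOR
    if _TAUTOMER_ENUMERATOR is None:
        _TAUTOMER_ENUMERATOR = rdMolStandardize.TautomerEnumerator()
    return _TAUTOMER_ENUMERATOR


def standardize_mol(mol: Chem.Mol) -> Chem.Mol:
    """Largest organic fragment, stereo stripped, canonical tautomer."""
    if mol is None:
        raise StructureError("structure is None")
    try:
        mol = rdMolStandardize.FragmentParent(mol)
        Chem.RemoveStereochemistry(mol)
        mol = _tautomer_enumerator().Canonicalize(mol)
    except Exception as exc:  # RDKit raises plain Exceptions on sanitize failure
        raise StructureError(f"standardization failed: {exc}") from exc
    if mol is None:
        raise StructureError("standardization produced no structure")
    return mol


def standardize_key(structure) -> str:
    """Deterministic achiral canonical-tautomer SMILES key.

    Stereoisomers map to one key (2D descriptors carry no chirality) and
    tautomer pairs collapse under the RDKit canonical-tautomer scheme
    (e.g. 2-hydroxypyridine and 2-pyridone share a key).
    """
    if isinstance(structure, str):
        mol = Chem.MolFromSmiles(structure)
        if mol is None:
            raise StructureError(f"unparseable SMILES: {structure!r}")
    else:
        mol = Chem.Mol(structure)
    return Chem.MolToSmiles(standardize_mol(mol))


def record_from_mol(mol: Chem.Mol, rec_id: str, source_flags=(), labels=None) -> MoleculeRecord:
    std = standardize_mol(Chem.Mol(mol))
    return MoleculeRecord(
        id=rec_id,
        smiles=Chem.MolToSmiles(std),
        source_flags=frozenset(source_flags),
        labels=dict(labels or {}),
        mw=Descriptors.MolWt(std),
    )


def _parse_label(raw: str, dialect: dict) -> int:
    token = raw.strip()
    if token not in dialect:
        raise ValueError(f"unknown label token {token!r} for declared dialect")
    return dialect[token]


def read_structure_file(
    path,
    format: str = "sdf",
    source_fields: dict | None = None,
    label_dialect: str | dict = "01",
    name: str | None = None,
    smiles_source: str = "table",
) -> DataSet:
    """Read an SDF or SMILES table into a :class:`DataSet`.

    ``source_fields`` maps a source name to ``(membership_field,
    label_field)`` pairs for SDF input (default: the public supplementary
    layout).  Unparseable records are counted and logged, not fatal; zero
    parseable records is an error.
    """
    dialect = LABEL_DIALECTS[label_dialect] if isinstance(label_dialect, str) else dict(label_dialect)
    records, n_rejected = [], 0
    if format == "sdf":
        source_fields = source_fields or SUPPLEMENTARY_FIELDS
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                n_rejected += 1
                logger.warning("rejected unparseable SDF record %d", i)
                continue
            flags, labels = set(), {}
            for source, (member_field, label_field) in source_fields.items():
                if member_field is not None:
                    if not (mol.HasProp(member_field) and mol.GetProp(member_field).strip() == "1"):
                        continue
                flags.add(source)
                if mol.HasProp(label_field):
                    labels[source] = _parse_label(mol.GetProp(label_field), dialect)
            rec_id = mol.GetProp("_Name") if mol.GetProp("_Name") else f"rec{i}"
            try:
                records.append(record_from_mol(mol, rec_id, flags, labels))
            except StructureError as exc:
                n_rejected += 1
                logger.warning("rejected record %s: %s", rec_id, exc)
    elif format == "smiles-table":
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                smi, rec_id = parts[0], parts[1] if len(parts) > 1 else f"rec{i}"
                labels = {}
                if len(parts) > 2:
                    labels[smiles_source] = _parse_label(parts[2], dialect)
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    n_rejected += 1
                    logger.warning("rejected unparseable SMILES line %d: %r", i, smi)
                    continue
                try:
                    records.append(record_from_mol(mol, rec_id, {smiles_source}, labels))
                except StructureError as exc:
                    n_rejected += 1
                    logger.warning("rejected record %s: %s", rec_id, exc)
    else:
        raise ValueError(f"unknown format {format!r}")
    if not records:
        raise ValueError("zero parseable records")
    return DataSet(name=name or str(path), records=records, n_rejected=n_rejected)


def write_structure_file(ds: DataSet, path, source_fields: dict | None = None) -> None:
    """Write a DataSet back to SDF in the supplementary field dialect."""
    source_fields = source_fields or SUPPLEMENTARY_FIELDS
    writer = Chem.SDWriter(str(path))
    try:
        for rec in ds.records:
            mol = rec.mol()
            mol.SetProp("_Name", rec.id)
            for source, (member_field, label_field) in source_fields.items():
                if source in rec.source_flags:
                    if member_field is not None:
                        mol.SetProp(member_field, "1")
                    if source in rec.labels:
                        mol.SetProp(label_field, str(rec.labels[source]))
            writer.write(mol)
    finally:
        writer.close()


def deduplicate_and_merge(ds: DataSet) -> DataSet:
    """One record per canonical key; flags and labels unioned.

    The merged label map keeps, per source, a positive if any duplicate
    reported one, so the consensus rule (any positive => positive) is
    preserved.  Idempotent.
    """
    merged: dict[str, MoleculeRecord] = {}
    order: list[str] = []
    for rec in ds.records:
        key = rec.smiles
        if key not in merged:
            merged[key] = rec
            order.append(key)
        else:
            prev = merged[key]
            labels = dict(prev.labels)
            for src, lab in rec.labels.items():
                labels[src] = POSITIVE if POSITIVE in (labels.get(src), lab) else lab
            merged[key] = replace(
                prev,
                source_flags=prev.source_flags | rec.source_flags,
                labels=labels,
            )
    return DataSet(
        name=ds.name,
        records=[merged[k] for k in order],
        dedup_applied=True,
        n_rejected=ds.n_rejected,
    )


def filter_by_weight(ds: DataSet, max_mw: float = 700.0) -> tuple[DataSet, int]:
    """Drop records heavier than ``max_mw`` g/mol (default 700); returns
    the filtered set and the number removed."""
    kept = [r for r in ds.records if r.mw <= max_mw]
    removed = len(ds.records) - len(kept)
    if removed:
        logger.info("filter_by_weight removed %d records > %.0f g/mol", removed, max_mw)
    return DataSet(ds.name, kept, ds.dedup_applied, ds.n_rejected), removed


def weight_summary(ds: DataSet, ranges=((0, 200), (200, 400), (400, 600), (600, 700))) -> WeightSummary:
    """Order-statistic median (even sets: mean of middle pair), IQR, and
    counts in half-open [lo, hi) molecular-weight ranges."""
    if not ds.records:
        raise ValueError("empty set")
    mws = np.array([r.mw for r in ds.records])
    q1, q3 = np.percentile(mws, [25, 75])
    counts = {
        (lo, hi): int(np.sum((mws >= lo) & (mws < hi))) for lo, hi in ranges
    }
    return WeightSummary(
        n=len(mws),
        median_mw=float(np.median(mws)),
        counts_in_ranges=counts,
        iqr=float(q3 - q1),
    )
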