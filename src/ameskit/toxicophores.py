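"""Mutagenic substructure ("toxicophore") matching and set profiling.

Each molecule receives exactly one class under a sequential priority
filter: the nitroaromatic query is tried first, then the aryl-amine
family, and anything matching no query falls into ``unspecified``.  The
class list and its order mirror the standard Kazius-style alert set for
aromatic amine chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from rdkit import Chem

from .io import DataSet, MoleculeRecord, POSITIVE

UNSPECIFIED = "unspecified"

#: Sequential class order; nitroaromatic always first.
CLASS_ORDER = (
    "Nitro",
    "ArNH2",
    "ArNHC(O)R",
    "ArNHMe",
    "ArNMe2",
    "aryl-amine alkylring",
    "ArNHSO2Me",
)

#: Exclusion queries applied when deriving aryl-amine-only sets: other
#: substructures with their own mutagenicity mechanism.
ARYLAMINE_EXCLUSIONS = (
    ("nitroaromatic", "c[$([NX3+](=O)[O-]),$([NX3](=O)=O)]"),
    ("N-nitroso", "[NX3][NX2]=O"),
    ("nitrile oxide", "[CX2]#[NX2+][O-]"),
)

PRIMARY_AROMATIC_AMINE = "[NX3;H2][c]"


@dataclass(frozen=True)
class Query:
    name: str
    smarts: str
    pattern: Chem.Mol


@dataclass
class QuerySet:
    """Ordered, compiled substructure queries with unique names."""

    queries: tuple

    def __post_init__(self):
        names = [q.name for q in self.queries]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate query names: {names}")

    def names(self) -> list:
        return [q.name for q in self.queries]


@dataclass
class ToxicophoreProfile:
    """Per-class molecule counts and Ames-positive rates for one set.

    ``counts``/``positives`` map class name -> count; percentages are
    derived views (exact fractions retained, integer rounding only in the
    rendered table).
    """

    set_name: str
    n_total: int
    counts: dict
    positives: dict

    def pct_of_set(self, cls: str) -> float:
        return 100.0 * self.counts[cls] / self.n_total

    def pct_positive(self, cls: str) -> float:
        n = self.counts[cls]
        return 100.0 * self.positives[cls] / n if n else float("nan")

    def table(self) -> pd.DataFrame:
        classes = list(self.counts)
        return pd.DataFrame(
            {
                "n_molecules": [self.counts[c] for c in classes],
                "pct_of_set": [round(self.pct_of_set(c)) for c in classes],
                "n_positive": [self.positives[c] for c in classes],
                "pct_positive": [
                    round(self.pct_positive(c)) if self.counts[c] else 0 for c in classes
                ],
            },
            index=classes,
        )


def _compile(name: str, smarts: str) -> Query:
    patt = Chem.MolFromSmarts(smarts)
    if patt is None:
        raise ValueError(f"query {name!r} does not compile: {smarts!r}")
    return Query(name, smarts, patt)


def load_queries(path) -> QuerySet:
    """Load an ordered QuerySet from a directory of ``NN_name.smarts``
    files (sorted by filename; a leading ``NN_`` rank is stripped)."""
    files = sorted(Path(path).glob("*.smarts"))
    if not files:
        raise ValueError(f"no .smarts queries in {path}")
    queries = []
    for f in files:
        lines = [
            ln.strip()
            for ln in f.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        if len(lines) != 1:
            raise ValueError(f"{f.name}: expected exactly one SMARTS line")
        stem = f.stem
        name = stem.split("_", 1)[1] if stem[:2].isdigit() and "_" in stem else stem
        queries.append(_compile(name, lines[0]))
    return QuerySet(tuple(queries))


def builtin_queries() -> QuerySet:
    """The packaged sequential toxicophore query set."""
    with resources.as_file(resources.files("ameskit") / "queries") as qdir:
        return load_queries(qdir)


def exclusion_queries() -> QuerySet:
    return QuerySet(tuple(_compile(n, s) for n, s in ARYLAMINE_EXCLUSIONS))


def _as_mol(m) -> Chem.Mol:
    return m.mol() if isinstance(m, MoleculeRecord) else m


def sequential_class(m, qs: QuerySet) -> str:
    """First matching class in priority order, else ``unspecified``."""
    mol = _as_mol(m)
    for q in qs.queries:
        if mol.HasSubstructMatch(q.pattern):
            return q.name
    return UNSPECIFIED


def profile(ds: DataSet, qs: QuerySet | None = None) -> ToxicophoreProfile:
    """Sequential-class counts and Ames+ rates for a deduplicated set."""
    if not ds.records:
        raise ValueError("empty set")
    qs = qs or builtin_queries()
    classes = qs.names() + [UNSPECIFIED]
    counts = {c: 0 for c in classes}
    positives = {c: 0 for c in classes}
    for rec in ds.records:
        cls = sequential_class(rec, qs)
        counts[cls] += 1
        if rec.consensus == POSITIVE:
            positives[cls] += 1
    return ToxicophoreProfile(ds.name, len(ds.records), counts, positives)


def extract_arylamines(
    ds: DataSet,
    qs: QuerySet | None = None,
    exclusions: QuerySet | None = None,
) -> DataSet:
    """Aryl-amine subset: records containing a primary aromatic amine and
    none of the exclusion substructures (nitroaromatic, N-nitroso, ...)."""
    amine = Chem.MolFromSmarts(PRIMARY_AROMATIC_AMINE)
    exclusions = exclusions or exclusion_queries()
    kept = []
    for rec in ds.records:
        mol = rec.mol()
        if not mol.HasSubstructMatch(amine):
            continue
        if any(mol.HasSubstructMatch(q.pattern) for q in exclusions.queries):
            continue
        kept.append(rec)
    return DataSet(f"{ds.name}/arylamines", kept, ds.dedup_applied, 0)
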