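"""End-to-end study orchestration: validated run configuration and the
profile / modeling / cross-set / SOM pipelines behind the CLI.

Every run writes a serialized copy of its configuration and a JSON
metadata record (seed, grammar version, package version) into the output
directory so any two runs with identical config and seed produce
identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .descriptors import fingerprint_matrix
from .evaluation import vertical_average
from .io import DataSet, deduplicate_and_merge, filter_by_weight, read_structure_file, weight_summary
from .models import ForestOOBClassifier, PlsClassifier, cross_set_evaluate, repeated_resampling
from .som import SelfOrganizingMap, cell_summary
from .synth import GRAMMAR_VERSION, builtin_profiles, generate_set
from .toxicophores import builtin_queries, profile as toxicophore_profile

logger = logging.getLogger(__name__)


@dataclass
class SetSpec:
    """One input set: either a file path or a synthetic profile."""

    name: str
    path: str | None = None
    format: str = "sdf"
    synthetic_profile: str | None = None
    n: int = 1000

    def validate(self):
        if (self.path is None) == (self.synthetic_profile is None):
            raise ValueError(f"set {self.name!r}: give exactly one of path / synthetic_profile")
        if self.path is not None and not Path(self.path).exists():
            raise ValueError(f"set {self.name!r}: missing input file {self.path}")
        if self.synthetic_profile is not None and self.synthetic_profile not in builtin_profiles():
            raise ValueError(f"set {self.name!r}: unknown profile {self.synthetic_profile!r}")


@dataclass
class RunConfig:
    sets: list = field(default_factory=list)
    seed: int = 0
    out_dir: str = "ameskit-out"
    max_mw: float = 700.0
    fp_radius: int = 3
    fp_slots: int = 1024
    model: str = "forest"  # or "pls"
    n_components: int = 1
    n_trees: int = 500
    n_reps: int = 100
    train_fraction: float = 0.7
    som_rows: int = 30
    som_cols: int = 30
    som_epochs: int = 100

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sets = [SetSpec(**s) for s in raw.pop("sets", [])]
        cfg = cls(sets=sets, **raw)
        cfg.validate()
        return cfg

    def validate(self):
        if not self.sets:
            raise ValueError("config lists no input sets")
        for s in self.sets:
            s.validate()
        if self.model not in ("forest", "pls"):
            raise ValueError(f"unknown model kind {self.model!r}")

    def dump(self, out_dir: Path):
        payload = asdict(self)
        with open(out_dir / "run_config.yaml", "w") as fh:
            yaml.safe_dump(payload, fh)
        with open(out_dir / "run_metadata.json", "w") as fh:
            json.dump({"seed": self.seed, "grammar_version": GRAMMAR_VERSION,
                       "ameskit_version": __version__}, fh, indent=2)


def _prepare_out(config: RunConfig) -> Path:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.dump(out)
    return out


def load_sets(config: RunConfig) -> dict:
    """Load or generate every configured set, deduplicate, apply the
    molecular-weight exclusion."""
    sets = {}
    for i, spec in enumerate(config.sets):
        if spec.synthetic_profile is not None:
            ds = generate_set(builtin_profiles()[spec.synthetic_profile], spec.n,
                              seed=config.seed + i)
        else:
            ds = read_structure_file(spec.path, format=spec.format, name=spec.name)
        ds = deduplicate_and_merge(ds)
        ds, n_removed = filter_by_weight(ds, config.max_mw)
        ds.name = spec.name
        logger.info("set %s: %d records (%d over %g g/mol removed)",
                    spec.name, len(ds), n_removed, config.max_mw)
        sets[spec.name] = ds
    return sets


def _labels(ds: DataSet) -> np.ndarray:
    return np.array([r.consensus for r in ds.records])


def run_profile_report(config: RunConfig) -> dict:
    """Set sizes, positive counts, sequential toxicophore tables and MW
    summaries; histogram figure per set."""
    out = _prepare_out(config)
    sets = load_sets(config)
    queries = builtin_queries()
    summary_rows, profiles = [], {}
    for name, ds in sets.items():
        ws = weight_summary(ds)
        summary_rows.append({
            "set": name, "n": len(ds), "n_positive": ds.positives(),
            "pct_positive": round(100.0 * ds.positives() / len(ds), 1),
            "median_mw": round(ws.median_mw, 1), "iqr_mw": round(ws.iqr, 1),
            "n_400_600": ws.counts_in_ranges.get((400, 600), 0),
        })
        prof = toxicophore_profile(ds, queries)
        profiles[name] = prof.table()
        prof.table().to_csv(out / f"toxicophores_{name}.csv")
    summary = pd.DataFrame(summary_rows).set_index("set")
    summary.to_csv(out / "set_summary.csv")
    _mw_histograms(sets, out / "mw_distributions.png")
    return {"summary": summary, "profiles": profiles, "sets": sets}


def _mw_histograms(sets: dict, path: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    bins = np.arange(0, 720, 20)
    for name, ds in sets.items():
        ax.hist([r.mw for r in ds.records], bins=bins, histtype="step", label=name, density=True)
    ax.set_xlabel("molecular weight (g/mol)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _model_factory(config: RunConfig):
    if config.model == "pls":
        return lambda seed: PlsClassifier(n_components=config.n_components)
    from .models import ForestSpec

    return lambda seed: ForestOOBClassifier(ForestSpec(n_trees=config.n_trees), seed=seed)


def run_modeling(config: RunConfig) -> dict:
    """Repeated-resampling evaluation per set; per-rep AUC tables,
    summary table, and averaged-ROC plots."""
    out = _prepare_out(config)
    sets = load_sets(config)
    factory = _model_factory(config)
    results, rows = {}, []
    for name, ds in sets.items():
        X = fingerprint_matrix(ds, config.fp_radius, config.fp_slots)
        res = repeated_resampling(X, _labels(ds), factory, n_reps=config.n_reps,
                                  train_fraction=config.train_fraction, seed=config.seed)
        res.per_rep_table().to_csv(out / f"resampling_{name}.csv", index=False)
        avg = res.averaged("test") if res.test_curves else res.averaged("train")
        pd.DataFrame({"fpr": avg.fpr_grid, "mean_tpr": avg.mean_tpr, "sd_tpr": avg.sd_tpr}).to_csv(
            out / f"roc_avg_{name}.csv", index=False)
        _roc_plot(res, out / f"roc_avg_{name}.png", title=f"{config.model} on {name}")
        rows.append({"set": name, "model": config.model, **res.summary()})
        results[name] = res
    pd.DataFrame(rows).set_index("set").to_csv(out / "model_summary.csv")
    return results


def _roc_plot(res, path: Path, title: str = ""):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for role, color in (("train", "tab:red"), ("test", "tab:green")):
        curves = res.train_curves if role == "train" else res.test_curves
        if not curves:
            continue
        avg = vertical_average(curves)
        ax.plot(avg.fpr_grid, avg.mean_tpr, color=color, label=role)
        ax.errorbar(avg.fpr_grid[::10], avg.mean_tpr[::10], yerr=avg.sd_tpr[::10],
                    fmt="none", ecolor=color, alpha=0.6)
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def run_crossset(config: RunConfig) -> pd.DataFrame:
    """Train on 100% of each set, evaluate on every other set: the
    within/transfer AUC table."""
    out = _prepare_out(config)
    sets = load_sets(config)
    if len(sets) < 2:
        raise ValueError("cross-set evaluation needs at least two sets")
    factory = _model_factory(config)
    matrices = {n: fingerprint_matrix(ds, config.fp_radius, config.fp_slots) for n, ds in sets.items()}
    rows = []
    for train_name, train_ds in sets.items():
        for test_name, test_ds in sets.items():
            if test_name == train_name:
                continue
            res = cross_set_evaluate(matrices[train_name], _labels(train_ds),
                                     matrices[test_name], _labels(test_ds),
                                     factory, seed=config.seed)
            rows.append({"train": train_name, "test": train_name, "auc": round(res.train_auc, 3)})
            rows.append({"train": train_name, "test": test_name, "auc": round(res.test_auc, 3)})
    table = pd.DataFrame(rows).drop_duplicates().pivot(index="train", columns="test", values="auc")
    table.to_csv(out / "crossset_auc.csv")
    return table


def run_som_maps(config: RunConfig) -> dict:
    """Train a hexagonal SOM on radius-2 functional-class fingerprints,
    write cell summaries and property/error maps."""
    out = _prepare_out(config)
    sets = load_sets(config)
    parts = []
    for name, ds in sets.items():
        X = fingerprint_matrix(ds, radius=2, n_slots=config.fp_slots, features=True)
        parts.append((name, ds, X))
    X_all = pd.concat([p[2] for p in parts])
    som = SelfOrganizingMap(rows=config.som_rows, cols=config.som_cols,
                            epochs=config.som_epochs, seed=config.seed).fit(X_all)
    som.to_json(out / "som_codebook.json")
    assignments = som.predict(X_all)
    labels = np.concatenate([_labels(p[1]) for p in parts])
    flags = {
        name: np.concatenate([np.full(len(p[1]), p[0] == name) for p in parts]).astype(float)
        for name in sets
    }
    predictions = None
    if len(sets) >= 1 and config.n_trees > 0:
        factory = _model_factory(config)
        try:
            from .descriptors import DescriptorPreprocessor

            prep = DescriptorPreprocessor().fit(X_all)
            model = factory(config.seed).fit(prep.transform(X_all), labels)
            predictions = getattr(model, "oob_scores_", None)
        except ValueError as exc:
            logger.warning("error maps skipped: %s", exc)
    summary = cell_summary(som.n_cells, assignments, labels=labels,
                           predictions=predictions, flags=flags)
    summary.to_csv(out / "som_cells.csv", index=False)
    _hex_map(som, summary, out / "som_map.png")
    return {"som": som, "assignments": assignments, "cells": summary}


def _hex_map(som: SelfOrganizingMap, cells: pd.DataFrame, path: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows, cols = som.rows, som.cols
    r, c = np.divmod(cells["cell"].to_numpy(), cols)
    x = c + 0.5 * (r % 2)
    y = r * np.sqrt(3) / 2
    color_col = "mae" if "mae" in cells and cells["mae"].notna().any() else "frac_positive"
    fig, ax = plt.subplots(figsize=(6, 6))
    sc = ax.scatter(x, y, c=cells[color_col], s=np.clip(cells["n"], 0, 60) * 4 + 4,
                    marker="h", cmap="RdYlGn_r")
    fig.colorbar(sc, ax=ax, label=color_col)
    ax.set_aspect("equal")
    ax.set_title("SOM cells")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def run_synth(config: RunConfig) -> dict:
    """Generate the configured synthetic sets and write them as SDF."""
    out = _prepare_out(config)
    from .io import write_structure_file

    written = {}
    for i, spec in enumerate(config.sets):
        if spec.synthetic_profile is None:
            continue
        ds = generate_set(builtin_profiles()[spec.synthetic_profile], spec.n, seed=config.seed + i)
        path = out / f"{spec.name}.sdf"
        write_structure_file(ds, path, source_fields={
            spec.synthetic_profile: (None, f"{spec.synthetic_profile}Ames")})
        written[spec.name] = path
    if not written:
        raise ValueError("no synthetic sets configured")
    return written
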