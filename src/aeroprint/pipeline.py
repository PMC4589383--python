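"""End-to-end orchestration: configuration, ingestion, pipeline runs.

A pipeline run chains simulate -> features -> classify -> qc on a named
factorial design (``ideal`` = 108 samples, ``realistic`` = 324 samples, or
a custom YAML design), writing a feature table, CV reports, quality-control
outputs and a manifest with per-output checksums.  External feature tables
with the same schema (a disease-level label column plus 32 or 36 numeric
fractal features) can be ingested in place of the synthetic route.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, fractal, quality, synth

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "ParseError",
    "ingest_feature_table",
    "run_pipeline",
    "load_design",
]

log = logging.getLogger("aeroprint")

__version__ = "0.1.0"


class ParseError(ValueError):
    """Feature-table ingestion failure, naming the offending column/row."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, YAML round-trippable."""

    design: str = "ideal"            # ideal | realistic | path to YAML design
    seed: int = 0
    n_particles: int = 10000
    raster_width: int = 512
    grid_rows: int = 6
    grid_cols: int = 6
    svm_c: float = 100.0
    svm_gamma: float = 1.0 / 32.0
    k_folds: int = 10
    repeats: int = 2
    label: str = "D"                 # D | Q
    linkage: str = "complete"
    out_dir: str = "aeroprint_out"
    render_figures: bool = True
    write_positions: bool = False
    generator: dict = field(default_factory=dict)  # GeneratorConstants overrides

    def __post_init__(self):
        if self.label not in ("D", "Q"):
            raise ValueError("label must be 'D' or 'Q'")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def generator_constants(self) -> synth.GeneratorConstants:
        base = synth.DEFAULT_CONSTANTS.to_dict()
        base.update(self.generator)
        return synth.GeneratorConstants.from_dict(base)


@dataclass
class RunManifest:
    """Record of one pipeline run: config snapshot, seeds, output checksums."""

    config: dict
    version: str
    seed: int
    outputs: dict            # path -> sha256
    stages: list
    started: float
    finished: float

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_design(name_or_path: str, n_particles: int = 10000) -> synth.ExperimentDesign:
    """Resolve a design name (ideal/realistic) or custom YAML design file."""
    if name_or_path == "ideal":
        return synth.ideal_design(n_particles=n_particles)
    if name_or_path == "realistic":
        return synth.realistic_design(n_particles=n_particles)
    spec = yaml.safe_load(Path(name_or_path).read_text())
    return synth.ExperimentDesign(
        flow_rates=tuple(spec["flow_rates"]),
        disease_levels=tuple(spec["disease_levels"]),
        particle_diameters=tuple(spec["particle_diameters"]),
        ua_variants=tuple(spec.get("ua_variants", ["control"])),
        replicates_per_cell=int(spec.get("replicates_per_cell", 1)),
        n_particles=int(spec.get("n_particles", n_particles)),
    )


def ingest_feature_table(
    path,
    label_columns: tuple[str, ...] = ("D",),
    feature_columns: list[str] | None = None,
    id_column: str = "sample_id",
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Read an external per-sample feature table (CSV/TSV/XLSX export).

    Returns ``(X, labels, retained_mask)`` where X holds the numeric
    feature columns after zero-variance pruning (36-column inputs drop the
    constant columns; 32-column inputs pass through), labels holds the id
    and label columns.  Missing or non-numeric cells raise a
    :class:`ParseError` naming the row and column.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        table = pd.read_excel(path)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        table = pd.read_csv(path, sep=sep)
    for col in label_columns:
        if col not in table.columns:
            raise ParseError(f"missing label column {col!r}")
    if feature_columns is None:
        feature_columns = [
            c
            for c in table.columns
            if c not in label_columns and c != id_column and pd.api.types.is_numeric_dtype(table[c])
        ]
        # common schema: f01..f36
        named = [c for c in table.columns if c.startswith("f") and c[1:].isdigit()]
        if named:
            feature_columns = named
    if len(feature_columns) not in (32, 36):
        raise ParseError(
            f"expected 32 or 36 feature columns, found {len(feature_columns)}"
        )
    for col in feature_columns:
        series = pd.to_numeric(table[col], errors="coerce")
        if series.isna().any():
            row = int(series.isna().idxmax())
            raise ParseError(f"missing or non-numeric value at row {row}, column {col!r}")
        table[col] = series
    X = table[feature_columns].to_numpy(dtype=float)
    if X.shape[1] == 36:
        X, mask = fractal.remove_zero_variance(X)
    else:
        mask = np.ones(32, dtype=bool)
    label_cols = [c for c in (id_column, *label_columns) if c in table.columns]
    labels = table[label_cols].copy()
    if id_column not in labels.columns:
        labels[id_column] = [f"S{i + 1}" for i in range(len(table))]
    return pd.DataFrame(X), labels, mask


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """simulate -> features -> classify -> qc, with a checksummed manifest.

    Any stage failure raises with the stage name; outputs already written
    stay on disk for inspection.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    stages: list[str] = []
    stage = "simulate"
    try:
        log.info("stage %s: design=%s seed=%d", stage, config.design, config.seed)
        design = load_design(config.design, n_particles=config.n_particles)
        dataset = synth.generate_dataset(
            design, seed=config.seed, constants=config.generator_constants()
        )
        manifest_path = out / "samples.csv"
        dataset.manifest.to_csv(manifest_path, index=False)
        outputs[str(manifest_path)] = _sha256(manifest_path)
        if config.write_positions:
            pos_path = out / "positions.csv"
            pd.concat(
                [
                    fp.to_dataframe(sid)
                    for fp, sid in zip(dataset.fingerprints, dataset.manifest["sample_id"])
                ],
                ignore_index=True,
            ).to_csv(pos_path, index=False)
            outputs[str(pos_path)] = _sha256(pos_path)
        stages.append(stage)

        stage = "features"
        log.info("stage %s: raster=%d grid=%dx%d", stage, config.raster_width,
                 config.grid_rows, config.grid_cols)
        grid = fractal.GridSpec(rows=config.grid_rows, cols=config.grid_cols)
        table = fractal.extract_feature_table(dataset, width_px=config.raster_width, grid=grid)
        feat_path = out / "features.csv"
        table.to_csv(feat_path, index=False)
        outputs[str(feat_path)] = _sha256(feat_path)
        X36 = table[fractal.FEATURE_COLUMNS].to_numpy()
        X, mask = fractal.remove_zero_variance(X36)
        mask_path = out / "retained_mask.json"
        mask_path.write_text(json.dumps({"retained_mask": mask.tolist()}))
        outputs[str(mask_path)] = _sha256(mask_path)
        stages.append(stage)

        stage = "classify"
        label_col = "D" if config.label == "D" else "Q_lpm"
        y = table[label_col].to_numpy()
        ids = table["sample_id"].to_numpy()
        params = classify.SVMParams(C=config.svm_c, gamma=config.svm_gamma)
        log.info("stage %s: label=%s k=%d seed=%d", stage, config.label,
                 config.k_folds, config.seed)
        stability = classify.repeat_cv_stability(
            X, y, k=config.k_folds,
            seeds=[config.seed + r for r in range(max(config.repeats, 2))],
            params=params, sample_ids=ids,
        )
        report = stability.reports[0]
        cv_path = out / "cv_report.json"
        cv_path.write_text(
            json.dumps(
                {
                    "runs": [r.to_dict() for r in stability.reports],
                    "persistent_misclassifications": sorted(stability.intersection),
                },
                indent=2,
            )
        )
        outputs[str(cv_path)] = _sha256(cv_path)
        cm_path = out / "confusion_matrix.csv"
        pd.DataFrame(
            report.confusion_matrix,
            index=[str(c) for c in report.classes],
            columns=[str(c) for c in report.classes],
        ).to_csv(cm_path)
        outputs[str(cm_path)] = _sha256(cm_path)
        stages.append(stage)

        stage = "qc"
        log.info("stage %s: linkage=%s", stage, config.linkage)
        dm = quality.distance_matrix(X, sample_ids=ids)
        combos = np.array(
            [f"D{d}/Q{int(q)}" for d, q in zip(table["D"], table["Q_lpm"])]
        )
        tree = quality.hierarchical_subgroups(dm, linkage=config.linkage, labels=combos)
        dm_path = out / "distance_matrix.csv"
        dm.to_dataframe().to_csv(dm_path)
        outputs[str(dm_path)] = _sha256(dm_path)
        sub_path = out / "subgroups.csv"
        pd.DataFrame(
            {"sample_id": ids, "subgroup": tree.subgroups, "combo": combos}
        ).to_csv(sub_path, index=False)
        outputs[str(sub_path)] = _sha256(sub_path)
        dossier = quality.forensics(report, dm, tree)
        dossier_path = out / "forensics.json"
        dossier_path.write_text(json.dumps(dossier, indent=2))
        outputs[str(dossier_path)] = _sha256(dossier_path)
        if config.render_figures:
            pca = quality.pca3(X)
            for f in quality.render(
                out, dm=dm, tree=tree, pca=pca, pca_labels=table["D"].to_numpy(),
                anova_values=X[:, 2], anova_groups=table["D"].to_numpy(),
            ):
                outputs[f] = _sha256(Path(f))
        stages.append(stage)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        version=__version__,
        seed=config.seed,
        outputs=outputs,
        stages=stages,
        started=t0,
        finished=time.time(),
    )
    manifest.to_json(out / "manifest.json")
    return manifest
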