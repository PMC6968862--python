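"""End-to-end orchestration: simulate -> preprocess -> connectivity ->
features -> outlier screening -> experiments -> classification -> summary.

Configuration is a flat dataclass round-trippable through YAML/JSON; a
run emits all intermediate artifacts under an output directory plus a
manifest recording the config, software version, timestamps and output
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .bands import CANONICAL_BANDS, get_band
from .cohort_selection import (
    define_experiments,
    detect_outliers,
    remove_outliers,
    silhouette_scores,
)
from .connectivity import band_average, coherence_spectrum, threshold_normalize
from .graph_features import all_feature_tables
from .io import (
    feature_table_filename,
    write_event_log,
    write_feature_table,
    write_ground_truth,
    write_matrix,
)
from .preprocessing import FlagCriteria, remove_artifacts, select_windows, surface_laplacian
from .synthetic import SimConfig, generate_cohort
from .tree import cross_validate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters and toggles for one pipeline run."""

    # simulation
    n_subjects_per_class: int = 5
    planted_band: str = "alpha"
    planted_electrodes: tuple[str, ...] = ("T3", "Cz")
    coupling_ha: float = 0.2
    coupling_aa: float = 0.45
    coupling_la: float = 0.8
    n_epochs: int = 57
    noise_exponent: float = 1.0
    # preprocessing
    run_ica: bool = False
    ica_seed: int = 0
    flag_frontal_corr: float = 0.7
    flag_hf_ratio: float = 0.6
    flag_kurtosis: float = 10.0
    run_laplacian: bool = True
    spline_order: int = 4
    spline_regularization: float = 1e-5
    # connectivity
    nfft: int = 256
    binarize: bool = False
    # outliers
    outlier_positive_fraction: float = 0.70
    outlier_min_variants: int = 1
    # classification
    confidence_factor: float = 0.25
    min_leaf: int = 2
    cv_folds: int = 10
    cv_repeats: int = 10
    # seeds
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["planted_electrodes"] = list(self.planted_electrodes)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "planted_electrodes" in kwargs:
            kwargs["planted_electrodes"] = tuple(kwargs["planted_electrodes"])
        cfg = cls(**kwargs)
        get_band(cfg.planted_band)  # validate before any work
        return cfg

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_subjects_per_class=self.n_subjects_per_class,
            planted_band=self.planted_band,
            planted_electrodes=self.planted_electrodes,
            coupling_strength_by_class={
                "HA": self.coupling_ha, "AA": self.coupling_aa, "LA": self.coupling_la,
            },
            n_epochs_per_subject=self.n_epochs,
            noise_exponent=self.noise_exponent,
            seed=self.seed,
        )


@dataclass
class RunManifest:
    config: dict
    version: str
    started: str
    finished: str = ""
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    removed_outliers: list[str] = field(default_factory=list)
    summary: list[dict] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute every stage on a simulated cohort and write all artifacts.

    Produces per-subject connectivity matrices, the 15 feature tables,
    an outlier report, the 90 experiment datasets, per-dataset CV
    accuracies, and a summary table of the best accuracy per class pair.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        version=__version__,
        started=datetime.now(timezone.utc).isoformat(),
    )

    def _record(path: Path) -> None:
        manifest.outputs[str(path.relative_to(out))] = _sha256(path)

    # --- simulate
    sim = config.sim_config()
    recordings, logs, truth = generate_cohort(sim)
    write_ground_truth(truth, out / "ground_truth.json")
    _record(out / "ground_truth.json")
    labels = truth.subject_classes

    # --- preprocess + connectivity
    criteria = FlagCriteria(
        frontal_corr=config.flag_frontal_corr,
        hf_ratio=config.flag_hf_ratio,
        kurtosis=config.flag_kurtosis,
    )
    matrices_by_band: dict[str, list] = {b.name: [] for b in CANONICAL_BANDS}
    mat_dir = out / "connectivity"
    mat_dir.mkdir(exist_ok=True)
    ev_dir = out / "events"
    ev_dir.mkdir(exist_ok=True)
    for rec, log in zip(recordings, logs):
        write_event_log(log, ev_dir / f"{rec.subject_id}.csv")
        if config.run_ica:
            rec, decomp = remove_artifacts(rec, criteria, seed=config.ica_seed)
            logger.info("subject %s: %d ICA components flagged",
                        rec.subject_id, decomp.n_flagged)
        epochs = select_windows(rec, log, n_keep=config.n_epochs)
        if config.run_laplacian:
            epochs = surface_laplacian(
                epochs, spline_order=config.spline_order,
                regularization=config.spline_regularization,
            )
        spectrum = coherence_spectrum(epochs, nfft=config.nfft)
        for band in CANONICAL_BANDS:
            M = band_average(spectrum, band, subject_id=rec.subject_id)
            W = threshold_normalize(M, binarize=config.binarize)
            logger.info("subject %s band %s: threshold U=%.4f",
                        rec.subject_id, band.name, W.threshold_value)
            matrices_by_band[band.name].append(W)
            write_matrix(W, mat_dir / f"{rec.subject_id}_{band.name}.csv")
            _record(mat_dir / f"{rec.subject_id}_{band.name}.csv")

    # --- feature tables (15 variants)
    tables = all_feature_tables(matrices_by_band, labels)
    ft_dir = out / "features"
    ft_dir.mkdir(exist_ok=True)
    for t in tables.values():
        p = ft_dir / feature_table_filename(t.band, t.metric)
        write_feature_table(t, p)
        _record(p)

    # --- outlier screening
    reports = [silhouette_scores(t) for t in tables.values()]
    decisions = detect_outliers(
        reports,
        positive_fraction=config.outlier_positive_fraction,
        min_variants=config.outlier_min_variants,
    )
    outlier_frame = pd.DataFrame(
        [(p, ";".join(sorted(d.flagged_in)), d.is_outlier)
         for p, d in sorted(decisions.items())],
        columns=["participant", "flagged_variants", "is_outlier"],
    )
    outlier_frame.to_csv(out / "outliers.csv", index=False)
    _record(out / "outliers.csv")
    manifest.removed_outliers = sorted(
        p for p, d in decisions.items() if d.is_outlier
    )
    logger.info("removed %d outliers", len(manifest.removed_outliers))
    clean = remove_outliers(tables, decisions)

    # --- experiments
    experiments = define_experiments(clean, seed=config.seed)
    exp_dir = out / "experiments"
    exp_dir.mkdir(exist_ok=True)
    for ds in experiments:
        p = exp_dir / f"{ds.name}.csv"
        ds.data.to_csv(p)
        _record(p)

    # --- classification
    rows = []
    for ds in experiments:
        res = cross_validate(
            ds.data.drop(columns=["class"]), ds.data["class"].to_numpy(),
            folds=config.cv_folds, repeats=config.cv_repeats,
            seed=config.seed, dataset_name=ds.name,
            confidence_factor=config.confidence_factor,
            min_leaf=config.min_leaf,
        )
        rows.append({
            "dataset": ds.name, "pair": ds.pair, "band": ds.band,
            "metric": ds.metric, "accuracy_pct": res.mean_accuracy_pct,
        })
    cv_frame = pd.DataFrame(rows)
    cv_frame.to_csv(out / "cv_results.csv", index=False)
    _record(out / "cv_results.csv")

    # --- summary: best accuracy per class pair
    best = cv_frame.loc[cv_frame.groupby("pair")["accuracy_pct"].idxmax()]
    best = best.sort_values("accuracy_pct", ascending=False)
    best.to_csv(out / "summary.csv", index=False)
    _record(out / "summary.csv")
    manifest.summary = best.to_dict("records")

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.write(out / "manifest.json")
    return manifest
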