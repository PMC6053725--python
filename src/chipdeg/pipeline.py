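"""End-to-end orchestration: features -> labels -> model -> prediction report.

A single YAML/JSON config names the input files and thresholds; every stage
failure is re-raised with the stage name, and a provenance record (config
hash, seed, package version) makes reruns verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from contextlib import contextmanager
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

import chipdeg
from chipdeg import io, labels as labels_mod, peaks as peaks_mod, prediction, signal
from chipdeg.ml import (
    cross_validate,
    rank_features,
    select_top_fraction,
    stratified_split,
    train_classifier,
)
from chipdeg.ml.evaluate import compute_metrics, roc_auc
from chipdeg.ml.classify import POSITIVE_CLASS
from chipdeg.segments import extract_all_segments, gene_intervals

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-labeled pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage label is the contract
        raise PipelineError(name, str(exc)) from exc


@dataclass
class Thresholds:
    fc: float = 1.5
    rpkm: float = 1.0
    m: float = 0.4
    p: float = 0.05
    max_distance: int = 5000
    top_fraction: float = 0.05
    split: float = 0.8
    folds: int = 10
    bin_size: int = 200
    precision: float = 0.95
    abs_fc: float = 4.0
    expressed_fraction: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.split < 1:
            raise ValueError("split must be in (0, 1)")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if not 0 < self.expressed_fraction <= 1:
            raise ValueError("expressed_fraction must be in (0, 1]")
        if self.folds < 2 or self.bin_size < 1:
            raise ValueError("folds must be >= 2 and bin_size >= 1")
        if not 0 < self.precision <= 1 or not 0 < self.p <= 1:
            raise ValueError("precision and p must be in (0, 1]")
        if self.fc <= 1 or self.rpkm < 0 or self.m < 0 or self.max_distance < 0:
            raise ValueError("fc must exceed 1; rpkm, m, max_distance nonnegative")


@dataclass
class PipelineConfig:
    annotation: str
    tracks: dict  # genotype -> mark -> condition -> reads BED path
    expression: dict  # genotype -> expression TSV path
    peaks: dict = field(default_factory=dict)
    truth: Optional[str] = None
    genotypes: tuple[str, ...] = ("C", "e")
    marks: tuple[str, ...] = ("K9", "K14", "K23")
    conditions: tuple[str, str] = ("A", "C")
    responsive_genotype: str = "C"
    selector: str = "infogain"
    classifier: str = "logistic"
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    base_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data.pop("simulation", None)
        thresholds = Thresholds(**data.pop("thresholds", {}))
        data.setdefault("base_dir", str(Path(path).parent))
        data["genotypes"] = tuple(data.get("genotypes", ("C", "e")))
        data["marks"] = tuple(data.get("marks", ("K9", "K14", "K23")))
        data["conditions"] = tuple(data.get("conditions", ("A", "C")))
        return cls(thresholds=thresholds, **data)

    def path(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else Path(self.base_dir) / p

    def to_canonical_dict(self) -> dict:
        d = asdict(self)
        d.pop("base_dir")
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def validate_files(self) -> None:
        """Check referenced files exist, naming the stage that needs them."""
        if not self.path(self.annotation).exists():
            raise PipelineError(
                "gene_segments", f"annotation file not found: {self.annotation}"
            )
        for g, by_mark in self.tracks.items():
            for m, by_cond in by_mark.items():
                for c, fname in by_cond.items():
                    if not self.path(fname).exists():
                        raise PipelineError(
                            "signal_features",
                            f"reads file not found for {g}{m}{c}: {fname}",
                        )
        for g, by_mark in self.peaks.items():
            for m, by_cond in by_mark.items():
                for c, fname in by_cond.items():
                    if not self.path(fname).exists():
                        raise PipelineError(
                            "peak_features",
                            f"peak file not found for {g}{m}{c}: {fname}",
                        )
        for g, fname in self.expression.items():
            if not self.path(fname).exists():
                raise PipelineError(
                    "deg_labels", f"expression file not found for {g}: {fname}"
                )
        if self.truth and not self.path(self.truth).exists():
            raise PipelineError(
                "prediction_selection", f"truth file not found: {self.truth}"
            )


def build_feature_matrix(config: PipelineConfig) -> pd.DataFrame:
    """Segment-signal features merged with per-track peak features."""
    with _stage("gene_segments"):
        genes = io.read_annotation(config.path(config.annotation))
        chrom_lengths: dict[str, int] = {}
        for g in genes:
            chrom_lengths[g.chromosome] = max(
                chrom_lengths.get(g.chromosome, 0), g.end + 3000
            )
        segment_sets = extract_all_segments(genes, chrom_lengths)
        intervals = gene_intervals(genes)

    with _stage("signal_features"):
        tracks = {
            (g, m, c): io.ReadTrack.from_bed(config.path(fname))
            for g, by_mark in config.tracks.items()
            for m, by_cond in by_mark.items()
            for c, fname in by_cond.items()
        }
        matrix = signal.build_segment_feature_matrix(
            tracks,
            segment_sets,
            config.genotypes,
            config.marks,
            config.conditions,
        )

    with _stage("peak_features"):
        th = config.thresholds
        cond_a, cond_c = config.conditions
        peak_frames: list[pd.DataFrame] = []
        for g, by_mark in config.peaks.items():
            for m, by_cond in by_mark.items():
                cond_peaks = {
                    c: io.read_narrowpeak(config.path(fname))
                    for c, fname in by_cond.items()
                }
                for c, plist in cond_peaks.items():
                    label = f"{g}{m}{c}"
                    assignment = peaks_mod.assign_peaks_to_genes(
                        plist, intervals, th.max_distance
                    )
                    peak_frames.append(
                        peaks_mod.peak_gene_features(assignment, label)
                    )
                if cond_a in cond_peaks and cond_c in cond_peaks:
                    merged = peaks_mod.merge_condition_peaks(
                        cond_peaks[cond_a],
                        cond_peaks[cond_c],
                        tracks[(g, m, cond_a)],
                        tracks[(g, m, cond_c)],
                    )
                    normed, _factor = peaks_mod.normalize_densities(merged)
                    diff = peaks_mod.call_differential_peaks(
                        normed, m_threshold=th.m, p_threshold=th.p
                    )
                    peak_frames.append(
                        peaks_mod.differential_peak_gene_features(
                            diff, intervals, f"{g}{m}diff", th.max_distance
                        )
                    )
        for frame in peak_frames:
            matrix = matrix.join(frame, how="left")
    return matrix


def run_pipeline(config: PipelineConfig, out_dir: str | os.PathLike) -> dict:
    """Run every stage and write the run directory; returns the report dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "pipeline.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("chipdeg")
    root_logger.addHandler(log_handler)
    try:
        config.validate_files()
        th = config.thresholds

        matrix = build_feature_matrix(config)
        matrix_imputed, missingness = signal.impute_missing(matrix)
        matrix.to_csv(out / "features.tsv", sep="\t", float_format="%.6g")

        with _stage("deg_labels"):
            expr = io.read_expression(
                config.path(config.expression[config.responsive_genotype])
            )
            deg_table = labels_mod.call_degs(
                expr, config.conditions, th.fc, th.rpkm
            )
            io.write_label_table(deg_table, out / "labels.tsv")
            labeled = deg_table[deg_table["label"] != "none"]
            known_dirs = labeled["label"].to_dict()

        with _stage("ml_core"):
            if labeled["label"].nunique() < 2:
                raise ValueError("need both up and down labels to train")
            ids = [g for g in labeled.index if g in matrix_imputed.index]
            X_labeled = matrix_imputed.loc[ids]
            y_labeled = labeled.loc[ids, "label"]
            split = stratified_split(
                ids, list(y_labeled), fraction=th.split, seed=config.seed
            )
            X_train = X_labeled.loc[split.train_ids]
            y_train = y_labeled.loc[split.train_ids].to_numpy()
            cv = cross_validate(
                config.classifier,
                X_train.reset_index(drop=True),
                y_train,
                folds=th.folds,
                seed=config.seed,
                selector=config.selector,
                top_fraction=th.top_fraction,
            )
            ranked = rank_features(X_train, y_train, config.selector)
            if config.selector == "cfs":
                chosen = ranked.names
            else:
                chosen = select_top_fraction(
                    ranked, X_labeled.shape[1], th.top_fraction
                )
            model = train_classifier(
                config.classifier, X_train[chosen], y_train, seed=config.seed
            )
            X_test = X_labeled.loc[split.test_ids]
            y_test = y_labeled.loc[split.test_ids].to_numpy()
            test_pred = model.predict(X_test[chosen])
            tp = int(((test_pred == POSITIVE_CLASS) & (y_test == POSITIVE_CLASS)).sum())
            fp = int(((test_pred == POSITIVE_CLASS) & (y_test != POSITIVE_CLASS)).sum())
            fn = int(((test_pred != POSITIVE_CLASS) & (y_test == POSITIVE_CLASS)).sum())
            tn = int(((test_pred != POSITIVE_CLASS) & (y_test != POSITIVE_CLASS)).sum())
            test_metrics = compute_metrics(tp, fp, fn, tn)
            if len(np.unique(y_test)) == 2:
                test_auc, _ = roc_auc(model.prob_up(X_test[chosen]), y_test)
            else:
                test_auc = float("nan")

        with _stage("prediction_selection"):
            pool = labels_mod.select_top_expressed(
                expr, th.expressed_fraction, config.conditions
            )
            pool = [g for g in pool if g in matrix_imputed.index]
            probs = pd.Series(
                model.prob_up(matrix_imputed.loc[pool][chosen]), index=pool
            )
            truth_dirs = None
            if config.truth:
                truth_df = io.read_label_table(config.path(config.truth))
                truth_dirs = {
                    g: lab
                    for g, lab in truth_df["label"].items()
                    if lab != "none"
                }
            report = prediction.build_prediction_report(
                probs,
                known_dirs,
                bin_size=th.bin_size,
                threshold=th.precision,
                evaluation_labels=truth_dirs,
                population_size=len(pool),
            )
            report.ranked.to_csv(out / "predictions.tsv", sep="\t", float_format="%.6g")
            report.bin_stats.to_csv(
                out / "precision_curve.tsv", sep="\t", float_format="%.6g"
            )

        result = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_genes": int(matrix.shape[0]),
            "n_features": int(matrix.shape[1]),
            "mean_missingness": float(missingness.mean()),
            "n_labeled": int(len(labeled)),
            "split": {
                "train": len(split.train_ids),
                "test": len(split.test_ids),
            },
            "selected_features": list(chosen),
            "cv": {
                "auc": cv.auc,
                "pooled": {
                    k: v for k, v in cv.pooled.items() if k != "flags"
                },
            },
            "test": {
                "auc": test_auc,
                **{k: v for k, v in test_metrics.items() if k != "flags"},
            },
            "prediction": report.summary(),
        }
        with open(out / "report.json", "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True, allow_nan=True)
        provenance = {
            "config": config.to_canonical_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "package_version": chipdeg.__version__,
        }
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
        return result
    finally:
        root_logger.removeHandler(log_handler)
        log_handler.close()
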