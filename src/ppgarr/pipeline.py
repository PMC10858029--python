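"""Configuration handling and the end-to-end pipeline driver.

The pipeline chains: synthetic data generation (or ingestion of existing
records) -> preprocessing -> delineation -> feature extraction ->
classification (and optionally PCA / feature-selection curves), writing all
artifacts as plain-text files whose headers echo the configuration hash and
seed, so a run is fully reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as ppgio
from .classify import ClassifierSpec, compare_classifiers, stratified_group_folds
from .delineate import DelineateConfig, delineate_segment, quality_mask
from .features import FEATURE_NAMES, extract_features
from .preprocess import PreprocConfig, Waveform, preprocess_record
from .selection import (
    accuracy_vs_components,
    accuracy_vs_selected_features,
    pca_fit,
    rank_features_by_loading,
    standardize_apply,
    standardize_fit,
)
from .synth import DEFAULT_SPECS, NoiseSpec, generate_records

__all__ = ["SynthConfig", "SelectConfig", "ClassifyConfig", "PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("ppgarr")


def _from_dict(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in config section '{section}': {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class SynthConfig:
    per_class_n: int = 5
    duration_s: float = 300.0
    fs: float = 250.0
    snr_db: float | None = 20.0
    wander_freq_hz: float = 0.2
    wander_amp_frac: float = 0.5

    def noise(self) -> NoiseSpec:
        return NoiseSpec(self.snr_db, self.wander_freq_hz, self.wander_amp_frac)


@dataclass(frozen=True)
class SelectConfig:
    enabled: bool = False
    classifier: str = "knn"
    k_min: int = 5
    k_max: int = 15
    rank_m_values: tuple[int, ...] = ()


@dataclass(frozen=True)
class ClassifyConfig:
    kinds: tuple[str, ...] = ("dt", "svm", "knn", "ensemble")
    folds: int = 10


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    out_dir: str = "ppgarr_out"
    log_level: str = "INFO"
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocConfig = field(default_factory=PreprocConfig)
    delineate: DelineateConfig = field(default_factory=DelineateConfig)
    select: SelectConfig = field(default_factory=SelectConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        sections = {
            "synth": SynthConfig,
            "preprocess": PreprocConfig,
            "delineate": DelineateConfig,
            "select": SelectConfig,
            "classify": ClassifyConfig,
        }
        kwargs: dict = {}
        for name, scls in sections.items():
            if name in data:
                sec = data.pop(name)
                if "kinds" in (sec or {}):
                    sec["kinds"] = tuple(sec["kinds"])
                if "rank_m_values" in (sec or {}):
                    sec["rank_m_values"] = tuple(sec["rank_m_values"])
                if "pi_bounds_s" in (sec or {}):
                    sec["pi_bounds_s"] = tuple(sec["pi_bounds_s"])
                kwargs[name] = _from_dict(scls, sec or {}, name)
        top = {"seed", "out_dir", "log_level"}
        unknown = set(data) - top
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        # hash only the scientific parameters: where the run is written and
        # how it logs must not change the identity of its results
        payload = self.to_dict()
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig.from_dict(data or {})


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured pipeline; returns a summary dict.

    Artifacts written under ``cfg.out_dir``: the synthetic dataset,
    delineation markers, the feature table, the classification report and
    (when selection is enabled) accuracy curves.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    log.info("stage synth: %d records/class", cfg.synth.per_class_n)
    records = generate_records(
        cfg.synth.per_class_n,
        cfg.synth.duration_s,
        cfg.synth.fs,
        cfg.seed,
        DEFAULT_SPECS,
        cfg.synth.noise(),
    )

    log.info("stage preprocess+delineate+features: %d records", len(records))
    tables = []
    marker_rows = []
    n_segments = 0
    n_unanalyzable = 0
    for rec in records:
        segs = preprocess_record(
            Waveform(rec.samples, rec.fs), cfg.preprocess, rec.record_id or "", rec.label
        )
        n_segments += len(segs)
        for seg in segs:
            markers = delineate_segment(seg, cfg.delineate)
            valid, analyzable = quality_mask(markers, seg, cfg.delineate)
            if not analyzable:
                n_unanalyzable += 1
                log.warning(
                    "segment %s@%gs: unanalyzable (%d valid pulses) — morphology imputed",
                    seg.source_record_id,
                    seg.start_s,
                    int(valid.sum()),
                )
            for j in range(markers.n_pulses):
                marker_rows.append(
                    {
                        "record_id": seg.source_record_id,
                        "segment_start_s": seg.start_s,
                        "pulse_index": j,
                        "valley_idx": int(markers.valley_idx[j]),
                        "peak_idx": int(markers.peak_idx[j]),
                        "notch_start_idx": int(markers.notch_start_idx[j]),
                        "notch_end_idx": int(markers.notch_end_idx[j]),
                        "valid_flag": bool(valid[j]),
                    }
                )
        tables.append(extract_features(segs, cfg.delineate))
    import pandas as pd

    table = pd.concat(tables, ignore_index=True)
    ppgio.write_markers(out / "markers.csv", marker_rows, meta)
    ppgio.write_feature_table(out / "features.csv", table, meta)

    X = table[list(FEATURE_NAMES)].to_numpy()
    y = table["label"].to_numpy()
    groups = table["record_id"].to_numpy()
    folds = stratified_group_folds(y, groups, cfg.classify.folds, cfg.seed)
    specs = [ClassifierSpec(kind, seed=cfg.seed) for kind in cfg.classify.kinds]
    log.info("stage classify: %s, %d-fold grouped CV", cfg.classify.kinds, cfg.classify.folds)
    reports, summary = compare_classifiers(X, y, folds, specs)
    report_payload = {r.config["classifier"]: r.to_dict() for r in reports}
    ppgio.write_report(out / "report.json", report_payload, meta)
    summary.to_csv(out / "summary.csv", index=False, float_format="%.6f")

    curves = {}
    if cfg.select.enabled:
        log.info("stage select: PCA curve K=%d..%d", cfg.select.k_min, cfg.select.k_max)
        sel_spec = ClassifierSpec(cfg.select.classifier, seed=cfg.seed)
        curve = accuracy_vs_components(
            X, y, folds, [sel_spec], range(cfg.select.k_min, cfg.select.k_max + 1)
        )
        curve.to_csv(out / "pca_curve.csv", index=False, float_format="%.6f")
        curves["pca"] = curve
        if cfg.select.rank_m_values:
            params = standardize_fit(X)
            model = pca_fit(standardize_apply(params, X), X.shape[1])
            ranking = rank_features_by_loading(model, list(FEATURE_NAMES))
            rcurve = accuracy_vs_selected_features(
                X, y, folds, ranking, [sel_spec], cfg.select.rank_m_values
            )
            rcurve.to_csv(out / "selection_curve.csv", index=False, float_format="%.6f")
            curves["selection"] = rcurve

    log.info(
        "done: %d segments (%d unanalyzable), best accuracy %.3f",
        n_segments,
        n_unanalyzable,
        max(r.accuracy for r in reports),
    )
    return {
        "n_records": len(records),
        "n_segments": n_segments,
        "n_unanalyzable": n_unanalyzable,
        "reports": reports,
        "summary": summary,
        "curves": curves,
        "feature_table": table,
    }
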