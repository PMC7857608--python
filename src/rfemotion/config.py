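"""Pipeline configuration and top-level orchestration
(simulate -> preprocess -> featurize -> train/evaluate -> report).

The configuration is a nested pydantic model mirroring every stage's
parameters; unknown keys are rejected, and the whole object round-trips
losslessly through YAML. Every artifact directory carries a provenance file
with the config hash and seeds; a stage is skipped on resume only when its
artifact exists and was produced by the same config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import io as dataset_io
from .evaluation import CVPlan, run_cv
from .features import FEATURE_NAMES, feature_table
from .models import FusionNetClassifier, train_baselines
from .preprocessing import PreprocessConfig, preprocess_recording
from .simulate import RadarConfig, default_emotion_profiles, generate_dataset
from .transforms import NetworkInputTransformer

logger = logging.getLogger("rfemotion")


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Section):
    n_subjects: int = 8
    duration: float = 150.0
    separation: float = 1.0
    with_ecg: bool = True
    carrier_frequency: float = 5.8e9
    static_distance: float = 0.30
    sampling_rate: float = 50.0
    ecg_sampling_rate: float = 250.0


class PreprocessSection(_Section):
    rf_band: tuple[float, float] = (0.1, 8.0)
    rf_filter_order: int = 4
    normalization: Literal["zscore", "minmax"] = "zscore"
    analysis_window: float = 120.0
    ecg_resample_rate: float = 154.0
    ecg_band: tuple[float, float] = (0.5, 45.0)
    ecg_filter_order: int = 4

    def to_config(self) -> PreprocessConfig:
        return PreprocessConfig(**self.model_dump())


class TransformSection(_Section):
    sequence_length: int = 256
    n_scales: int = 64
    image_size: tuple[int, int] = (32, 32)


class ModelSection(_Section):
    epochs: int = 40
    batch_size: int = 8
    learning_rate: float = 1e-3
    lstm_hidden: int = 64
    dense_units: int = 64
    dropout: float = 0.25
    validation_fraction: float = 0.0
    patience: int = 10


class EvaluationSection(_Section):
    mode: Literal["loso", "loro"] = "loso"
    baselines: bool = True


class PipelineConfig(_Section):
    master_seed: int = 0
    out_dir: str = "rfemotion_run"
    verbosity: int = 1
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    transforms: TransformSection = Field(default_factory=TransformSection)
    model: ModelSection = Field(default_factory=ModelSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location and verbosity
        excluded, so moving a run directory does not invalidate artifacts)."""
        payload = self.model_dump(exclude={"out_dir", "verbosity"})
        return hashlib.sha256(json.dumps(payload, sort_keys=True,
                                         default=str).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
        return path


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not serializable: {type(o)}")


def run_pipeline(config: PipelineConfig, resume: bool = False) -> Path:
    """Execute all stages in order, writing artifacts plus a provenance log.

    Returns the output directory. With ``resume=True`` a stage whose artifact
    exists under the same config hash is loaded instead of recomputed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    provenance: dict = {"config_hash": chash, "master_seed": config.master_seed,
                        "stages": {}}
    logging.basicConfig(level=logging.INFO if config.verbosity else logging.WARNING)

    for marker in out.glob("*.hash"):
        if marker.read_text() != chash:
            logger.warning("artifact %s was produced by config %s, replacing "
                           "under new config %s", marker.stem,
                           marker.read_text(), chash)

    def artifact_fresh(name: str) -> bool:
        marker = out / f"{name}.hash"
        return resume and marker.exists() and marker.read_text() == chash

    def mark(name: str, t0: float) -> None:
        (out / f"{name}.hash").write_text(chash)
        provenance["stages"][name] = {"seconds": round(_time.time() - t0, 3)}
        logger.info("stage %s done (%.1fs)", name, _time.time() - t0)

    # -- simulate ----------------------------------------------------------
    sim = config.simulate
    dataset_path = out / "dataset.npz"
    t0 = _time.time()
    if artifact_fresh("simulate") and dataset_path.exists():
        recordings = dataset_io.read_dataset(dataset_path)
        logger.info("stage simulate resumed from %s", dataset_path)
    else:
        radar = RadarConfig(carrier_frequency=sim.carrier_frequency,
                            static_distance=sim.static_distance,
                            sampling_rate=sim.sampling_rate)
        recordings = generate_dataset(
            default_emotion_profiles(sim.separation), sim.n_subjects,
            sim.duration, radar, config.master_seed, with_ecg=sim.with_ecg,
            ecg_sampling_rate=sim.ecg_sampling_rate)
        dataset_io.write_dataset(recordings, dataset_path)
        mark("simulate", t0)

    # -- preprocess --------------------------------------------------------
    t0 = _time.time()
    pre_path = out / "preprocessed.npz"
    if artifact_fresh("preprocess") and pre_path.exists():
        processed = dataset_io.read_dataset(pre_path)
    else:
        pconf = config.preprocess.to_config()
        processed = [preprocess_recording(r, pconf) for r in recordings]
        dataset_io.write_dataset(processed, pre_path)
        mark("preprocess", t0)

    # -- featurize ---------------------------------------------------------
    t0 = _time.time()
    feat_path = out / "features.csv"
    table = feature_table(processed)
    table.to_csv(feat_path, index=False, float_format="%.12g")
    mark("featurize", t0)

    # -- evaluate ----------------------------------------------------------
    t0 = _time.time()
    tf = config.transforms
    builder = NetworkInputTransformer(
        sequence_length=tf.sequence_length, n_scales=tf.n_scales,
        image_size=tuple(tf.image_size))
    X_seq, X_img = builder.fit(processed).transform(processed)
    y = np.array([r.label for r in processed])
    groups = np.array([r.subject_id for r in processed])
    plan = CVPlan(mode=config.evaluation.mode)
    m = config.model

    def fusion_builder(seed: int) -> FusionNetClassifier:
        return FusionNetClassifier(
            epochs=m.epochs, batch_size=m.batch_size,
            learning_rate=m.learning_rate, lstm_hidden=m.lstm_hidden,
            dense_units=m.dense_units, dropout=m.dropout,
            validation_fraction=m.validation_fraction, patience=m.patience,
            seed=seed)

    fusion_report, _ = run_cv((X_seq, X_img), y, groups, fusion_builder,
                              plan, master_seed=config.master_seed)
    report = {"config_hash": chash, "master_seed": config.master_seed,
              "feature_names": list(FEATURE_NAMES),
              "fusion": fusion_report.to_dict(), "baselines": {}}
    if config.evaluation.baselines:
        F = table[list(FEATURE_NAMES)].to_numpy()

        for name in ("random_forest", "svm", "knn", "decision_tree", "lda"):
            def baseline_builder(seed: int, _name=name):
                from .models import make_baselines
                return make_baselines(seed)[_name]

            rep, _ = run_cv(F, y, groups, baseline_builder, plan,
                            master_seed=config.master_seed)
            report["baselines"][name] = rep.to_dict()
    mark("evaluate", t0)

    # -- report ------------------------------------------------------------
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, sort_keys=True, indent=2,
                                      default=_json_default))
    config.to_yaml(out / "config.yaml")
    (out / "provenance.json").write_text(
        json.dumps(provenance, sort_keys=True, indent=2))
    return out
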