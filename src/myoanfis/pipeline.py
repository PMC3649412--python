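"""End-to-end experiment orchestration.

Ties the stages together: simulate (optional) -> featurize -> subtractive
clustering -> initial Sugeno FIS -> hybrid ANFIS training -> decode ->
session scoring. The library entry points here are what the CLI, the tests
and the examples all call.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .clustering import ClusterConfig, cluster
from .codec import MOVEMENT_LABELS, SessionResult, aggregate, confusion_matrix, decode, encode, score_session
from .fis import SugenoFIS, build_initial_fis
from .preprocessing import FeatureVector, PreprocessingConfig, Recording, featurize
from .simulate import NoiseModel, Protocol, default_activation_map, generate_subject
from .training import TrainConfig, TrainReport, hybrid_fit

logger = logging.getLogger(__name__)

__all__ = [
    "AppConfig",
    "ExperimentResult",
    "features_to_arrays",
    "train_classifier",
    "classify_features",
    "evaluate_sessions",
    "run_synthetic_experiment",
    "run_pipeline",
]


@dataclass
class AppConfig:
    """One document holding every stage's knobs."""

    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    clustering: ClusterConfig = field(default_factory=lambda: ClusterConfig(max_clusters=60))
    training: TrainConfig = field(default_factory=TrainConfig)
    protocol: Protocol = field(default_factory=Protocol)
    noise: NoiseModel = field(default_factory=NoiseModel)
    crosstalk: float = 0.4
    baseline_gain: float = 0.05
    amplitude_jitter: float = 0.0
    order: str = "first"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AppConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        sections = {
            "preprocessing": PreprocessingConfig,
            "clustering": ClusterConfig,
            "training": TrainConfig,
            "protocol": Protocol,
            "noise": NoiseModel,
        }
        for name, typ in sections.items():
            if name in raw:
                sub = dict(raw[name])
                for k in ("band", "rest_interval", "emg_band"):
                    if k in sub:
                        sub[k] = tuple(sub[k])
                kwargs[name] = typ(**sub)
        for k in ("crosstalk", "baseline_gain", "amplitude_jitter", "order", "seed"):
            if k in raw:
                kwargs[k] = raw[k]
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["noise"]["dc_offset"] = float(np.mean(self.noise.dc_for(8)))
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclass
class ExperimentResult:
    fis: SugenoFIS
    train_report: TrainReport
    session_results: list[SessionResult]
    accuracy_table: pd.DataFrame
    confusion: pd.DataFrame

    @property
    def overall_accuracy(self) -> float:
        """Mean hit rate (%) over movements, averaged across evaluation sessions."""
        return float(self.accuracy_table.loc["Average", "Overall"])


def features_to_arrays(features: list[FeatureVector]) -> tuple[np.ndarray, list[str]]:
    X = np.vstack([fv.rms for fv in features])
    labels = [fv.label for fv in features]
    return X, labels


def train_classifier(
    features: list[FeatureVector],
    cluster_config: ClusterConfig | None = None,
    train_config: TrainConfig | None = None,
    order: str = "first",
) -> tuple[SugenoFIS, TrainReport]:
    """Cluster labelled training features, seed a FIS and run hybrid training."""
    X, labels = features_to_arrays(features)
    if any(lab is None for lab in labels):
        raise ValueError("training features must be labelled")
    y = np.array([encode(lab) for lab in labels])
    result = cluster(X, cluster_config or ClusterConfig(max_clusters=60))
    fis = build_initial_fis(
        result, order=order, data=X, input_names=list(features[0].channel_ids)
    )
    report = hybrid_fit(fis, X, y, train_config or TrainConfig())
    return report.fis, report


def classify_features(
    fis: SugenoFIS, features: list[FeatureVector], session_id: str = "", subject_id: str = ""
) -> SessionResult:
    """Run the forward pass on each feature vector and decode the output."""
    result = SessionResult(session_id=session_id, subject_id=subject_id)
    X, labels = features_to_arrays(features)
    gammas = fis.evaluate_batch(X)
    for lab, g in zip(labels, gammas):
        result.add(lab if lab is not None else "", decode(float(g)), float(g))
    return result


def evaluate_sessions(
    fis: SugenoFIS, sessions: list[list[FeatureVector]], session_ids: list[str] | None = None
) -> tuple[list[SessionResult], pd.DataFrame, pd.DataFrame]:
    ids = session_ids or [f"Session {i + 2}" for i in range(len(sessions))]
    results = [classify_features(fis, feats, session_id=sid) for feats, sid in zip(sessions, ids)]
    table = aggregate([score_session(r) for r in results], ids)
    return results, table, confusion_matrix(results)


def run_synthetic_experiment(
    seed: int = 0,
    config: AppConfig | None = None,
    crosstalk: float | None = None,
    noise_model: NoiseModel | None = None,
) -> ExperimentResult:
    """Simulate one subject, train on session 1, evaluate on the rest.

    The returned accuracy table has the shape of a per-subject summary:
    one row per held-out session, an ``Average`` row per movement and an
    overall mean.
    """
    cfg = config or AppConfig()
    xt = cfg.crosstalk if crosstalk is None else crosstalk
    amap = default_activation_map(crosstalk=xt, baseline=cfg.baseline_gain)
    noise = noise_model or cfg.noise
    sessions = generate_subject(
        cfg.protocol, amap, noise, seed=seed, amplitude_jitter=cfg.amplitude_jitter
    )
    feature_sets = [
        featurize(rec, sched, cfg.preprocessing) for rec, sched in sessions
    ]
    fis, report = train_classifier(
        feature_sets[0], cfg.clustering, cfg.training, order=cfg.order
    )
    results, table, conf = evaluate_sessions(fis, feature_sets[1:])
    return ExperimentResult(
        fis=fis,
        train_report=report,
        session_results=results,
        accuracy_table=table,
        confusion=conf,
    )


def run_pipeline(config: AppConfig, out_dir: str | Path) -> dict[str, Path]:
    """Full simulate -> featurize -> train -> classify -> score run, writing
    all artifacts (features, model JSON, accuracy table, confusion matrix,
    training error curve) under ``out_dir``. Returns the artifact paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    t0 = time.perf_counter()

    result = run_synthetic_experiment(seed=config.seed, config=config)
    amap = default_activation_map(config.crosstalk, config.baseline_gain)
    sessions = generate_subject(
        config.protocol, amap, config.noise, seed=config.seed,
        amplitude_jitter=config.amplitude_jitter,
    )
    for i, (rec, sched) in enumerate(sessions, start=1):
        feats = featurize(rec, sched, config.preprocessing)
        p = out / f"features_session{i}.csv"
        mio.write_features(p, feats)
        artifacts[f"features_session{i}"] = p

    model_path = out / "model.json"
    result.fis.to_json(model_path)
    artifacts["model"] = model_path

    acc_path = out / "accuracy.csv"
    result.accuracy_table.to_csv(acc_path)
    artifacts["accuracy"] = acc_path

    conf_path = out / "confusion.csv"
    result.confusion.to_csv(conf_path)
    artifacts["confusion"] = conf_path

    pred_path = out / "predictions.csv"
    pd.concat([r.to_frame() for r in result.session_results]).to_csv(pred_path, index=False)
    artifacts["predictions"] = pred_path

    curve_path = out / "training_error.json"
    curve_path.write_text(
        json.dumps(
            {
                "rmse": result.train_report.errors,
                "converged": result.train_report.converged,
            },
            indent=2,
        )
    )
    artifacts["training_error"] = curve_path

    logger.info(
        "pipeline finished in %.1f s: overall accuracy %.1f%%, %d rules",
        time.perf_counter() - t0,
        result.overall_accuracy,
        result.fis.n_rules,
    )
    return artifacts
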