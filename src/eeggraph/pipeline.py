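"""End-to-end analysis: cohort -> epochs -> networks -> metrics ->
group statistics -> cross-validated classification.

The stages are the package's scikit-learn transformers chained over the
epoch batch; this module wires them together, keeps the per-state
bookkeeping, and writes result tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortConfig, EEGRecording, generate_cohort
from .preprocessing import preprocess
from .connectivity import PearsonConnectivity, SparsityThreshold
from .metrics import GraphMetricsExtractor, MetricSet, metrics_to_frames
from .features import feature_table
from .stats import compare_groups, comparisons_to_frame
from .classify import ClassificationReport, cross_validate

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "reports_to_frame"]

#: Headline neighbor counts per state: K=3 for the resting states, K=5
#: for the working-memory task.
HEADLINE_K = {"eyes_open": 3, "eyes_closed": 3, "wm_task": 5}


@dataclass
class PipelineConfig:
    """Resolved parameters of one analysis run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    low_hz: float = 0.5
    high_hz: float = 45.0
    notch_hz: float | None = 50.0
    epoch_length_s: float = 20.0
    n_epochs: int = 9
    density: float = 0.3
    mode: str = "weighted"
    alpha: float = 0.05
    per_epoch_instances: bool = False
    classifiers: tuple[str, ...] = ("knn", "svm", "rf")
    knn_ks: tuple[int, ...] = (1, 3, 5)
    folds: int = 10
    seed: int = 0


@dataclass
class PipelineResult:
    config: PipelineConfig
    metric_sets: list[MetricSet]
    node_metrics: pd.DataFrame
    network_metrics: pd.DataFrame
    features: dict[str, pd.DataFrame]  # per state
    comparisons: pd.DataFrame
    reports: list[ClassificationReport]


def recordings_to_metrics(
    recordings: list[EEGRecording], config: PipelineConfig
) -> list[MetricSet]:
    """Preprocess every recording and compute per-epoch network metrics."""
    epochs = []
    for rec in recordings:
        epochs.extend(
            preprocess(
                rec,
                low_hz=config.low_hz,
                high_hz=config.high_hz,
                notch_hz=config.notch_hz,
                epoch_length_s=config.epoch_length_s,
                n_epochs=config.n_epochs,
            )
        )
    matrices = PearsonConnectivity().fit(epochs).transform(epochs)
    networks = (
        SparsityThreshold(density=config.density, mode=config.mode)
        .fit(matrices)
        .transform(matrices)
    )
    return GraphMetricsExtractor().fit(networks).transform(networks)


def _state_xy(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    meta = [c for c in ("subject_id", "group", "state", "epoch") if c in frame.columns]
    X = frame.drop(columns=meta).to_numpy(dtype=float)
    return X, frame["group"].to_numpy()


def run_pipeline(
    config: PipelineConfig | None = None,
    recordings: list[EEGRecording] | None = None,
) -> PipelineResult:
    """Run the full analysis.

    If ``recordings`` is omitted, a synthetic cohort is generated from
    ``config.cohort``.  Returns metric tables, the per-(measure, state)
    rank-sum comparison table, and one classification report per
    (state, classifier[, K]).
    """
    config = config or PipelineConfig()
    if recordings is None:
        recordings = generate_cohort(config.cohort)

    metric_sets = recordings_to_metrics(recordings, config)
    node_frame, net_frame = metrics_to_frames(metric_sets)
    comparisons = comparisons_to_frame(compare_groups(metric_sets, alpha=config.alpha))

    features: dict[str, pd.DataFrame] = {}
    reports: list[ClassificationReport] = []
    for state in sorted({ms.state for ms in metric_sets}):
        state_sets = [ms for ms in metric_sets if ms.state == state]
        frame = feature_table(state_sets, per_epoch=config.per_epoch_instances)
        features[state] = frame
        X, y = _state_xy(frame)
        for name in config.classifiers:
            if name == "knn":
                for k in config.knn_ks:
                    rep = cross_validate(
                        X, y, "knn", folds=config.folds, seed=config.seed,
                        state=state, k=k,
                    )
                    rep.classifier = f"knn_k{k}"
                    reports.append(rep)
            else:
                reports.append(
                    cross_validate(
                        X, y, name, folds=config.folds, seed=config.seed, state=state
                    )
                )
    return PipelineResult(
        config=config,
        metric_sets=metric_sets,
        node_metrics=node_frame,
        network_metrics=net_frame,
        features=features,
        comparisons=comparisons,
        reports=reports,
    )


def reports_to_frame(reports: list[ClassificationReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append(
            {
                "state": r.state,
                "classifier": r.classifier,
                "accuracy_pct": r.accuracy,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "kappa": r.kappa,
                "f_score": r.f_score,
                "precision": r.precision,
                "auc": r.auc,
                "tp": r.confusion.tp,
                "tn": r.confusion.tn,
                "fp": r.confusion.fp,
                "fn": r.confusion.fn,
                "seed": r.seed,
            }
        )
    return pd.DataFrame(rows)


def write_results(result: PipelineResult, out_dir) -> None:
    """Write result tables and a resolved-parameter log under ``out_dir``."""
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.node_metrics.to_csv(out / "node_metrics.csv", index=False)
    result.network_metrics.to_csv(out / "network_metrics.csv", index=False)
    result.comparisons.to_csv(out / "group_comparisons.csv", index=False)
    reports_to_frame(result.reports).to_csv(out / "classification.csv", index=False)
    for state, frame in result.features.items():
        frame.to_csv(out / f"features_{state}.csv", index=False)
    cfg = asdict(result.config)
    cfg["cohort"]["states"] = list(cfg["cohort"]["states"])
    cfg["cohort"]["channel_labels"] = list(cfg["cohort"]["channel_labels"])
    cfg["classifiers"] = list(cfg["classifiers"])
    cfg["knn_ks"] = list(cfg["knn_ks"])
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
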