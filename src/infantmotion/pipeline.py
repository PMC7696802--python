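"""End-to-end orchestration: stream -> windows -> cumulative curves ->
latents -> silhouette-selected k-means -> named activity timeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from infantmotion import clustering, preprocessing
from infantmotion.autoencoder import (
    ConvAutoencoder,
    ModelConfig,
    TrainingConfig,
    build_model,
    train,
)
from infantmotion.clustering import ActivityLabel, ACTIVITY_NAMES, ClusterModel
from infantmotion.sensorlog import SensorStream, segment_stream, WINDOW, STRIDE


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a training run."""

    window: int = WINDOW
    stride: int = STRIDE
    input_scale: float = preprocessing.DEFAULT_SCALE
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    silhouette_threshold: float = clustering.DEFAULT_SILHOUETTE_THRESHOLD
    k_max: int = clustering.DEFAULT_K_MAX
    activity_map_override: dict[int, int] | None = None
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class FittedPipeline:
    autoencoder: ConvAutoencoder
    cluster_model: ClusterModel
    config: PipelineConfig


@dataclass
class ActivityTimeline:
    """Ordered per-window activity labels for one recording."""

    segment_indices: np.ndarray
    start_samples: np.ndarray
    codes: np.ndarray

    def to_csv(self) -> str:
        lines = ["segment_index,start_sample,activity_code,activity_name"]
        for i, s, c in zip(self.segment_indices, self.start_samples, self.codes):
            lines.append(f"{i},{s},{c},{ACTIVITY_NAMES[ActivityLabel(int(c))]}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_csv(cls, text: str) -> "ActivityTimeline":
        rows = [line.split(",") for line in text.strip().splitlines()[1:]]
        return cls(
            segment_indices=np.array([int(r[0]) for r in rows]),
            start_samples=np.array([int(r[1]) for r in rows]),
            codes=np.array([int(r[2]) for r in rows]),
        )


def fit_pipeline(
    stream: SensorStream | np.ndarray,
    config: PipelineConfig | None = None,
) -> FittedPipeline:
    """Train the full unsupervised model on one recording.

    Steps: window the stream, apply the cumulative transform, train the
    autoencoder on the scaled curves, sweep k-means over k with the mean
    silhouette coefficient, keep the silhouette-selected k, and name the
    clusters from their movement statistics.
    """
    cfg = config or PipelineConfig()
    segments = segment_stream(stream, window=cfg.window, stride=cfg.stride)
    if not segments:
        raise ValueError("training stream is shorter than one window")
    curves = preprocessing.preprocess_segments(segments, scale=cfg.input_scale)

    model = build_model(ModelConfig(input_length=cfg.window, seed=cfg.seed))
    train(model, curves, TrainingConfig(
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate, seed=cfg.seed,
        input_scale=cfg.input_scale,
    ))
    latents = model.encode(curves)

    curve = clustering.silhouette_curve(
        latents, range(2, cfg.k_max + 1), seed=cfg.seed
    )
    k, threshold_met = clustering.select_cluster_count(
        curve, threshold=cfg.silhouette_threshold, k_max=cfg.k_max
    )
    centroids, assignments = clustering.fit_kmeans(latents, k, seed=cfg.seed)

    intensity = preprocessing.final_cumulative(segments)
    steps = preprocessing.max_step(segments)
    per_cluster_intensity = np.array(
        [intensity[assignments == c].mean() for c in range(k)]
    )
    per_cluster_step = np.array(
        [steps[assignments == c].mean() for c in range(k)]
    )
    override = None
    if cfg.activity_map_override:
        override = {int(c): ActivityLabel(v) for c, v in cfg.activity_map_override.items()}
    activity_map = clustering.map_clusters_to_activities(
        centroids, per_cluster_intensity, per_cluster_step, override=override
    )
    cluster_model = ClusterModel(
        k=k, centroids=centroids, silhouette_curve=curve,
        activity_map=activity_map, threshold_met=threshold_met,
    )
    return FittedPipeline(autoencoder=model, cluster_model=cluster_model, config=cfg)


def classify_stream(
    stream: SensorStream | np.ndarray,
    fitted: FittedPipeline,
) -> ActivityTimeline:
    """Label every window of a recording with the fitted model."""
    cfg = fitted.config
    segments = segment_stream(stream, window=cfg.window, stride=cfg.stride)
    if not segments:
        raise ValueError("stream is shorter than one window")
    curves = preprocessing.preprocess_segments(segments, scale=cfg.input_scale)
    latents = fitted.autoencoder.encode(curves)
    codes = clustering.assign(fitted.cluster_model, latents)
    return ActivityTimeline(
        segment_indices=np.arange(len(segments)),
        start_samples=np.array([s.start_index for s in segments]),
        codes=codes,
    )
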