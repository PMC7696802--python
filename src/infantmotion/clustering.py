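"""K-means over latent vectors with silhouette-guided model selection.

The number of clusters is chosen by sweeping k from 2 upward, scoring
each fit with the mean silhouette coefficient, and keeping the largest k
(up to ``k_max``) whose score clears a threshold — high cohesion alone
would always favor k = 2, but the activity vocabulary needs enough
clusters to cover distinct behaviors. With the default threshold of 0.6
this lands on four clusters for data containing the four activity
regimes.

Because training is unsupervised, clusters carry no names; they are
assigned to activities by a movement-intensity ranking (final cumulative
magnitude) plus a transient-step statistic that singles out
caregiver-induced motion. The mapping can be overridden when, e.g.,
video review says otherwise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score


class ActivityLabel(IntEnum):
    SLEEPING = 0
    STRONG_MOVEMENT = 1
    WEAK_MOVEMENT = 2
    EXTERNAL_FORCE = 3


ACTIVITY_NAMES = {
    ActivityLabel.SLEEPING: "sleeping",
    ActivityLabel.STRONG_MOVEMENT: "strong movement",
    ActivityLabel.WEAK_MOVEMENT: "weak movement",
    ActivityLabel.EXTERNAL_FORCE: "external force movement",
}

DEFAULT_SILHOUETTE_THRESHOLD = 0.6
DEFAULT_K_MAX = 8


class DegenerateInputError(ValueError):
    """All vectors identical: silhouette is undefined."""


@dataclass
class ClusterModel:
    """Fitted centroids plus the silhouette sweep and activity naming."""

    k: int
    centroids: np.ndarray  # (k, d)
    silhouette_curve: list[tuple[int, float]] = field(default_factory=list)
    activity_map: dict[int, ActivityLabel] = field(default_factory=dict)
    threshold_met: bool = True

    def save(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "silhouette_curve": [[int(k), float(s)] for k, s in self.silhouette_curve],
            "activity_map": {str(c): int(a) for c, a in self.activity_map.items()},
            "threshold_met": self.threshold_met,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ClusterModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            k=payload["k"],
            centroids=np.asarray(payload["centroids"], dtype=float),
            silhouette_curve=[(int(k), float(s)) for k, s in payload["silhouette_curve"]],
            activity_map={int(c): ActivityLabel(a) for c, a in payload["activity_map"].items()},
            threshold_met=payload["threshold_met"],
        )


def fit_kmeans(latents: np.ndarray, k: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded k-means (k-means++ init, 10 restarts, Euclidean).

    Returns ``(centroids, assignments)``.
    """
    x = np.asarray(latents, dtype=float)
    if k < 2:
        raise ValueError(f"need k >= 2, got {k}")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds number of vectors {x.shape[0]}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    return km.cluster_centers_.copy(), km.labels_.copy()


def silhouette_curve(
    latents: np.ndarray,
    k_range: range | list[int] | None = None,
    seed: int = 0,
) -> list[tuple[int, float]]:
    """Mean silhouette coefficient of a fresh k-means fit for each k."""
    x = np.asarray(latents, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 vectors for a silhouette sweep")
    if np.allclose(x, x[0]):
        raise DegenerateInputError("all vectors identical; silhouette undefined")
    ks = list(k_range) if k_range is not None else list(range(2, DEFAULT_K_MAX + 1))
    curve = []
    for k in ks:
        if k > x.shape[0] - 1:
            break
        _, labels = fit_kmeans(x, k, seed=seed)
        if len(np.unique(labels)) < 2:
            continue
        curve.append((k, float(silhouette_score(x, labels))))
    return curve


def select_cluster_count(
    curve: list[tuple[int, float]],
    threshold: float = DEFAULT_SILHOUETTE_THRESHOLD,
    k_max: int = DEFAULT_K_MAX,
) -> tuple[int, bool]:
    """Largest k <= k_max with mean silhouette >= threshold.

    Falls back to the argmax of the curve (with ``threshold_met=False``)
    when no k qualifies.
    """
    if not curve:
        raise ValueError("empty silhouette curve")
    eligible = [(k, s) for k, s in curve if k <= k_max and s >= threshold]
    if eligible:
        return max(k for k, _ in eligible), True
    best_k = max(curve, key=lambda ks: ks[1])[0]
    return best_k, False


def map_clusters_to_activities(
    centroids: np.ndarray,
    intensity: np.ndarray,
    max_step: np.ndarray | None = None,
    override: dict[int, ActivityLabel] | None = None,
) -> dict[int, ActivityLabel]:
    """Name clusters by movement statistics.

    ``intensity`` is the per-cluster mean final cumulative magnitude and
    ``max_step`` the per-cluster mean of the largest single-sample jump.
    The cluster with the largest transient step is called external-force
    movement; the rest are ranked by intensity as sleeping < weak <
    strong. With k != 4 no principled naming exists, so the identity map
    is returned with a warning. An ``override`` map is echoed verbatim.
    """
    k = np.asarray(centroids).shape[0]
    if override is not None:
        return dict(override)
    if k != 4:
        warnings.warn(f"activity naming needs k=4, got k={k}; using identity map")
        return {i: ActivityLabel(i % 4) for i in range(k)}
    intensity = np.asarray(intensity, dtype=float)
    if max_step is None:
        # No transient statistic: rank all four by intensity alone and
        # let the most intense cluster stand in for external force.
        order = np.argsort(intensity)
        ranks = [ActivityLabel.SLEEPING, ActivityLabel.WEAK_MOVEMENT,
                 ActivityLabel.STRONG_MOVEMENT, ActivityLabel.EXTERNAL_FORCE]
        return {int(c): ranks[i] for i, c in enumerate(order)}
    ext = int(np.argmax(np.asarray(max_step, dtype=float)))
    rest = [c for c in range(4) if c != ext]
    rest_sorted = sorted(rest, key=lambda c: intensity[c])
    mapping = {ext: ActivityLabel.EXTERNAL_FORCE}
    for cluster, label in zip(
        rest_sorted,
        [ActivityLabel.SLEEPING, ActivityLabel.WEAK_MOVEMENT, ActivityLabel.STRONG_MOVEMENT],
    ):
        mapping[int(cluster)] = label
    return mapping


def assign(model: ClusterModel, latents: np.ndarray) -> np.ndarray:
    """Activity code of the nearest centroid; ties break to the lowest
    cluster index."""
    x = np.atleast_2d(np.asarray(latents, dtype=float))
    if x.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"latent dimension {x.shape[1]} != centroid dimension {model.centroids.shape[1]}"
        )
    d = np.linalg.norm(x[:, None, :] - model.centroids[None], axis=2)
    clusters = d.argmin(axis=1)  # argmin takes the first (lowest) index on ties
    if model.activity_map:
        return np.array([int(model.activity_map[int(c)]) for c in clusters])
    return clusters
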