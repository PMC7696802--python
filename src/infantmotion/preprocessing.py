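"""Cumulative-difference transform of raw accelerometer windows.

A raw window oscillates around a per-axis baseline set by gravity and
sensor mounting. The transform removes that baseline, rectifies the
sample-to-sample change, and accumulates it, producing a per-axis
monotone non-decreasing curve whose final value is the window's total
movement. Three steps, each element-wise per axis:

1. centering:      z_i = s_i - mean(s)
2. rectified diff: d_i = |z_{i+1} - z_i|, with the last value duplicated
                   (d_{n-1} = d_{n-2}) so the length stays n
3. accumulation:   c_i = sum_{k<=i} d_k

The result is invariant to constant per-axis offsets and to per-axis
sign flips, which is exactly the nuisance introduced by attaching the
sensor in a different position or orientation on each subject. Centering
is in fact redundant given step 2 (constants cancel in the difference)
but is kept as part of the defined transform.
"""

from __future__ import annotations

import numpy as np

from infantmotion.sensorlog import Segment

#: Divisor applied to cumulative values before autoencoder training.
#: Raw cumulative magnitudes span roughly 10^2-10^4 chip units; a small
#: network trains far more stably on O(1) inputs.
DEFAULT_SCALE = 1000.0


def _as_array(segment: Segment | np.ndarray) -> np.ndarray:
    arr = segment.samples if isinstance(segment, Segment) else np.asarray(segment, dtype=float)
    return np.asarray(arr, dtype=float)


def center(segment: Segment | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the per-axis mean; returns ``(centered, mu)``."""
    arr = _as_array(segment)
    mu = arr.mean(axis=0)
    return arr - mu, mu


def abs_diff(centered: np.ndarray) -> np.ndarray:
    """Absolute sample-to-sample difference, last row duplicated."""
    z = np.asarray(centered, dtype=float)
    if z.shape[0] < 2:
        raise ValueError("need at least 2 samples to difference")
    d = np.abs(np.diff(z, axis=0))
    return np.vstack([d, d[-1]])


def cumsum(diff: np.ndarray) -> np.ndarray:
    """Per-axis running sum of the rectified differences."""
    return np.cumsum(np.asarray(diff, dtype=float), axis=0)


def preprocess_segment(segment: Segment | np.ndarray) -> np.ndarray:
    """Full transform: center, rectify differences, accumulate.

    Input and output are (n, 3); the output is non-negative and
    non-decreasing along axis 0.
    """
    z, _ = center(segment)
    return cumsum(abs_diff(z))


def preprocess_segments(
    segments: list[Segment] | np.ndarray,
    scale: float = DEFAULT_SCALE,
) -> np.ndarray:
    """Transform a batch of windows into scaled network inputs.

    Returns a (k, n, 3) array of cumulative curves divided by ``scale``.
    """
    if isinstance(segments, np.ndarray) and segments.ndim == 3:
        batch = segments.astype(float)
    else:
        batch = np.stack([_as_array(s) for s in segments])
    mu = batch.mean(axis=1, keepdims=True)
    z = batch - mu
    d = np.abs(np.diff(z, axis=1))
    d = np.concatenate([d, d[:, -1:, :]], axis=1)
    return np.cumsum(d, axis=1) / scale


def final_cumulative(segments: list[Segment] | np.ndarray) -> np.ndarray:
    """Final (unscaled) cumulative value per segment, averaged over axes.

    This is the movement-intensity statistic used to name clusters:
    sleeping windows land around a few hundred chip units, strong
    movement around several thousand.
    """
    cum = preprocess_segments(segments, scale=1.0)
    return cum[:, -1, :].mean(axis=1)


def max_step(segments: list[Segment] | np.ndarray) -> np.ndarray:
    """Largest single-sample absolute difference per segment (any axis).

    External-force handling produces abrupt baseline jumps, so this
    transient statistic separates caregiver-induced motion from equally
    intense self-generated movement.
    """
    if isinstance(segments, np.ndarray) and segments.ndim == 3:
        batch = segments.astype(float)
    else:
        batch = np.stack([_as_array(s) for s in segments])
    return np.abs(np.diff(batch, axis=1)).max(axis=(1, 2))
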