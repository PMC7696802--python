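"""Regime-switching synthetic accelerometer streams with ground truth.

The study's recordings are not deposited, so this module emulates the
signal structure the pipeline relies on: a 40 Hz triaxial stream that
alternates between four activity regimes, each a simple stochastic
process in raw chip units within [-1000, 1000]:

* sleeping          — a still baseline plus small white noise,
* weak movement     — a low-amplitude, low-frequency oscillation,
* strong movement   — a high-amplitude multi-frequency oscillation
                      (largest on the z axis, as chest-worn sensors
                      show), plus moderate noise,
* external force    — abrupt baseline jumps from caregiver handling
                      superposed on moderate noise.

Amplitudes are calibrated so the per-window final cumulative value sits
near a few hundred chip units for sleeping and several thousand for
strong movement — roughly a 10x separation. Each recording additionally
gets a fixed orientation nuisance (axis permutation, per-axis sign
flips, constant offset) standing in for the uncontrolled way the sensor
is attached to each subject.

Ground truth is per sample; window labels are derived by majority vote,
the way a human would label 4-second clips from video.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from infantmotion.clustering import ActivityLabel
from infantmotion.sensorlog import (
    ACCEL_MAX,
    ACCEL_MIN,
    SEQ_MOD,
    SensorRecord,
    SensorStream,
    WINDOW,
    STRIDE,
)


@dataclass(frozen=True)
class RegimeSpec:
    """Per-activity signal process.

    ``oscillations`` is a list of (amplitude, f_low_hz, f_high_hz)
    sinusoid components; the frequency is redrawn per regime episode.
    ``axis_weights`` scales oscillation amplitude per axis. Steps model
    caregiver handling: a Poisson process of baseline jumps with
    magnitudes drawn from ``step_magnitude`` (uniform range).
    """

    activity: ActivityLabel
    noise_sd: float
    oscillations: tuple[tuple[float, float, float], ...] = ()
    axis_weights: tuple[float, float, float] = (0.6, 0.6, 1.0)
    step_rate_hz: float = 0.0
    step_magnitude: tuple[float, float] = (0.0, 0.0)
    min_duration_s: float = 5.0
    mean_duration_s: float = 14.0
    #: Depth of the slow (several-second) drift of overall movement
    #: intensity; models an episode gradually intensifying or calming.
    drift_depth: float = 0.12
    #: Depth of a fast per-axis burst envelope whose 4-s rolling mean is
    #: normalized to 1: local twitch/burst texture varies richly while
    #: the per-window movement total stays pinned. Used for quiet sleep,
    #: where breathing and startles modulate an otherwise still signal.
    burst_depth: float = 0.0


def default_regime_specs() -> dict[ActivityLabel, RegimeSpec]:
    """The reference scenario used throughout the tests and examples."""
    return {
        ActivityLabel.SLEEPING: RegimeSpec(
            activity=ActivityLabel.SLEEPING, noise_sd=3.0,
            min_duration_s=20.0, mean_duration_s=45.0,
            drift_depth=0.0, burst_depth=1.8,
        ),
        ActivityLabel.WEAK_MOVEMENT: RegimeSpec(
            activity=ActivityLabel.WEAK_MOVEMENT, noise_sd=7.0,
            oscillations=((58.0, 1.4, 1.6),),
            min_duration_s=15.0, mean_duration_s=30.0,
        ),
        ActivityLabel.STRONG_MOVEMENT: RegimeSpec(
            activity=ActivityLabel.STRONG_MOVEMENT, noise_sd=12.0,
            oscillations=((150.0, 2.2, 2.4), (50.0, 1.0, 1.2)),
            min_duration_s=12.0, mean_duration_s=25.0,
        ),
        ActivityLabel.EXTERNAL_FORCE: RegimeSpec(
            activity=ActivityLabel.EXTERNAL_FORCE, noise_sd=6.0,
            oscillations=((30.0, 0.3, 0.8),),
            step_rate_hz=2.0, step_magnitude=(210.0, 300.0),
            min_duration_s=10.0, mean_duration_s=22.0,
        ),
    }


@dataclass
class LabeledStream:
    """A synthetic stream plus per-sample truth and the nuisance draw."""

    stream: SensorStream
    labels: np.ndarray  # (n,) activity codes
    nuisance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.stream)


def _draw_duration(rng: np.random.Generator, spec: RegimeSpec, rate_hz: float) -> int:
    """Truncated-geometric episode length in samples (whole seconds)."""
    extra_mean = max(spec.mean_duration_s - spec.min_duration_s, 1.0)
    extra = rng.geometric(1.0 / extra_mean)
    return int(round((spec.min_duration_s - 1.0 + extra) * rate_hz))


def _smooth_noise(rng: np.random.Generator, n: int, rate_hz: float,
                  control_period_s: float = 2.0) -> np.ndarray:
    """Unit-variance noise band-limited by linear interpolation between
    control points every ``control_period_s`` seconds."""
    step = max(int(round(control_period_s * rate_hz)), 1)
    n_ctrl = n // step + 2
    ctrl = rng.normal(0.0, 1.0, size=n_ctrl)
    return np.interp(np.arange(n) / step, np.arange(n_ctrl), ctrl)


def _rolling_mean_norm(env: np.ndarray, window: int) -> np.ndarray:
    """Divide an envelope by its centered rolling mean so any
    window-length average of the result is close to 1."""
    pad = np.pad(env, (window // 2, window - window // 2 - 1), mode="edge")
    ma = np.convolve(pad, np.ones(window) / window, mode="valid")
    return env / np.maximum(ma, 1e-6)


def _regime_samples(
    rng: np.random.Generator, spec: RegimeSpec, n: int, rate_hz: float
) -> np.ndarray:
    w = np.asarray(spec.axis_weights)
    if spec.burst_depth > 0:
        # Per-axis burst texture, normalized so ~4-s totals stay stable.
        win = min(int(4 * rate_hz), max(n, 1))
        env = np.stack([
            _rolling_mean_norm(
                np.maximum(1 + spec.burst_depth * _smooth_noise(rng, n, rate_hz, 1.0), 0.0),
                win)
            for _ in range(3)
        ], axis=1)
    elif spec.drift_depth > 0:
        env = np.maximum(
            1 + spec.drift_depth * _smooth_noise(rng, n, rate_hz, 6.0), 0.1
        )[:, None]
    else:
        env = np.ones((n, 1))
    x = rng.normal(0.0, 1.0, size=(n, 3)) * spec.noise_sd * env
    for amp, f_lo, f_hi in spec.oscillations:
        # Frequency wanders smoothly within the episode so window-level
        # movement statistics vary continuously rather than jumping
        # between per-episode values.
        f_mid, f_half = (f_lo + f_hi) / 2, (f_hi - f_lo) / 2
        freq = f_mid + f_half * np.clip(_smooth_noise(rng, n, rate_hz) / 2, -1, 1)
        phase0 = rng.uniform(0, 2 * np.pi, size=3)
        phase = 2 * np.pi * np.cumsum(freq) / rate_hz
        x += (amp * w) * env * np.sin(phase[:, None] + phase0)
    if spec.step_rate_hz > 0:
        # Quasi-periodic handling: lifts and repositionings arrive at a
        # roughly regular cadence with timing jitter, each shifting the
        # gravity baseline; shifts revert toward zero to stay in range.
        period = rate_hz / spec.step_rate_hz
        k = int(n / period)
        times = (np.arange(1, k + 1) * period
                 + rng.uniform(-0.2, 0.2, size=k) * period).astype(int)
        baseline = np.zeros(3)
        offsets = np.zeros((n, 3))
        for t0 in times[(times > 0) & (times < n)]:
            mag = rng.uniform(*spec.step_magnitude, size=3)
            sign = np.where(np.abs(baseline) > 250, -np.sign(baseline),
                            rng.choice([-1.0, 1.0], size=3))
            baseline = baseline + sign * mag
            offsets[t0:] = baseline
        x += offsets
    return x


def generate_stream(
    specs: dict[ActivityLabel, RegimeSpec] | None = None,
    total_duration_s: float = 600.0,
    rate_hz: float = 40.0,
    seed: int = 0,
    nuisance: bool = True,
) -> LabeledStream:
    """Markov regime-switching stream, deterministic given ``seed``.

    Episodes draw a random activity different from the previous one and
    a truncated-geometric duration (>= ``min_duration_s``); the stream
    is cut to ``round(total_duration_s * rate_hz)`` samples. When
    ``nuisance`` is true, a per-recording axis permutation, sign flips,
    and constant offset are applied to the accelerometer channels.
    """
    if rate_hz <= 0:
        raise ValueError(f"rate must be positive, got {rate_hz}")
    if total_duration_s < 4:
        raise ValueError("need at least 4 seconds of signal")
    specs = specs if specs is not None else default_regime_specs()
    rng = np.random.default_rng(seed)
    n_total = int(round(total_duration_s * rate_hz))

    activities = list(specs)
    chunks, labels = [], []
    n_done = 0
    current = activities[rng.integers(len(activities))]
    while n_done < n_total:
        spec = specs[current]
        n = min(_draw_duration(rng, spec, rate_hz), n_total - n_done)
        chunks.append(_regime_samples(rng, spec, n, rate_hz))
        labels.append(np.full(n, int(spec.activity)))
        n_done += n
        others = [a for a in activities if a != current] or [current]
        current = others[rng.integers(len(others))]
    accel = np.vstack(chunks)
    label_arr = np.concatenate(labels)

    nuis: dict = {"sign_flips": (1, 1, 1), "permutation": (0, 1, 2),
                  "offset": (0.0, 0.0, 0.0)}
    if nuisance:
        nuis = {
            "sign_flips": tuple(rng.choice([-1, 1], size=3).tolist()),
            "permutation": tuple(rng.permutation(3).tolist()),
            "offset": tuple(rng.uniform(-200, 200, size=3).tolist()),
        }
        accel = _apply_nuisance_array(accel, **nuis)

    accel = np.clip(np.rint(accel), ACCEL_MIN, ACCEL_MAX).astype(int)
    records = []
    for i in range(n_total):
        us = int(round(i * 1_000_000 / rate_hz))
        s, us = divmod(us, 1_000_000)
        m, s = divmod(s, 60)
        h, m = divmod(m, 60)
        records.append(SensorRecord(
            timestamp=f"{h:02d}:{m:02d}:{s:02d}.{us:06d}",
            frame_index=i * 30 // int(rate_hz),
            gyro=(0, 0, 0),
            accel=tuple(accel[i].tolist()),
            seq=i % SEQ_MOD,
        ))
    return LabeledStream(
        stream=SensorStream(records=records, nominal_rate=rate_hz),
        labels=label_arr, nuisance=nuis,
    )


def _apply_nuisance_array(accel, sign_flips, permutation, offset) -> np.ndarray:
    arr = np.asarray(accel, dtype=float)
    arr = arr[:, list(permutation)]
    return arr * np.asarray(sign_flips) + np.asarray(offset)


def apply_nuisance(
    stream: SensorStream,
    sign_flips: tuple[int, int, int] = (1, 1, 1),
    permutation: tuple[int, int, int] = (0, 1, 2),
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> SensorStream:
    """Re-orient a stream: permute axes, flip signs, add a constant
    offset (in that order), clipping to the sensor range."""
    accel = _apply_nuisance_array(stream.accel_array(), sign_flips, permutation, offset)
    accel = np.clip(np.rint(accel), ACCEL_MIN, ACCEL_MAX).astype(int)
    records = [
        replace(r, accel=tuple(accel[i].tolist()))
        for i, r in enumerate(stream.records)
    ]
    return SensorStream(records=records, nominal_rate=stream.nominal_rate)


def segment_labels(
    labeled: LabeledStream, window: int = WINDOW, stride: int = STRIDE
) -> np.ndarray:
    """Majority per-sample label per window; ties go to the label at the
    window midpoint."""
    labels = np.asarray(labeled.labels, dtype=int)
    n = labels.size
    if n < window:
        return np.empty(0, dtype=int)
    out = []
    for start in range(0, n - window + 1, stride):
        win = labels[start : start + window]
        counts = np.bincount(win)
        top = counts.max()
        winners = np.flatnonzero(counts == top)
        if winners.size == 1:
            out.append(int(winners[0]))
        else:
            out.append(int(win[window // 2]))
    return np.array(out, dtype=int)


def labels_to_csv(labels: np.ndarray) -> str:
    """Parallel label file (sample_idx, activity_code)."""
    lines = ["sample_idx,activity_code"]
    lines += [f"{i},{int(code)}" for i, code in enumerate(labels)]
    return "\n".join(lines) + "\n"
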