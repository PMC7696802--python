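"""The 1D convolutional autoencoder and its training loop.

The encoder maps a preprocessed 160x3 window to a 64-element latent
vector through three stride-1 convolutions interleaved with max-pooling
(lengths 160 -> 159 -> 39 -> 38 -> 9 -> 8 -> 4, channels 3 -> 4 -> 8 ->
16; the flattened 16x4 tail is the latent code). The decoder restores
the input shape with two transposed convolutions of kernel = stride = 4
(lengths 4 -> 16 -> 64) followed by an affine 64 -> 160 map shared
across the three axes. Training minimizes mean squared reconstruction
error with Adam; everything is reproducible from (seed, config).

Per-layer trainable parameter counts for the default configuration are
28, 72, 272, 32, 520, 99 and 10,400 (total 11,423).
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from infantmotion import nn


@dataclass(frozen=True)
class ModelConfig:
    input_length: int = 160
    input_channels: int = 3
    encoder_channels: tuple[int, int, int] = (4, 8, 16)
    encoder_kernel: int = 2
    pool_sizes: tuple[int, int, int] = (4, 4, 2)
    decoder_kernel: int = 4  # stride equals kernel
    latent_length: int = 64
    seed: int = 0


@dataclass
class TrainingConfig:
    epochs: int = 1000
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    input_scale: float = 1000.0


class ModelConstructionError(ValueError):
    """The configured layer chain does not produce the stated shapes."""


class TrainingFailure(RuntimeError):
    """Loss became non-finite during optimization."""


class ConvAutoencoder:
    """Encoder-decoder over (batch, 3, 160) arrays.

    ``layers`` holds the sequential computation graph;
    ``trainable_layers`` lists only the seven parameterized layers in
    architecture-table order.
    """

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)

        c1, c2, c3 = cfg.encoder_channels
        p1, p2, p3 = cfg.pool_sizes
        k = cfg.encoder_kernel

        # Verify the encoder length chain reaches the latent size.
        L = cfg.input_length
        chain = []
        for i, p in enumerate(cfg.pool_sizes):
            L = L - k + 1
            chain.append(("conv%d" % (i + 1), L))
            L = L // p
            chain.append(("pool%d" % (i + 1), L))
        if c3 * L != cfg.latent_length:
            raise ModelConstructionError(
                f"encoder chain {chain} ends with {c3}x{L} != latent {cfg.latent_length}"
            )
        self._latent_spatial = L  # 4 at defaults

        dk = cfg.decoder_kernel
        if L * dk * dk != cfg.latent_length:
            raise ModelConstructionError(
                f"decoder upsampling {L} -> {L * dk} -> {L * dk * dk} "
                f"does not reach {cfg.latent_length}"
            )

        conv1 = nn.Conv1d(cfg.input_channels, c1, k, rng)
        conv2 = nn.Conv1d(c1, c2, k, rng)
        conv3 = nn.Conv1d(c2, c3, k, rng)
        bn = nn.BatchNorm1d(c3)
        deconv1 = nn.ConvTranspose1d(c3, c2, dk, rng)
        deconv2 = nn.ConvTranspose1d(c2, cfg.input_channels, dk, rng)
        out = nn.SharedLinear(cfg.latent_length, cfg.input_length, rng)

        self.encoder_layers: list[nn.Layer] = [
            conv1, nn.ReLU(), nn.MaxPool1d(p1),
            conv2, nn.ReLU(), nn.MaxPool1d(p2),
            conv3, bn, nn.ReLU(), nn.MaxPool1d(p3),
            nn.Flatten(),
        ]
        self.decoder_layers: list[nn.Layer] = [
            nn.Reshape(c3, self._latent_spatial),
            deconv1, nn.ReLU(),
            deconv2, nn.ReLU(),
            out,
        ]
        self.layers = self.encoder_layers + self.decoder_layers
        self.trainable_layers: list[nn.Layer] = [conv1, conv2, conv3, bn, deconv1, deconv2, out]
        self.history: list[float] = []

    # -- forward passes ------------------------------------------------

    def _forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def _backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    @staticmethod
    def _to_net(segments: np.ndarray) -> np.ndarray:
        """(k, 160, 3) or (160, 3) sample-major -> (k, 3, 160) channel-major."""
        arr = np.asarray(segments, dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"expected (k, n, 3) segments, got {arr.shape}")
        return arr.transpose(0, 2, 1)

    def encode(self, segments: np.ndarray) -> np.ndarray:
        """Latent vectors, one 64-element row per input window."""
        x = self._to_net(segments)
        if x.shape[2] != self.config.input_length:
            raise ValueError(
                f"expected length {self.config.input_length}, got {x.shape[2]}"
            )
        for layer in self.encoder_layers:
            x = layer.forward(x, training=False)
        return x

    def reconstruct(self, segments: np.ndarray) -> np.ndarray:
        """Decoder output in sample-major (k, 160, 3) layout."""
        out = self._forward(self._to_net(segments), training=False)
        return out.transpose(0, 2, 1)

    def reconstruction_error(self, segments: np.ndarray) -> float:
        arr = np.asarray(segments, dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
        return float(np.mean((self.reconstruct(arr) - arr) ** 2))


def build_model(config: ModelConfig | None = None) -> ConvAutoencoder:
    return ConvAutoencoder(config)


def count_parameters(model: ConvAutoencoder) -> list[int]:
    """Trainable parameter count per parameterized layer, in order."""
    return [layer.n_params() for layer in model.trainable_layers]


def train(
    model: ConvAutoencoder,
    segments: np.ndarray,
    config: TrainingConfig | None = None,
) -> ConvAutoencoder:
    """Fit the autoencoder on pre-scaled cumulative windows (k, 160, 3).

    Minibatch Adam on mean squared reconstruction error. The per-epoch
    mean batch loss is appended to ``model.history``; a non-finite loss
    aborts with :class:`TrainingFailure`.
    """
    cfg = config or TrainingConfig()
    data = np.asarray(segments, dtype=float)
    if data.ndim != 3 or data.shape[0] == 0:
        raise ValueError("training set must be a non-empty (k, n, 3) array")
    x_all = data.transpose(0, 2, 1)
    n = x_all.shape[0]
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.layers, lr=cfg.learning_rate)

    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            xb = x_all[order[start : start + cfg.batch_size]]
            out = model._forward(xb, training=True)
            resid = out - xb
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise TrainingFailure(f"non-finite loss at epoch {len(model.history)}")
            model._backward(2.0 * resid / resid.size)
            opt.step()
            losses.append(loss)
        model.history.append(float(np.mean(losses)))
    return model


def save_model(model: ConvAutoencoder, path: str | Path) -> None:
    """Persist config, weights, batch-norm statistics and history."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.trainable_layers):
        for k, v in layer.params.items():
            arrays[f"layer{i}.{k}"] = v
        if isinstance(layer, nn.BatchNorm1d):
            arrays[f"layer{i}.running_mean"] = layer.running_mean
            arrays[f"layer{i}.running_var"] = layer.running_var
    arrays["history"] = np.asarray(model.history, dtype=float)
    cfg = asdict(model.config)
    cfg["encoder_channels"] = list(cfg["encoder_channels"])
    cfg["pool_sizes"] = list(cfg["pool_sizes"])
    arrays["config_json"] = np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str | Path) -> ConvAutoencoder:
    path = Path(path)
    try:
        with np.load(path) as data:
            cfg_dict = json.loads(bytes(data["config_json"].tobytes()).decode())
            cfg_dict["encoder_channels"] = tuple(cfg_dict["encoder_channels"])
            cfg_dict["pool_sizes"] = tuple(cfg_dict["pool_sizes"])
            model = ConvAutoencoder(ModelConfig(**cfg_dict))
            for i, layer in enumerate(model.trainable_layers):
                for k in layer.params:
                    layer.params[k][...] = data[f"layer{i}.{k}"]
                if isinstance(layer, nn.BatchNorm1d):
                    layer.running_mean = data[f"layer{i}.running_mean"]
                    layer.running_var = data[f"layer{i}.running_var"]
            model.history = list(data["history"])
    except (OSError, KeyError, ValueError, zipfile.BadZipFile,
            json.JSONDecodeError) as exc:
        raise IOError(f"cannot load model from {path}: {exc}") from exc
    return model
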