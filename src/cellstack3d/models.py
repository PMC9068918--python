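"""Neural reconstruction modules.

Four tasks share two architecture families:

- a convolutional classifier (3 strided conv stages + FC head, 20
  outputs) estimating the depth class of a single blurred layer;
- a 6-stage encoder-decoder (3 strided convolutions, 3 transposed
  convolutions) used for deblurring (1 linear output plane), two-layer
  depth-map regression (1 sigmoid plane) and 4-layer cell detection
  (4 sigmoid planes, single- or dual-sensor input);
- a residual variant of the detector (residual feature extractor at
  full resolution + 2-convolution head) for the moving-cluster
  dynamics task.

Inputs are min-max normalized to [0, 1] per view before entering any
network, which makes predictions invariant to global gain and offset of
the acquisition.  The depth classifier additionally works on the
normalized log power spectrum of the view (see
:func:`log_spectrum_view`), where the PSF's depth-dependent
high-frequency roll-off is directly visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .datasets import (
    DeblurPair,
    DepthSample,
    FourLayerSample,
    N_DEPTH_CLASSES,
    TwoLayerSample,
)
from .optics import SensorView


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; ``loss`` must match the task."""

    loss: str  # cross_entropy | mse | bce
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0


def normalize_view(image: np.ndarray) -> np.ndarray:
    """Min-max normalize one view to [0, 1] (flat images map to 0)."""
    x = np.asarray(image, dtype=np.float32)
    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        return (x - lo) / (hi - lo)
    return np.zeros_like(x)


def _views_to_array(views: list[SensorView]) -> np.ndarray:
    return np.stack([normalize_view(v.image)[None] for v in views])


def log_spectrum_view(image: np.ndarray) -> np.ndarray:
    """Normalized log power spectrum of a view (Hann-windowed, centered).

    The depth of a layer is encoded in how fast the PSF attenuates high
    spatial frequencies, so the depth classifier works on the log power
    spectrum rather than raw pixels: the Gaussian kernel's ``exp(-(2 pi
    sigma f)^2)`` roll-off becomes a large, nearly linear feature in this
    representation.  Windowing suppresses boundary leakage that would
    otherwise mask the roll-off.  The result is min-max normalized and
    keeps the 51x51 single-channel input contract.
    """
    x = normalize_view(image)
    h, w = x.shape
    win = np.hanning(h)[:, None] * np.hanning(w)[None, :]
    power = np.abs(np.fft.fft2((x - x.mean()) * win)) ** 2
    s = np.log(np.fft.fftshift(power) + 1e-40)
    lo, hi = float(s.min()), float(s.max())
    if hi > lo:
        s = (s - lo) / (hi - lo)
    return s.astype(np.float32)


def _spectral_to_array(views: list[SensorView]) -> np.ndarray:
    return np.stack([log_spectrum_view(v.image)[None] for v in views])


def _dual_to_array(samples: list[FourLayerSample]) -> np.ndarray:
    xs = []
    for s in samples:
        a = normalize_view(s.view_a.image)
        if s.view_b is None:
            xs.append(a[None])
        else:
            xs.append(np.stack([a, normalize_view(s.view_b.image)]))
    return np.stack(xs)


# ---------------------------------------------------------------------------
# architectures


def build_depth_classifier(seed: int = 0) -> nn.Sequential:
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, 0))))
    return nn.Sequential(
        nn.Conv2d(1, 16, stride=2, rng=rng),
        nn.ReLU(),
        nn.Conv2d(16, 32, stride=2, rng=rng),
        nn.ReLU(),
        nn.Conv2d(32, 64, stride=2, rng=rng),
        nn.ReLU(),
        nn.Flatten(),
        nn.Dense(7 * 7 * 64, 256, rng=rng),
        nn.ReLU(),
        nn.Dense(256, N_DEPTH_CLASSES, rng=rng),
    )


def build_encoder_decoder(
    in_channels: int,
    out_channels: int,
    channels: tuple[int, int, int] = (16, 32, 64),
    final_sigmoid: bool = True,
    seed: int = 0,
) -> nn.Sequential:
    """3 conv + 3 deconv stages; 51x51 in, 51x51 out."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, 1))))
    c1, c2, c3 = channels
    layers: list[nn.Layer] = [
        nn.Conv2d(in_channels, c1, stride=2, rng=rng),
        nn.ReLU(),
        nn.Conv2d(c1, c2, stride=2, rng=rng),
        nn.ReLU(),
        nn.Conv2d(c2, c3, stride=2, rng=rng),
        nn.ReLU(),
        nn.ConvTranspose2d(c3, c2, output_padding=0, rng=rng),
        nn.ReLU(),
        nn.ConvTranspose2d(c2, c1, output_padding=1, rng=rng),
        nn.ReLU(),
        nn.ConvTranspose2d(c1, out_channels, output_padding=0, rng=rng),
    ]
    if final_sigmoid:
        layers.append(nn.Sigmoid())
    return nn.Sequential(*layers)


def build_resnet_detector(
    in_channels: int = 2,
    channels: int = 12,
    n_blocks: int = 4,
    seed: int = 0,
) -> nn.Sequential:
    """Residual feature extractor + 2-convolution detection head.

    Operates at full 51x51 resolution; the head emits 4 logistic planes.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, 2))))
    layers: list[nn.Layer] = [nn.Conv2d(in_channels, channels, rng=rng), nn.ReLU()]
    layers += [nn.ResidualBlock(channels, rng=rng) for _ in range(n_blocks)]
    layers += [
        nn.Conv2d(channels, channels, rng=rng),
        nn.ReLU(),
        nn.Conv2d(channels, 4, rng=rng),
        nn.Sigmoid(),
    ]
    return nn.Sequential(*layers)


# ---------------------------------------------------------------------------
# training entry points


def train_depth_classifier(
    train: list[DepthSample], cfg: TrainConfig
) -> tuple[nn.Sequential, list[float]]:
    if not train:
        raise ValueError("empty training set")
    labels = np.array([s.depth_class for s in train])
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 depth classes to train")
    x = _spectral_to_array([s.view for s in train])
    model = build_depth_classifier(cfg.seed)
    history = nn.fit(
        model,
        x,
        labels,
        nn.softmax_cross_entropy,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        lr=cfg.learning_rate,
        seed=cfg.seed,
    )
    return model, history


def train_deblur_net(
    train: list[DeblurPair], cfg: TrainConfig
) -> tuple[nn.Sequential, list[float]]:
    if not train:
        raise ValueError("empty training set")
    x = _views_to_array([p.blurred for p in train])
    y = np.stack([normalize_view(p.target.intensity)[None] for p in train])
    model = build_encoder_decoder(1, 1, final_sigmoid=False, seed=cfg.seed)
    history = nn.fit(
        model, x, y, nn.mse_loss,
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        lr=cfg.learning_rate, seed=cfg.seed,
    )
    return model, history


def train_depth_map_net(
    train: list[TwoLayerSample], cfg: TrainConfig
) -> tuple[nn.Sequential, list[float]]:
    """Two-layer depth-map regression (sigmoid output plane, MSE loss)."""
    if not train:
        raise ValueError("empty training set")
    x = _views_to_array([s.view for s in train])
    y = np.stack([s.depth_map[None] for s in train]).astype(np.float32)
    model = build_encoder_decoder(1, 1, final_sigmoid=True, seed=cfg.seed)
    history = nn.fit(
        model, x, y, nn.mse_loss,
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        lr=cfg.learning_rate, seed=cfg.seed,
    )
    return model, history


def train_detector(
    train: list[FourLayerSample],
    cfg: TrainConfig,
    arch: str = "encdec",
    **arch_kwargs,
) -> tuple[nn.Sequential, list[float]]:
    """Train the 4-plane cell detector (single- or dual-sensor input)."""
    if not train:
        raise ValueError("empty training set")
    x = _dual_to_array(train)
    in_channels = x.shape[1]
    y = np.stack([s.label_planes for s in train]).astype(np.float32)
    if arch == "encdec":
        model = build_encoder_decoder(in_channels, 4, seed=cfg.seed, **arch_kwargs)
    elif arch == "resnet":
        model = build_resnet_detector(in_channels, seed=cfg.seed, **arch_kwargs)
    else:
        raise ValueError(f"unknown detector architecture {arch!r}")
    history = nn.fit(
        model, x, y, nn.bce_loss,
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        lr=cfg.learning_rate, seed=cfg.seed,
    )
    return model, history


# ---------------------------------------------------------------------------
# inference


def predict(model: nn.Sequential, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Pure batched inference on a prepared (N, C, H, W) array."""
    if x.ndim != 4:
        raise ValueError(f"expected (N, C, H, W) input, got shape {x.shape}")
    return nn.predict_batched(model, x.astype(np.float32), batch_size)


def predict_depth_classes(model: nn.Sequential, views: list[SensorView]) -> np.ndarray:
    return predict(model, _spectral_to_array(views)).argmax(axis=1)


def predict_deblurred(model: nn.Sequential, views: list[SensorView]) -> np.ndarray:
    """Deblurred images in [0, 1]; negative intensities clamped."""
    out = predict(model, _views_to_array(views))[:, 0]
    return np.clip(out, 0.0, 1.0)


def predict_planes(model: nn.Sequential, samples: list[FourLayerSample]) -> np.ndarray:
    """(N, 4, H, W) cell-presence probabilities."""
    return predict(model, _dual_to_array(samples))


# ---------------------------------------------------------------------------
# checkpoints

_BUILDERS = {
    "depth_classifier": build_depth_classifier,
    "encoder_decoder": build_encoder_decoder,
    "resnet_detector": build_resnet_detector,
}


def save_model(
    model: nn.Sequential, path, arch: str, arch_kwargs: dict | None = None,
    meta: dict | None = None,
) -> None:
    """Write a checkpoint: parameter arrays + JSON metadata in one .npz."""
    import json

    blob = json.dumps(
        {"arch": arch, "arch_kwargs": arch_kwargs or {}, "meta": meta or {}}
    )
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    np.savez(path, _meta=np.array(blob), **arrays)


def load_model(path) -> tuple[nn.Sequential, dict]:
    """Rebuild the architecture from metadata and restore its parameters."""
    import json

    with np.load(path, allow_pickle=False) as data:
        info = json.loads(str(data["_meta"]))
        model = _BUILDERS[info["arch"]](**info["arch_kwargs"])
        params = model.params()
        for i, p in enumerate(params):
            p.value[...] = data[f"p{i}"]
    return model, info
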