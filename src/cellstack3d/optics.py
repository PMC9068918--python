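"""Depth-dependent PSF forward model for the lensless imager.

A chip-scale lensless sensor has no focusing optics, so its point spread
function widens with the distance between the emitting cell layer and
the sensor surface.  This module models that degradation with a
parametric kernel family (isotropic Gaussian or flat disc, width growing
linearly with depth, or a bank of measured kernels), blurs single layers
with it, and composes multi-layer acquisitions for one sensor or for two
sensors facing each other across the specimen.

All kernels are non-negative and sum to one (flux conservation): deeper
layers get dimmer per pixel only because their light spreads, not
because energy is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import fftconvolve

from .phantom import CellImage, IntensityStats, TumorMask

DEFAULT_SIGMA0_PX = 0.5
DEFAULT_SLOPE_PX_PER_MM = 4.0
DEFAULT_TRUNCATION_SIGMAS = 3.0
DEFAULT_SEPARATION_UM = 1000.0


@dataclass(frozen=True)
class PSFModel:
    """Depth-parameterized blur-kernel family.

    For ``kind="gaussian"`` the width follows
    ``sigma(z) = sigma0_px + slope_px_per_mm * z_mm`` and the kernel is
    truncated at ``truncation_radius_sigmas`` then renormalized.  For
    ``kind="disc"`` the same width law gives the disc radius.  For
    ``kind="measured"`` kernels come from ``kernel_bank`` (depth-um ->
    kernel grid) by nearest-neighbor depth lookup.
    """

    kind: Literal["gaussian", "disc", "measured"] = "gaussian"
    sigma0_px: float = DEFAULT_SIGMA0_PX
    slope_px_per_mm: float = DEFAULT_SLOPE_PX_PER_MM
    truncation_radius_sigmas: float = DEFAULT_TRUNCATION_SIGMAS
    kernel_bank: dict[float, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.sigma0_px < 0 or self.slope_px_per_mm < 0:
            raise ValueError("sigma0_px and slope_px_per_mm must be >= 0")
        if self.kind == "measured" and not self.kernel_bank:
            raise ValueError("measured PSF requires a non-empty kernel_bank")


@dataclass(frozen=True)
class SensorGeometry:
    """Two sensors facing each other: A at depth 0, B at ``separation_um``."""

    separation_um: float = DEFAULT_SEPARATION_UM

    def effective_depth(self, depth_um: float, sensor: str) -> float:
        """Distance between a layer and the given sensor's surface."""
        if not 0 <= depth_um <= self.separation_um:
            raise ValueError(
                f"depth {depth_um} um outside [0, {self.separation_um}] um"
            )
        if sensor == "A":
            return depth_um
        if sensor == "B":
            return self.separation_um - depth_um
        raise ValueError(f"unknown sensor {sensor!r}")


@dataclass(frozen=True)
class LayerStack:
    """Ordered (CellImage, depth-um) pairs; depth measured from sensor A."""

    layers: tuple[tuple[CellImage, float], ...]

    def __post_init__(self) -> None:
        depths = [d for _, d in self.layers]
        if any(d < 0 for d in depths):
            raise ValueError("depths must be non-negative")
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError("depths must be strictly increasing")

    @property
    def depths(self) -> tuple[float, ...]:
        return tuple(d for _, d in self.layers)


@dataclass(frozen=True)
class SensorView:
    """A single composite acquisition as seen by one sensor."""

    image: np.ndarray
    sensor_id: Literal["A", "B"] = "A"


def _gaussian_kernel(sigma: float, truncation_sigmas: float) -> np.ndarray:
    if sigma <= 0:
        return np.ones((1, 1))
    radius = max(int(np.ceil(truncation_sigmas * sigma)), 1)
    ax = np.arange(-radius, radius + 1)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return k / k.sum()


def _disc_kernel(radius: float) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1))
    r = max(int(np.ceil(radius)), 1)
    ax = np.arange(-r, r + 1)
    xx, yy = np.meshgrid(ax, ax)
    k = (xx**2 + yy**2 <= radius**2).astype(np.float64)
    return k / k.sum()


def psf_kernel(model: PSFModel, depth_um: float) -> np.ndarray:
    """Blur kernel at a given depth; normalized, odd side length."""
    if depth_um < 0:
        raise ValueError("depth must be non-negative")
    if model.kind == "measured":
        bank = model.kernel_bank or {}
        key = min(bank, key=lambda d: abs(d - depth_um))
        k = np.asarray(bank[key], dtype=np.float64)
        if k.min() < 0:
            raise ValueError("measured kernels must be non-negative")
        return k / k.sum()
    width = model.sigma0_px + model.slope_px_per_mm * (depth_um / 1000.0)
    if model.kind == "gaussian":
        return _gaussian_kernel(width, model.truncation_radius_sigmas)
    if model.kind == "disc":
        return _disc_kernel(width)
    raise ValueError(f"unknown PSF kind {model.kind!r}")


def blur(image: np.ndarray | CellImage, depth_um: float, model: PSFModel) -> np.ndarray:
    """Convolve an intensity grid with the PSF at ``depth_um``.

    Zero padding outside the frame: tissue beyond the field of view is
    treated as dark, appropriate for a dark-field fluorescence scene.
    """
    grid = image.intensity if isinstance(image, CellImage) else np.asarray(image)
    k = psf_kernel(model, depth_um)
    if k.shape == (1, 1):
        return grid.astype(np.float64) * k[0, 0]
    return fftconvolve(grid.astype(np.float64), k, mode="same")


def compose_stack(
    stack: LayerStack,
    model: PSFModel,
    sensor: Literal["A", "B"] = "A",
    geometry: SensorGeometry | None = None,
) -> SensorView:
    """Sum the depth-blurred layers into one sensor acquisition.

    Sensor A sees a layer at its nominal depth; sensor B, facing A from
    ``separation_um`` away, sees it at ``separation_um - depth``.  The raw
    sum is returned without renormalization.
    """
    if not stack.layers:
        raise ValueError("stack must contain at least one layer")
    geometry = geometry or SensorGeometry()
    total: np.ndarray | None = None
    for img, depth in stack.layers:
        eff = geometry.effective_depth(depth, sensor)
        b = blur(img, eff, model)
        total = b if total is None else total + b
    assert total is not None
    return SensorView(total, sensor)


def subtract_overlap(
    layer1: CellImage, layer2: CellImage, seed: int | None = None
) -> tuple[CellImage, CellImage]:
    """Remove mutually overlapping cell regions from a pair of layers.

    Pixels where both masks are set are cleared from both masks and
    repainted with freshly drawn background intensity, so the returned
    masks are disjoint — the construction used for the non-overlapping
    two-layer dataset.
    """
    if layer1.intensity.shape != layer2.intensity.shape:
        raise ValueError("layers must share a shape")
    overlap = layer1.mask.mask & layer2.mask.mask
    if not overlap.any():
        return layer1, layer2
    if seed is None:
        seed = (layer1.seed * 1_000_003 + layer2.seed) % (2**31)
    out = []
    for i, layer in enumerate((layer1, layer2)):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, i))))
        s = layer.stats
        bg = rng.normal(s.background_mean, s.background_std, layer.intensity.shape)
        np.clip(bg, 0.0, None, out=bg)
        intensity = np.where(overlap, bg, layer.intensity).astype(np.float32)
        mask = layer.mask.mask & ~overlap
        out.append(
            CellImage(intensity, TumorMask(mask, layer.mask.threshold), s, layer.seed)
        )
    return out[0], out[1]
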