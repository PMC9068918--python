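"""Builders for the five synthetic task datasets.

Each builder is a pure function of a configuration and a root seed:
per-sample child seeds are spawned from ``numpy.random.SeedSequence`` so
any dataset can be regenerated bit-exactly from its manifest.

Tasks
-----
- depth:        single blurred layer -> one of 20 depth classes
                (50, 150, ..., 1950 um; class = (depth - 50) / 100)
- deblur:       (blurred, sharp) pairs at continuous depths in [0, 1] mm
- nonoverlap:   two layers >= 500 um apart, overlap subtracted, labeled
                with a per-pixel normalized depth map
- overlap:      four layers in [0, 1] mm, one per 250 um bin, adjacent
                gaps >= 200 um, labeled with four binary planes;
                optionally a dual (two-sensor) acquisition
- dynamics:     four-step sequences in which a single cell cluster hops
                from layer 0 to layer 3 over a fixed background scene
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import phantom
from .optics import (
    LayerStack,
    PSFModel,
    SensorGeometry,
    SensorView,
    blur,
    compose_stack,
    subtract_overlap,
)
from .phantom import CellImage, TumorMask

DEPTH_CLASS_STEP_UM = 100.0
DEPTH_CLASS_OFFSET_UM = 50.0
N_DEPTH_CLASSES = 20
TWO_LAYER_MIN_GAP_UM = 500.0
FOUR_LAYER_MIN_GAP_UM = 200.0
FOUR_LAYER_BIN_UM = 250.0
STACK_EXTENT_UM = 1000.0
MAX_DEPTH_DRAW_ATTEMPTS = 1000


@dataclass(frozen=True)
class DepthSample:
    view: SensorView
    depth_um: float
    depth_class: int


@dataclass(frozen=True)
class DeblurPair:
    blurred: SensorView
    target: CellImage
    depth_um: float


@dataclass(frozen=True)
class TwoLayerSample:
    view: SensorView
    depth_map: np.ndarray  # 0 on background, depth/1000 on cell pixels
    depths: tuple[float, float]


@dataclass(frozen=True)
class FourLayerSample:
    view_a: SensorView
    view_b: SensorView | None  # present for dual-sensor acquisitions
    label_planes: np.ndarray  # (4, H, W) bool, ordered by distance from A
    depths: tuple[float, float, float, float]


@dataclass(frozen=True)
class TrajectorySequence:
    steps: tuple[FourLayerSample, ...]
    cluster_mask: np.ndarray
    cluster_layer_at_step: tuple[int, ...]


def depth_to_class(depth_um: float) -> int:
    """Map a bin-center depth (50, 150, ... 1950 um) to its class index."""
    return int(round((depth_um - DEPTH_CLASS_OFFSET_UM) / DEPTH_CLASS_STEP_UM))


def class_to_depth(depth_class: int) -> float:
    return DEPTH_CLASS_OFFSET_UM + DEPTH_CLASS_STEP_UM * depth_class


def _spawn_rng(seed: int, label: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, label))))


def build_depth_dataset(
    n_train: int,
    n_test: int,
    seed: int,
    model: PSFModel | None = None,
    **phantom_kwargs,
) -> tuple[list[DepthSample], list[DepthSample]]:
    """Single blurred layers at one of 20 depth classes in (0, 2] mm."""
    model = model or PSFModel()
    splits = []
    for split_idx, n in enumerate((n_train, n_test)):
        if n < 1:
            raise ValueError("n_train and n_test must be >= 1")
        rng = _spawn_rng(seed, split_idx)
        samples = []
        for i in range(n):
            cls = int(rng.integers(N_DEPTH_CLASSES))
            depth = class_to_depth(cls)
            img_seed = int(rng.integers(2**31))
            img = phantom.generate_cell_image(img_seed, **phantom_kwargs)
            samples.append(
                DepthSample(SensorView(blur(img, depth, model)), depth, cls)
            )
        splits.append(samples)
    return splits[0], splits[1]


def build_deblur_dataset(
    n: int, seed: int, model: PSFModel | None = None, **phantom_kwargs
) -> list[DeblurPair]:
    """(blurred, sharp) pairs at continuous uniform depths in [0, 1] mm."""
    if n < 1:
        raise ValueError("n must be >= 1")
    model = model or PSFModel()
    rng = _spawn_rng(seed, 10)
    pairs = []
    for i in range(n):
        depth = float(rng.uniform(0.0, STACK_EXTENT_UM))
        img = phantom.generate_cell_image(int(rng.integers(2**31)), **phantom_kwargs)
        pairs.append(DeblurPair(SensorView(blur(img, depth, model)), img, depth))
    return pairs


def _draw_two_depths(rng: np.random.Generator) -> tuple[float, float]:
    for _ in range(MAX_DEPTH_DRAW_ATTEMPTS):
        d1, d2 = rng.uniform(0.0, STACK_EXTENT_UM, size=2)
        if abs(d1 - d2) >= TWO_LAYER_MIN_GAP_UM:
            return (min(d1, d2), max(d1, d2))
    raise RuntimeError("could not satisfy the two-layer depth gap")  # pragma: no cover


def build_nonoverlap_dataset(
    n: int, seed: int, model: PSFModel | None = None, **phantom_kwargs
) -> list[TwoLayerSample]:
    """Two-layer stacks >= 500 um apart with mutually exclusive masks.

    Overlapping cell regions are subtracted from both layers before
    blurring, so every cell pixel belongs to exactly one depth; the
    label is a per-pixel depth map normalized by the 1 mm stack extent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    model = model or PSFModel()
    rng = _spawn_rng(seed, 20)
    samples = []
    for i in range(n):
        d1, d2 = _draw_two_depths(rng)
        img1 = phantom.generate_cell_image(int(rng.integers(2**31)), **phantom_kwargs)
        img2 = phantom.generate_cell_image(int(rng.integers(2**31)), **phantom_kwargs)
        img1, img2 = subtract_overlap(img1, img2, seed=int(rng.integers(2**31)))
        view = SensorView(blur(img1, d1, model) + blur(img2, d2, model))
        depth_map = np.zeros(img1.intensity.shape, dtype=np.float32)
        depth_map[img1.mask.mask] = d1 / STACK_EXTENT_UM
        depth_map[img2.mask.mask] = d2 / STACK_EXTENT_UM
        samples.append(TwoLayerSample(view, depth_map, (d1, d2)))
    return samples


def _draw_four_depths(rng: np.random.Generator) -> tuple[float, ...]:
    """One depth per 250 um bin, adjacent gaps >= 200 um."""
    for _ in range(MAX_DEPTH_DRAW_ATTEMPTS):
        depths = [
            float(rng.uniform(k * FOUR_LAYER_BIN_UM, (k + 1) * FOUR_LAYER_BIN_UM))
            for k in range(4)
        ]
        if all(b - a >= FOUR_LAYER_MIN_GAP_UM for a, b in zip(depths, depths[1:])):
            return tuple(depths)
    raise RuntimeError("could not satisfy the four-layer depth gaps")


def _compose_four_layer(
    images: list[CellImage],
    depths: tuple[float, ...],
    model: PSFModel,
    dual: bool,
    geometry: SensorGeometry,
) -> FourLayerSample:
    stack = LayerStack(tuple(zip(images, depths)))
    view_a = compose_stack(stack, model, "A", geometry)
    view_b = compose_stack(stack, model, "B", geometry) if dual else None
    planes = np.stack([img.mask.mask for img in images])
    return FourLayerSample(view_a, view_b, planes, tuple(depths))


def build_overlap_dataset(
    n: int,
    seed: int,
    dual: bool = False,
    model: PSFModel | None = None,
    geometry: SensorGeometry | None = None,
    **phantom_kwargs,
) -> list[FourLayerSample]:
    """Four uncorrelated layers in [0, 1] mm; overlaps are kept."""
    if n < 1:
        raise ValueError("n must be >= 1")
    model = model or PSFModel()
    geometry = geometry or SensorGeometry()
    rng = _spawn_rng(seed, 30)
    samples = []
    for i in range(n):
        depths = _draw_four_depths(rng)
        images = [
            phantom.generate_cell_image(int(rng.integers(2**31)), **phantom_kwargs)
            for _ in range(4)
        ]
        samples.append(_compose_four_layer(images, depths, model, dual, geometry))
    return samples


def _make_cluster_mask(
    shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """A single connected Perlin focus, the 'moving cluster'."""
    for _ in range(100):
        f = phantom.generate_perlin_field(
            shape, grid_period=8, seed=int(rng.integers(2**31))
        )
        cand = f.values > 0.75
        labels, nlab = ndimage.label(cand)
        if nlab == 0:
            continue
        sizes = ndimage.sum_labels(cand, labels, index=range(1, nlab + 1))
        best = int(np.argmax(sizes)) + 1
        mask = labels == best
        if 10 <= mask.sum() <= shape[0] * shape[1] // 4:
            return mask
    raise RuntimeError("could not draw a cluster mask")  # pragma: no cover


def build_moving_cluster_set(
    n_sequences: int,
    seed: int,
    model: PSFModel | None = None,
    geometry: SensorGeometry | None = None,
    **phantom_kwargs,
) -> list[TrajectorySequence]:
    """Sequences where one cluster hops from layer 0 to layer 3.

    The cluster footprint is reserved (cleared) in every base layer, so
    between steps only the cluster's layer assignment changes and the
    total cell-pixel count across planes stays constant.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    model = model or PSFModel()
    geometry = geometry or SensorGeometry()
    rng = _spawn_rng(seed, 40)
    sequences = []
    for s in range(n_sequences):
        depths = _draw_four_depths(rng)
        base = [
            phantom.generate_cell_image(int(rng.integers(2**31)), **phantom_kwargs)
            for _ in range(4)
        ]
        cluster = _make_cluster_mask(base[0].intensity.shape, rng)
        # reserve the cluster footprint in the background scene
        cleared = []
        for img in base:
            r = _spawn_rng(int(rng.integers(2**31)), 0)
            bg = r.normal(
                img.stats.background_mean, img.stats.background_std, img.shape
            )
            np.clip(bg, 0.0, None, out=bg)
            intensity = np.where(cluster, bg, img.intensity).astype(np.float32)
            mask = img.mask.mask & ~cluster
            cleared.append(
                CellImage(
                    intensity, TumorMask(mask, img.mask.threshold), img.stats, img.seed
                )
            )
        steps = []
        for t in range(4):
            layer_imgs = []
            for k, img in enumerate(cleared):
                if k == t:
                    r = _spawn_rng(seed + s, 100 + t)
                    sig = r.normal(img.stats.signal_mean, img.stats.signal_std, img.shape)
                    np.clip(sig, 0.0, None, out=sig)
                    intensity = np.where(cluster, sig, img.intensity).astype(np.float32)
                    mask = img.mask.mask | cluster
                    layer_imgs.append(
                        CellImage(
                            intensity,
                            TumorMask(mask, img.mask.threshold),
                            img.stats,
                            img.seed,
                        )
                    )
                else:
                    layer_imgs.append(img)
            steps.append(
                _compose_four_layer(layer_imgs, depths, model, True, geometry)
            )
        sequences.append(TrajectorySequence(tuple(steps), cluster, (0, 1, 2, 3)))
    return sequences


# ---------------------------------------------------------------------------
# validation


def validate_depth_sample(s: DepthSample) -> list[str]:
    errs = []
    if not 0 <= s.depth_class < N_DEPTH_CLASSES:
        errs.append(f"depth_class {s.depth_class} outside [0, {N_DEPTH_CLASSES})")
    if abs(class_to_depth(s.depth_class) - s.depth_um) > 1e-6:
        errs.append(f"depth {s.depth_um} does not match class {s.depth_class}")
    return errs


def validate_two_layer_sample(s: TwoLayerSample) -> list[str]:
    errs = []
    d1, d2 = s.depths
    if abs(d2 - d1) < TWO_LAYER_MIN_GAP_UM:
        errs.append(f"two-layer gap {abs(d2 - d1):.1f} um < {TWO_LAYER_MIN_GAP_UM}")
    if not (0 <= d1 <= STACK_EXTENT_UM and 0 <= d2 <= STACK_EXTENT_UM):
        errs.append("two-layer depth outside [0, 1000] um")
    vals = np.unique(s.depth_map[s.depth_map > 0])
    if len(vals) > 2:
        errs.append("depth map carries more than two distinct depth labels")
    return errs


def validate_four_layer_sample(s: FourLayerSample) -> list[str]:
    errs = []
    d = s.depths
    if any(b - a < FOUR_LAYER_MIN_GAP_UM for a, b in zip(d, d[1:])):
        errs.append(f"adjacent gap below {FOUR_LAYER_MIN_GAP_UM} um in {d}")
    if min(d) < 0 or max(d) > STACK_EXTENT_UM:
        errs.append(f"depth outside [0, {STACK_EXTENT_UM}] um in {d}")
    if s.label_planes.shape[0] != 4:
        errs.append("expected 4 label planes")
    return errs
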