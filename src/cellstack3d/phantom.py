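"""Synthetic tumor-cell phantom generation.

Single-layer fluorescence phantoms are built in three steps:

1. a coherent lattice-gradient (Perlin) noise field shapes smooth,
   blob-like "cell focus" structure;
2. thresholding the field yields a binary tumor mask (high values =
   tumor, low values = background);
3. per-pixel intensities are drawn from two Gaussian populations
   (signal on mask pixels, background elsewhere), clipped at zero.

Every function is a pure function of its arguments and seed, so whole
datasets are bit-reproducible from a config and a root seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_SHAPE = (51, 51)
DEFAULT_GRID_PERIOD = 10
DEFAULT_OCTAVES = 1
DEFAULT_PERSISTENCE = 0.5
DEFAULT_THRESHOLD = 0.5
DEFAULT_SNR_RANGE = (2.0, 10.0)
DEFAULT_BACKGROUND_MEAN_RANGE = (50.0, 150.0)
DEFAULT_CV = 0.15


@dataclass(frozen=True)
class NoiseField:
    """A 2D coherent-noise field min-max normalized to [0, 1]."""

    values: np.ndarray
    grid_period: int
    octaves: int
    persistence: float
    seed: int


@dataclass(frozen=True)
class TumorMask:
    """Binary cell-presence mask obtained by thresholding a noise field."""

    mask: np.ndarray
    threshold: float = DEFAULT_THRESHOLD


@dataclass(frozen=True)
class IntensityStats:
    """Two-population intensity model in arbitrary fluorescence units.

    ``signal_*`` describe pixels inside cell foci, ``background_*`` the
    surrounding tissue.  The signal-to-noise ratio reported by ``snr`` is
    the ratio of the two means, the convention used when calibrating the
    generator against real chip images.
    """

    signal_mean: float
    signal_std: float
    background_mean: float
    background_std: float

    def __post_init__(self) -> None:
        if self.signal_mean <= self.background_mean:
            raise ValueError("signal_mean must exceed background_mean")
        if min(self.signal_std, self.background_std, self.background_mean) < 0:
            raise ValueError("stds and background_mean must be non-negative")

    @property
    def snr(self) -> float:
        return self.signal_mean / self.background_mean


@dataclass(frozen=True)
class CellImage:
    """A rendered 51x51 phantom with its ground-truth mask and stats."""

    intensity: np.ndarray
    mask: TumorMask
    stats: IntensityStats
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


def _perlin_octave(
    shape: tuple[int, int], period: float, rng: np.random.Generator
) -> np.ndarray:
    """Classic 2D lattice-gradient noise at one frequency, range ~[-1, 1]."""
    h, w = shape
    ys = np.arange(h) / period
    xs = np.arange(w) / period
    iy = ys.astype(np.int64)
    ix = xs.astype(np.int64)
    fy = (ys - iy)[:, None]
    fx = (xs - ix)[None, :]

    # pseudorandom unit gradients on the integer lattice
    angles = rng.uniform(0.0, 2 * np.pi, size=(iy.max() + 2, ix.max() + 2))
    gy, gx = np.sin(angles), np.cos(angles)

    def dot(dy: int, dx: int) -> np.ndarray:
        ay = iy + dy
        ax = ix + dx
        return gx[np.ix_(ay, ax)] * (fx - dx) + gy[np.ix_(ay, ax)] * (fy - dy)

    # quintic fade (6t^5 - 15t^4 + 10t^3) for C2-continuous interpolation
    def fade(t: np.ndarray) -> np.ndarray:
        return t * t * t * (t * (t * 6 - 15) + 10)

    uy, ux = fade(fy), fade(fx)
    top = dot(0, 0) + ux * (dot(0, 1) - dot(0, 0))
    bot = dot(1, 0) + ux * (dot(1, 1) - dot(1, 0))
    return top + uy * (bot - top)


def generate_perlin_field(
    shape: tuple[int, int] = DEFAULT_SHAPE,
    grid_period: int = DEFAULT_GRID_PERIOD,
    octaves: int = DEFAULT_OCTAVES,
    persistence: float = DEFAULT_PERSISTENCE,
    seed: int = 0,
) -> NoiseField:
    """Generate a normalized Perlin noise field.

    Octaves double the spatial frequency while attenuating amplitude by
    ``persistence``; the sum is min-max normalized to [0, 1].
    """
    h, w = shape
    if h < 8 or w < 8:
        raise ValueError(f"shape must be at least 8x8, got {shape}")
    if grid_period < 2:
        raise ValueError("grid_period must be >= 2")
    if octaves < 1:
        raise ValueError("octaves must be >= 1")
    if not 0 < persistence <= 1:
        raise ValueError("persistence must be in (0, 1]")

    total = np.zeros(shape, dtype=np.float64)
    for o in range(octaves):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, o))))
        period = max(grid_period / 2**o, 1.5)
        total += persistence**o * _perlin_octave(shape, period, rng)

    lo, hi = total.min(), total.max()
    if hi > lo:
        total = (total - lo) / (hi - lo)
    else:  # degenerate flat field
        total = np.full(shape, 0.5)
    return NoiseField(total, grid_period, octaves, persistence, seed)


def threshold_mask(field: NoiseField, threshold: float = DEFAULT_THRESHOLD) -> TumorMask:
    """Binarize a noise field: values above ``threshold`` are tumor."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return TumorMask(field.values > threshold, threshold)


def sample_stats(
    snr_range: tuple[float, float] = DEFAULT_SNR_RANGE,
    background_mean_range: tuple[float, float] = DEFAULT_BACKGROUND_MEAN_RANGE,
    cv: float = DEFAULT_CV,
    rng_seed: int = 0,
) -> IntensityStats:
    """Draw per-image intensity statistics.

    The SNR and background mean are uniform over their ranges; the signal
    mean is ``background_mean * snr``; standard deviations are a fixed
    coefficient of variation ``cv`` times the respective means.
    """
    lo, hi = snr_range
    if not 1 < lo <= hi:
        raise ValueError("snr_range must satisfy 1 < lo <= hi")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(rng_seed)))
    snr = rng.uniform(lo, hi)
    background_mean = rng.uniform(*background_mean_range)
    signal_mean = background_mean * snr
    return IntensityStats(
        signal_mean=signal_mean,
        signal_std=cv * signal_mean,
        background_mean=background_mean,
        background_std=cv * background_mean,
    )


def render_cell_image(mask: TumorMask, stats: IntensityStats, seed: int) -> CellImage:
    """Render intensities over a mask: Gaussian signal/background, clipped at 0."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    shape = mask.mask.shape
    background = rng.normal(stats.background_mean, stats.background_std, shape)
    signal = rng.normal(stats.signal_mean, stats.signal_std, shape)
    intensity = np.where(mask.mask, signal, background)
    np.clip(intensity, 0.0, None, out=intensity)
    return CellImage(intensity.astype(np.float32), mask, stats, seed)


def generate_cell_image(
    seed: int,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    grid_period: int = DEFAULT_GRID_PERIOD,
    octaves: int = DEFAULT_OCTAVES,
    persistence: float = DEFAULT_PERSISTENCE,
    threshold: float = DEFAULT_THRESHOLD,
    snr_range: tuple[float, float] = DEFAULT_SNR_RANGE,
    background_mean_range: tuple[float, float] = DEFAULT_BACKGROUND_MEAN_RANGE,
    cv: float = DEFAULT_CV,
) -> CellImage:
    """One-stop phantom: Perlin field -> mask -> stats -> rendered image.

    Child seeds for the field, stats and rendering are derived from
    ``seed`` by fixed offsets so the whole image is reproducible.
    """
    f = generate_perlin_field(shape, grid_period, octaves, persistence, seed=seed)
    m = threshold_mask(f, threshold)
    s = sample_stats(snr_range, background_mean_range, cv, rng_seed=seed + 1)
    return render_cell_image(m, s, seed=seed + 2)
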