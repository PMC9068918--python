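"""Evaluation metrics and 3D reconstruction export.

Pixel-level conventions:

- error rate: fraction of pixels whose thresholded prediction disagrees
  with the binary ground truth;
- sensitivity: TP / (TP + FN) over ground-truth cell pixels;
- specificity: TN / (TN + FP) over ground-truth empty pixels;
- mean normalized deviation (continuous maps): mean |pred - truth|
  divided by the dynamic range of the truth, reported as a fraction.

Multi-sample reporting computes the metric per sample and averages the
per-sample values.  ROC analysis pools pixels across layers and samples.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from sklearn import metrics as _skm

from .optics import SensorGeometry


@dataclass(frozen=True)
class PixelMetrics:
    error_rate: float
    sensitivity: float  # NaN when the truth has no cell pixels
    specificity: float  # NaN when the truth has no empty pixels


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray  # descending
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class VoxelReconstruction:
    """Binary occupancy planes placed at their depths in a voxel grid."""

    occupancy: np.ndarray  # (n_z, H, W) uint8
    z_um: np.ndarray  # depth coordinate of every z slice
    sensor_z_um: tuple[float, float]


def pixel_error_rate(
    pred_plane: np.ndarray, truth_plane: np.ndarray, threshold: float = 0.5
) -> float:
    """Fraction of pixels mislabeled after thresholding the prediction."""
    pred_plane = np.asarray(pred_plane)
    truth_plane = np.asarray(truth_plane).astype(bool)
    if pred_plane.shape != truth_plane.shape:
        raise ValueError("prediction and truth shapes differ")
    return float(np.mean((pred_plane > threshold) != truth_plane))


def mean_normalized_deviation(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean |pred - truth| over the dynamic range of the truth."""
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    rng = truth.max() - truth.min()
    if rng == 0:
        rng = 1.0
    return float(np.mean(np.abs(pred - truth)) / rng)


def depth_metrics(
    pred_classes: np.ndarray, true_classes: np.ndarray, step_um: float = 100.0
) -> tuple[float, float]:
    """(exact-class accuracy, maximum depth error in um)."""
    pred_classes = np.asarray(pred_classes)
    true_classes = np.asarray(true_classes)
    if pred_classes.size == 0:
        raise ValueError("empty prediction array")
    if pred_classes.shape != true_classes.shape:
        raise ValueError("length mismatch")
    accuracy = float(np.mean(pred_classes == true_classes))
    max_error = float(np.abs(pred_classes - true_classes).max() * step_um)
    return accuracy, max_error


def sensitivity_specificity(
    pred_planes: np.ndarray, truth_planes: np.ndarray, threshold: float = 0.5
) -> tuple[list[PixelMetrics], PixelMetrics]:
    """Per-plane and averaged confusion metrics over a (L, H, W) stack.

    Planes without ground-truth cell (or empty) pixels contribute NaN to
    the corresponding rate and are excluded from the average, with a
    warning.
    """
    pred_planes = np.asarray(pred_planes)
    truth_planes = np.asarray(truth_planes).astype(bool)
    if pred_planes.shape != truth_planes.shape:
        raise ValueError("prediction and truth shapes differ")
    per_layer: list[PixelMetrics] = []
    for pred, truth in zip(pred_planes, truth_planes):
        hard = pred > threshold
        tp = float(np.sum(hard & truth))
        fn = float(np.sum(~hard & truth))
        tn = float(np.sum(~hard & ~truth))
        fp = float(np.sum(hard & ~truth))
        sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
        spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
        if np.isnan(sens):
            warnings.warn("plane with no ground-truth cell pixels: sensitivity undefined")
        per_layer.append(PixelMetrics(float(np.mean(hard != truth)), sens, spec))
    mean = PixelMetrics(
        float(np.mean([m.error_rate for m in per_layer])),
        float(np.nanmean([m.sensitivity for m in per_layer])),
        float(np.nanmean([m.specificity for m in per_layer])),
    )
    return per_layer, mean


def roc_curve(
    pred_planes: np.ndarray, truth_planes: np.ndarray, n_thresholds: int | None = None
) -> RocCurve:
    """ROC over pixels pooled across layers and samples.

    ``n_thresholds``, when given, subsamples the operating points for
    compact export; the AUC is always computed on the full curve by the
    trapezoid rule.
    """
    if n_thresholds is not None and n_thresholds < 2:
        raise ValueError("n_thresholds must be >= 2")
    scores = np.asarray(pred_planes, float).ravel()
    truth = np.asarray(truth_planes).astype(bool).ravel()
    if truth.all() or not truth.any():
        raise ValueError("single-class ground truth yields a degenerate ROC")
    fpr, tpr, thr = _skm.roc_curve(truth, scores)
    auc = float(_skm.auc(fpr, tpr))
    if n_thresholds is not None and len(thr) > n_thresholds:
        idx = np.linspace(0, len(thr) - 1, n_thresholds).astype(int)
        fpr, tpr, thr = fpr[idx], tpr[idx], thr[idx]
    return RocCurve(thr, tpr, fpr, auc)


def reconstruct_3d(
    pred_planes: np.ndarray,
    depths_um: list[float] | np.ndarray,
    geometry: SensorGeometry | None = None,
    threshold: float = 0.5,
    z_step_um: float = 50.0,
) -> VoxelReconstruction:
    """Place thresholded prediction planes at their depths in a 3D grid.

    The grid spans [0, separation] along z at ``z_step_um`` resolution;
    each prediction plane occupies the nearest z slice, and the two
    sensor surfaces sit at z = 0 and z = separation.
    """
    geometry = geometry or SensorGeometry()
    pred_planes = np.asarray(pred_planes)
    depths = np.asarray(depths_um, float)
    if pred_planes.shape[0] != depths.size:
        raise ValueError("one depth per plane required")
    if depths.min() < 0 or depths.max() > geometry.separation_um:
        raise ValueError("depth outside [0, separation]")
    z = np.arange(0.0, geometry.separation_um + z_step_um / 2, z_step_um)
    occ = np.zeros((z.size,) + pred_planes.shape[1:], dtype=np.uint8)
    for plane, d in zip(pred_planes, depths):
        occ[int(np.argmin(np.abs(z - d)))] |= (plane > threshold).astype(np.uint8)
    return VoxelReconstruction(occ, z, (0.0, geometry.separation_um))


def export_reconstruction(rec: VoxelReconstruction, out_dir: str | Path) -> None:
    """Write a voxel CSV (x, y, z_um) and an occupancy TIFF stack."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out_dir / "occupancy.tif", rec.occupancy)
    with open(out_dir / "voxels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_px", "y_px", "z_um"])
        for zi, plane in enumerate(rec.occupancy):
            ys, xs = np.nonzero(plane)
            for x, y in zip(xs, ys):
                w.writerow([int(x), int(y), float(rec.z_um[zi])])


def import_reconstruction(out_dir: str | Path) -> np.ndarray:
    """Read back the occupancy TIFF written by :func:`export_reconstruction`."""
    return tifffile.imread(Path(out_dir) / "occupancy.tif")
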