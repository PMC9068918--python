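"""Dataset export, manifests and on-disk validation.

Datasets are written as 16-bit grayscale TIFF views, 8-bit PNG masks
and a ``manifest.csv`` naming every sample, its seed and its depths,
next to a ``config_snapshot.yaml`` capturing the generating
configuration — enough to regenerate or audit any dataset bit-exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from . import datasets as ds


def _to_uint16(image: np.ndarray) -> np.ndarray:
    x = np.asarray(image, float)
    hi = x.max()
    if hi > 0:
        x = x / hi
    return (x * 65535).astype(np.uint16)


def write_view(path: Path, image: np.ndarray) -> None:
    tifffile.imwrite(path, _to_uint16(image))


def write_mask(path: Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))


@dataclass
class ManifestRow:
    sample_id: str
    seed: int
    depths_um: list[float]
    split: str
    files: list[str]
    extra: dict = field(default_factory=dict)


def write_manifest(out_dir: Path, task: str, rows: list[ManifestRow], config: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "task", "seed", "depths_um", "split", "files"])
        for r in rows:
            w.writerow(
                [
                    r.sample_id,
                    task,
                    r.seed,
                    ";".join(f"{d:.3f}" for d in r.depths_um),
                    r.split,
                    ";".join(r.files),
                ]
            )
    with open(out_dir / "config_snapshot.yaml", "w") as fh:
        yaml.safe_dump({"task": task, **config}, fh)


def save_depth_dataset(
    out_dir: str | Path, train: list[ds.DepthSample], test: list[ds.DepthSample],
    seed: int, config: dict | None = None,
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for split, samples in (("train", train), ("test", test)):
        for i, s in enumerate(samples):
            sid = f"{split}_{i:05d}"
            f = f"{sid}.tif"
            write_view(out_dir / f, s.view.image)
            rows.append(ManifestRow(sid, seed, [s.depth_um], split, [f]))
    write_manifest(out_dir, "depth", rows, config or {})


def save_four_layer_dataset(
    out_dir: str | Path, samples: list[ds.FourLayerSample],
    seed: int, config: dict | None = None,
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        sid = f"sample_{i:05d}"
        files = [f"{sid}_A.tif"]
        write_view(out_dir / files[0], s.view_a.image)
        if s.view_b is not None:
            files.append(f"{sid}_B.tif")
            write_view(out_dir / files[-1], s.view_b.image)
        for k in range(4):
            files.append(f"{sid}_plane{k}.png")
            write_mask(out_dir / files[-1], s.label_planes[k])
        rows.append(ManifestRow(sid, seed, list(s.depths), "train", files))
    write_manifest(out_dir, "overlap", rows, config or {})


@dataclass
class ValidationReport:
    passed: bool
    violations: list[str]


def validate_manifest(path: str | Path) -> ValidationReport:
    """Re-check dataset invariants (gaps, ranges, file integrity) on disk."""
    path = Path(path)
    manifest = path if path.is_file() else path / "manifest.csv"
    if not manifest.exists():
        return ValidationReport(False, [f"manifest not found at {manifest}"])
    violations: list[str] = []
    with open(manifest) as fh:
        for row in csv.DictReader(fh):
            sid, task = row["sample_id"], row["task"]
            depths = [float(d) for d in row["depths_um"].split(";") if d]
            if task == "depth":
                if not depths or not (
                    0 < depths[0] <= 2000
                    and abs((depths[0] - 50) % 100) < 1e-6
                ):
                    violations.append(f"{sid}: invalid depth {depths}")
            elif task == "nonoverlap":
                if len(depths) != 2 or abs(depths[1] - depths[0]) < ds.TWO_LAYER_MIN_GAP_UM:
                    violations.append(f"{sid}: two-layer gap violation {depths}")
            elif task in ("overlap", "dynamics"):
                gaps_ok = all(
                    b - a >= ds.FOUR_LAYER_MIN_GAP_UM
                    for a, b in zip(depths, depths[1:])
                )
                if len(depths) != 4 or not gaps_ok:
                    violations.append(f"{sid}: four-layer gap violation {depths}")
                if depths and (min(depths) < 0 or max(depths) > ds.STACK_EXTENT_UM):
                    violations.append(f"{sid}: depth outside [0, 1000] um")
            for f in row["files"].split(";"):
                fp = manifest.parent / f
                try:
                    if f.endswith(".tif"):
                        tifffile.imread(fp)
                    else:
                        iio.imread(fp)
                except Exception as exc:  # noqa: BLE001 - diagnosis wanted
                    violations.append(f"{sid}: unreadable file {f}: {exc}")
    return ValidationReport(not violations, violations)
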