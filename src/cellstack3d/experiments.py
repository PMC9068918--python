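"""End-to-end experiment orchestration.

``run_experiment(name, cfg)`` regenerates the data for one of the
study's experiments, trains the corresponding network, evaluates it and
returns a JSON-serializable report.  With ``output_dir`` set, the report,
a config snapshot and (for detector tasks) a 3D reconstruction of the
first test sample are written to disk.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from . import datasets as ds
from . import metrics, models
from .config import config_hash, snapshot
from .models import TrainConfig
from .optics import PSFModel, SensorGeometry

EXPERIMENTS = (
    "depth",
    "deblur",
    "nonoverlap",
    "overlap_single",
    "overlap_dual",
    "overlap_resnet",
    "dynamics",
)


def psf_from_config(cfg: dict) -> PSFModel:
    o = cfg["optics"]
    return PSFModel(
        kind=o["kind"],
        sigma0_px=o["sigma0_px"],
        slope_px_per_mm=o["slope_px_per_mm"],
        truncation_radius_sigmas=o["truncation_radius_sigmas"],
    )


def geometry_from_config(cfg: dict) -> SensorGeometry:
    return SensorGeometry(separation_um=cfg["optics"]["separation_um"])


def phantom_kwargs(cfg: dict) -> dict:
    p = cfg["phantom"]
    return {
        "shape": tuple(p["shape"]),
        "grid_period": p["grid_period"],
        "octaves": p["octaves"],
        "persistence": p["persistence"],
        "threshold": p["threshold"],
        "snr_range": tuple(p["snr_range"]),
        "background_mean_range": tuple(p["background_mean_range"]),
        "cv": p["cv"],
    }


def train_config(cfg: dict, loss: str) -> TrainConfig:
    t = cfg["train"]
    return TrainConfig(
        loss=loss,
        epochs=t["epochs"],
        batch_size=t["batch_size"],
        learning_rate=t["learning_rate"],
        seed=t["seed"],
    )


def _run_depth(cfg: dict) -> dict:
    d = cfg["dataset"]
    train, test = ds.build_depth_dataset(
        d["n_train"], d["n_test"], d["seed"], psf_from_config(cfg), **phantom_kwargs(cfg)
    )
    model, history = models.train_depth_classifier(train, train_config(cfg, "cross_entropy"))
    pred = models.predict_depth_classes(model, [s.view for s in test])
    truth = np.array([s.depth_class for s in test])
    accuracy, max_error = metrics.depth_metrics(pred, truth)
    return {
        "accuracy": accuracy,
        "max_error_um": max_error,
        "n_test": len(test),
        "final_train_loss": history[-1],
        "_model": model,
    }


def _run_deblur(cfg: dict) -> dict:
    d = cfg["dataset"]
    psf, pk = psf_from_config(cfg), phantom_kwargs(cfg)
    train = ds.build_deblur_dataset(d["n_train"], d["seed"], psf, **pk)
    test = ds.build_deblur_dataset(d["n_test"], d["seed"] + 1, psf, **pk)
    model, history = models.train_deblur_net(train, train_config(cfg, "mse"))
    pred = models.predict_deblurred(model, [p.blurred for p in test])
    devs = [
        metrics.mean_normalized_deviation(
            pred[i], models.normalize_view(p.target.intensity)
        )
        for i, p in enumerate(test)
    ]
    return {
        "mean_pixel_error": float(np.mean(devs)),
        "std_pixel_error": float(np.std(devs)),
        "n_test": len(test),
        "final_train_loss": history[-1],
        "_model": model,
    }


def _run_nonoverlap(cfg: dict) -> dict:
    d = cfg["dataset"]
    psf, pk = psf_from_config(cfg), phantom_kwargs(cfg)
    train = ds.build_nonoverlap_dataset(d["n_train"], d["seed"], psf, **pk)
    test = ds.build_nonoverlap_dataset(d["n_test"], d["seed"] + 1, psf, **pk)
    model, history = models.train_depth_map_net(train, train_config(cfg, "mse"))
    pred = models.predict(model, models._views_to_array([s.view for s in test]))[:, 0]
    devs = [
        metrics.mean_normalized_deviation(pred[i], s.depth_map)
        for i, s in enumerate(test)
    ]
    return {
        "mean_depth_map_deviation": float(np.mean(devs)),
        "std_depth_map_deviation": float(np.std(devs)),
        "n_test": len(test),
        "final_train_loss": history[-1],
        "_model": model,
    }


def _run_overlap(cfg: dict, dual: bool, arch: str = "encdec") -> dict:
    d = cfg["dataset"]
    psf, geom, pk = psf_from_config(cfg), geometry_from_config(cfg), phantom_kwargs(cfg)
    train = ds.build_overlap_dataset(d["n_train"], d["seed"], dual, psf, geom, **pk)
    test = ds.build_overlap_dataset(d["n_test"], d["seed"] + 1, dual, psf, geom, **pk)
    model, history = models.train_detector(train, train_config(cfg, "bce"), arch=arch)
    pred = models.predict_planes(model, test)
    thr = cfg["eval"]["threshold"]
    per_sample = np.array(
        [
            [metrics.pixel_error_rate(pred[i, k], s.label_planes[k], thr) for k in range(4)]
            for i, s in enumerate(test)
        ]
    )
    truth = np.stack([s.label_planes for s in test])
    roc = metrics.roc_curve(pred.reshape(-1, *pred.shape[2:]), truth.reshape(-1, *truth.shape[2:]))
    _, mean_ss = metrics.sensitivity_specificity(
        pred.reshape(-1, *pred.shape[2:]), truth.reshape(-1, *truth.shape[2:]), thr
    )
    report = {
        "per_layer_error_rate": per_sample.mean(axis=0).tolist(),
        "mean_error_rate": float(per_sample.mean()),
        "sensitivity": mean_ss.sensitivity,
        "specificity": mean_ss.specificity,
        "auc": roc.auc,
        "n_test": len(test),
        "final_train_loss": history[-1],
        "_model": model,
        "_first_sample": (pred[0], test[0].depths),
    }
    return report


def _run_dynamics(cfg: dict) -> dict:
    """Residual dual-sensor detector evaluated on moving-cluster sequences."""
    d = cfg["dataset"]
    psf, geom, pk = psf_from_config(cfg), geometry_from_config(cfg), phantom_kwargs(cfg)
    train = ds.build_overlap_dataset(d["n_train"], d["seed"], True, psf, geom, **pk)
    n_seq = max(d["n_test"] // 4, 1)
    sequences = ds.build_moving_cluster_set(n_seq, d["seed"] + 1, psf, geom, **pk)
    model, history = models.train_detector(train, train_config(cfg, "bce"), arch="resnet")
    steps = [step for seq in sequences for step in seq.steps]
    pred = models.predict_planes(model, steps)
    truth = np.stack([s.label_planes for s in steps])
    thr = cfg["eval"]["threshold"]
    per_layer = []
    for k in range(4):
        _, mean_ss = metrics.sensitivity_specificity(pred[:, k], truth[:, k], thr)
        per_layer.append(mean_ss)
    roc = metrics.roc_curve(pred.reshape(-1, *pred.shape[2:]), truth.reshape(-1, *truth.shape[2:]))
    # cluster tracking: restrict the metrics to the moving cluster's pixels
    c_sens = []
    for seq in sequences:
        p = models.predict_planes(model, list(seq.steps))
        for t, step in enumerate(seq.steps):
            layer = seq.cluster_layer_at_step[t]
            c_sens.append(float(np.mean(p[t, layer][seq.cluster_mask] > thr)))
    return {
        "sensitivity_per_layer": [m.sensitivity for m in per_layer],
        "specificity_per_layer": [m.specificity for m in per_layer],
        "mean_sensitivity": float(np.mean([m.sensitivity for m in per_layer])),
        "mean_specificity": float(np.mean([m.specificity for m in per_layer])),
        "cluster_sensitivity": float(np.mean(c_sens)),
        "auc": roc.auc,
        "n_sequences": len(sequences),
        "final_train_loss": history[-1],
        "_model": model,
    }


def run_experiment(name: str, cfg: dict) -> dict:
    """Run one named experiment end to end and return its report."""
    runners = {
        "depth": _run_depth,
        "deblur": _run_deblur,
        "nonoverlap": _run_nonoverlap,
        "overlap_single": lambda c: _run_overlap(c, dual=False),
        "overlap_dual": lambda c: _run_overlap(c, dual=True),
        "overlap_resnet": lambda c: _run_overlap(c, dual=True, arch="resnet"),
        "dynamics": _run_dynamics,
    }
    if name not in runners:
        raise ValueError(f"unknown experiment {name!r}; choose from {EXPERIMENTS}")
    t0 = time.time()
    report = runners[name](cfg)
    model = report.pop("_model", None)
    first = report.pop("_first_sample", None)
    report.update(
        {"experiment": name, "config_hash": config_hash(cfg), "runtime_s": time.time() - t0}
    )
    out = cfg.get("output_dir")
    if out:
        out = Path(out) / name
        out.mkdir(parents=True, exist_ok=True)
        snapshot(cfg, out)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        if model is not None:
            arch, kwargs = {
                "depth": ("depth_classifier", {}),
                "deblur": (
                    "encoder_decoder",
                    {"in_channels": 1, "out_channels": 1, "final_sigmoid": False},
                ),
                "nonoverlap": ("encoder_decoder", {"in_channels": 1, "out_channels": 1}),
                "overlap_single": ("encoder_decoder", {"in_channels": 1, "out_channels": 4}),
                "overlap_dual": ("encoder_decoder", {"in_channels": 2, "out_channels": 4}),
                "overlap_resnet": ("resnet_detector", {"in_channels": 2}),
                "dynamics": ("resnet_detector", {"in_channels": 2}),
            }[name]
            models.save_model(model, out / "model.npz", arch, kwargs, meta={"experiment": name})
        if first is not None:
            pred_planes, depths = first
            rec = metrics.reconstruct_3d(pred_planes, list(depths), geometry_from_config(cfg))
            metrics.export_reconstruction(rec, out / "reconstruction")
    return report
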