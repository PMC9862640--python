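"""End-to-end orchestration of the sorting cascade.

Two operating modes mirror the machine software: *acquire* stages raw
per-cocoon captures into the canonical on-disk layout (one BMP folder per
camera, the photodiode CSV in its folder, names embedding timestamp, camera
and progressive number), and *select* runs every record through the station
cascade - size gate, shape model, top/bottom stain detection, alive/dead
sensor model - recording all verdicts and routing each cocoon on its first
failing station in the physical order.  When ground truth is available the
evaluation layer reports a confusion matrix, overall accuracy (one-decimal
percent) and recall per station; positive cases are the defect classes:
undersized-or-oversized, bad-shaped, stained, and dead cocoons.
"""

from __future__ import annotations

import json
import logging
import shutil
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import classifiers, imaging, morphometrics, sensor, stains
from .config import PipelineConfig
from .errors import CocoonSortError, ValidationError

logger = logging.getLogger("cocoonsort")

ROUTE_ORDER = ("size", "shape", "stain", "vital")
ROUTE_LABELS = {
    "size": "discard:size",
    "shape": "discard:shape",
    "stain": "class:stained",
    "vital": "class:dead",
}
PASS_ROUTE = "grade:first"

SHAPE_GOOD, SHAPE_BAD = "good", "bad"


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def segment_cocoon(rgb: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """RGB frame -> filled single-cocoon mask (HSB, edge map, Otsu, largest
    component)."""
    hsb = imaging.rgb_to_hsb(rgb)
    edge = imaging.edge_map(hsb, eps=config.imaging.eps)
    mask = imaging.otsu_binarize(edge, foreground=config.imaging.foreground)
    return imaging.select_cocoon_region(mask, connectivity=config.imaging.connectivity)


# ---------------------------------------------------------------------------
# Acquisition mode
# ---------------------------------------------------------------------------

def run_acquire(input_dir, output_dir) -> pd.DataFrame:
    """Stage a capture session into the canonical dataset layout.

    ``input_dir`` must contain a ``manifest.csv`` referencing the per-camera
    images plus ``sensor/sensor.csv``.  Images are copied under one folder
    per camera with ``{timestamp}_{camera}_{id:06d}.bmp`` names, the sensor
    CSV is rewritten in its folder, and a manifest with normalized paths
    (ground-truth columns passed through) is returned and saved.
    """
    src = Path(input_dir)
    out = Path(output_dir)
    manifest_path = src / "manifest.csv"
    if not manifest_path.exists():
        raise ValidationError(f"no manifest.csv under {src}")
    manifest = pd.read_csv(manifest_path)
    frames = sensor.read_sensor_csv(src / "sensor" / "sensor.csv")
    known_ids = {f.cocoon_id for f in frames}

    for cam in ("camera_shape", "camera_top", "camera_bottom"):
        (out / cam).mkdir(parents=True, exist_ok=True)
    (out / "sensor").mkdir(parents=True, exist_ok=True)

    rows = []
    for rec in manifest.to_dict("records"):
        cid = int(rec["id"])
        ts = str(rec.get("timestamp", f"{cid:014d}"))
        if cid not in known_ids:
            raise ValidationError(f"cocoon {cid} has no sensor frame")
        for cam in ("camera_shape", "camera_top", "camera_bottom"):
            col = f"{cam.removeprefix('camera_')}_image"
            src_img = src / str(rec[col])
            if not src_img.exists():
                raise ValidationError(f"missing image {src_img}")
            fname = f"{ts}_{cam}_{cid:06d}.bmp"
            shutil.copyfile(src_img, out / cam / fname)
            rec[col] = f"{cam}/{fname}"
        rows.append(rec)

    sensor.write_sensor_csv(out / "sensor" / "sensor.csv", frames)
    staged = pd.DataFrame.from_records(rows)
    staged.to_csv(out / "manifest.csv", index=False)
    return staged


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def extract_shape_features(
    dataset_dir, manifest: pd.DataFrame, config: PipelineConfig
) -> list[morphometrics.Outline]:
    base = Path(dataset_dir)
    outlines = []
    for rec in manifest.to_dict("records"):
        mask = segment_cocoon(read_image(base / str(rec["shape_image"])), config)
        outlines.append(
            morphometrics.digitize_outline(mask, n_points=config.imaging.outline_points)
        )
    return outlines


def train_shape_model(dataset_dir, config: PipelineConfig, seed=None) -> dict:
    """Fit the shape station: segment, digitize, GPA, EFA, truncate,
    balance, 70/30 split, logistic fit, then 100-iteration Monte Carlo CV.

    Returns a dict with the model, standardizer, metadata (mean shape,
    truncation order) and the held-out/CV reports.
    """
    base = Path(dataset_dir)
    manifest = pd.read_csv(base / "manifest.csv")
    if "true_shape_class" not in manifest.columns:
        raise ValidationError("manifest lacks true_shape_class labels")
    labels = manifest["true_shape_class"].to_numpy()

    outlines = extract_shape_features(dataset_dir, manifest, config)
    aligned = morphometrics.procrustes_align(outlines)
    n_h = min(config.shape_model.n_harmonics, config.imaging.outline_points // 2)
    descriptors = [
        morphometrics.efa_decompose(pts, n_h, method=config.shape_model.efa_method)
        for pts in aligned.outlines
    ]
    k = morphometrics.truncation_order(descriptors, config.shape_model.power_fraction)
    features = np.stack([d.flat_coefficients(k) for d in descriptors])
    schema = [
        f"{name}{h}" for h in range(1, k + 1) for name in ("a", "b", "c", "d")
    ]

    ss = np.random.SeedSequence(seed)
    s_balance, s_split, s_cv = ss.spawn(3)
    xb, yb = classifiers.balance_binary(features, labels, np.random.default_rng(s_balance))
    tr, te = classifiers.stratified_split(
        yb, config.shape_model.train_fraction, np.random.default_rng(s_split)
    )
    std = classifiers.Standardizer.fit(xb[tr], on_constant="drop")
    model = classifiers.fit_logistic(
        std.apply(xb[tr]),
        yb[tr],
        positive_label=SHAPE_BAD,
        feature_schema=[schema[c] for c in std.kept_columns],
    )
    report = {}
    for split_name, idx in (("train", tr), ("test", te)):
        pred = model.predict(std.apply(xb[idx]))
        cm = classifiers.ConfusionMatrix.from_predictions(yb[idx], pred, SHAPE_BAD)
        acc, rec = classifiers.metrics(cm)
        report[split_name] = {
            "n": int(idx.size),
            "accuracy": acc,
            "recall": rec,
            "confusion": cm.to_dict(),
        }
    cv = classifiers.monte_carlo_cv(
        features,
        labels,
        config.shape_model.train_fraction,
        n_iter=config.shape_model.cv_iterations,
        seed=s_cv,
        balance=config.shape_model.balance_mode,
        positive_label=SHAPE_BAD,
    )
    metadata = {
        "station": "shape",
        "k_truncation": int(k),
        "n_harmonics": int(n_h),
        "outline_points": int(config.imaging.outline_points),
        "efa_method": config.shape_model.efa_method,
        "mean_shape": aligned.mean_shape.tolist(),
        "cv_mean_train": cv.mean_train,
        "cv_mean_test": cv.mean_test,
    }
    return {
        "model": model,
        "standardizer": std,
        "metadata": metadata,
        "report": report,
        "cv": cv,
    }


def train_vital_model(dataset_dir, config: PipelineConfig, seed=None) -> dict:
    """Fit the alive/dead station from the photodiode CSV (80/20 split)."""
    base = Path(dataset_dir)
    manifest = pd.read_csv(base / "manifest.csv").set_index("id")
    if "true_vital_state" not in manifest.columns:
        raise ValidationError("manifest lacks true_vital_state labels")
    frames = sensor.read_sensor_csv(base / "sensor" / "sensor.csv")
    labels = np.array(
        [manifest.loc[f.cocoon_id, "true_vital_state"] for f in frames]
    )
    ss = np.random.SeedSequence(seed)
    s_fit, s_cv = ss.spawn(2)
    model, std, report = sensor.fit_alive_dead(
        frames,
        labels,
        seed=np.random.default_rng(s_fit),
        train_fraction=config.vital_model.train_fraction,
    )
    cv = classifiers.monte_carlo_cv(
        sensor.frames_to_matrix(frames),
        labels,
        config.vital_model.train_fraction,
        n_iter=config.vital_model.cv_iterations,
        seed=s_cv,
        balance="none",
        positive_label=sensor.DEAD,
    )
    metadata = {
        "station": "vital",
        "cv_mean_train": cv.mean_train,
        "cv_mean_test": cv.mean_test,
    }
    return {"model": model, "standardizer": std, "metadata": metadata, "report": report, "cv": cv}


def save_station_model(path, trained: dict) -> None:
    classifiers.save_model_bundle(
        path, trained["model"], trained["standardizer"], trained["metadata"]
    )


# ---------------------------------------------------------------------------
# Selection mode
# ---------------------------------------------------------------------------

def _shape_verdict(
    mask: np.ndarray,
    model: classifiers.LogisticModel,
    std: classifiers.Standardizer,
    meta: dict,
    config: PipelineConfig,
) -> tuple[str, float]:
    outline = morphometrics.digitize_outline(
        mask, n_points=int(meta.get("outline_points", config.imaging.outline_points))
    )
    aligned = morphometrics.align_to(outline, np.asarray(meta["mean_shape"]))
    desc = morphometrics.efa_decompose(
        aligned, int(meta["n_harmonics"]), method=meta.get("efa_method", "dft")
    )
    z = std.apply(desc.flat_coefficients(int(meta["k_truncation"])))
    prob = float(model.predict_proba(z)[0])
    label = SHAPE_BAD if prob >= model.decision_threshold else SHAPE_GOOD
    return label, prob


def run_select(
    dataset_dir,
    config: PipelineConfig,
    shape_model_path=None,
    vital_model_path=None,
) -> pd.DataFrame:
    """Run the sorting cascade over a staged dataset.

    Every enabled station is evaluated for every record (so reports cover
    all stations), but the route is assigned by the first failure in the
    physical order size -> shape -> stain -> vital.  Records with missing
    inputs are routed ``incomplete`` and excluded from metrics.
    """
    base = Path(dataset_dir)
    manifest = pd.read_csv(base / "manifest.csv")
    stations = config.stations

    shape_model = shape_std = shape_meta = None
    if stations.shape:
        if shape_model_path is None:
            raise ValidationError("shape station enabled but no model provided")
        shape_model, shape_std, shape_meta = classifiers.load_model_bundle(shape_model_path)
    vital_model = vital_std = None
    if stations.vital:
        if vital_model_path is None:
            raise ValidationError("vital station enabled but no model provided")
        vital_model, vital_std, _ = classifiers.load_model_bundle(vital_model_path)

    frames = {}
    if stations.vital:
        frames = {
            f.cocoon_id: f for f in sensor.read_sensor_csv(base / "sensor" / "sensor.csv")
        }

    decisions = []
    for rec in manifest.to_dict("records"):
        cid = int(rec["id"])
        row: dict = {"id": cid}
        try:
            shape_mask = None
            if stations.size or stations.shape:
                shape_mask = segment_cocoon(
                    read_image(base / str(rec["shape_image"])), config
                )
            if stations.size:
                area, verdict = imaging.measure_and_gate_size(shape_mask, config.size)
                row["area_px2"] = area
                row["size_verdict"] = verdict
            if stations.shape:
                label, prob = _shape_verdict(
                    shape_mask, shape_model, shape_std, shape_meta, config
                )
                row["shape_verdict"] = label
                row["shape_prob_bad"] = round(prob, 6)
            if stations.stain:
                per_view = {}
                for view, profile in (
                    ("top", config.stain.top),
                    ("bottom", config.stain.bottom),
                ):
                    rgb = read_image(base / str(rec[f"{view}_image"]))
                    hsb = imaging.rgb_to_hsb(rgb)
                    roi = (
                        segment_cocoon(rgb, config)
                        if config.stain.restrict_to_cocoon
                        else None
                    )
                    flagged = stains.stain_filter(hsb, profile, roi=roi)
                    per_view[view] = stains.stain_verdict(flagged, profile, cocoon_id=cid)
                    row[f"stain_{view}"] = per_view[view].stained
                row["stained"] = stains.combine_views(per_view["top"], per_view["bottom"])
            if stations.vital:
                if cid not in frames:
                    raise ValidationError(f"no sensor frame for cocoon {cid}")
                z = vital_std.apply(sensor.frame_to_features(frames[cid]))
                prob = float(vital_model.predict_proba(z)[0])
                row["vital_prob_dead"] = round(prob, 6)
                row["vital_verdict"] = (
                    sensor.DEAD if prob >= vital_model.decision_threshold else sensor.ALIVE
                )
        except (CocoonSortError, FileNotFoundError) as exc:
            logger.info("cocoon %d incomplete: %s", cid, exc)
            row["route"] = "incomplete"
            decisions.append(row)
            continue

        failed = {
            "size": stations.size and row.get("size_verdict") != "ok",
            "shape": stations.shape and row.get("shape_verdict") == SHAPE_BAD,
            "stain": stations.stain and bool(row.get("stained")),
            "vital": stations.vital and row.get("vital_verdict") == sensor.DEAD,
        }
        row["route"] = next(
            (ROUTE_LABELS[s] for s in ROUTE_ORDER if failed[s]), PASS_ROUTE
        )
        logger.info("cocoon %d -> %s", cid, row["route"])
        decisions.append(row)
    return pd.DataFrame.from_records(decisions)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

#: station -> (truth extractor, prediction extractor); positives are defects.
_STATION_RULES = {
    "size": (
        lambda m: m["true_size_class"] != "ok",
        lambda d: d["size_verdict"] != "ok",
        "size_verdict",
        "true_size_class",
    ),
    "shape": (
        lambda m: m["true_shape_class"] == SHAPE_BAD,
        lambda d: d["shape_verdict"] == SHAPE_BAD,
        "shape_verdict",
        "true_shape_class",
    ),
    "stain": (
        lambda m: m["true_stain"].astype(bool),
        lambda d: d["stained"].astype(bool),
        "stained",
        "true_stain",
    ),
    "vital": (
        lambda m: m["true_vital_state"] == sensor.DEAD,
        lambda d: d["vital_verdict"] == sensor.DEAD,
        "vital_verdict",
        "true_vital_state",
    ),
}


def evaluate(decisions: pd.DataFrame, manifest: pd.DataFrame) -> dict:
    """Join decisions to ground truth on id and score each station.

    Reports tp/tn/fp/fn, overall accuracy as a one-decimal percent, and
    recall (two decimals) per station.  Records routed ``incomplete`` are
    dropped; ids in the decisions without ground truth raise a join error.
    """
    if "route" in decisions.columns:
        decisions = decisions[decisions["route"] != "incomplete"]
    missing = set(decisions["id"]) - set(manifest["id"])
    if missing:
        raise ValidationError(f"ids without ground truth: {sorted(missing)}")
    merged = decisions.merge(manifest, on="id", how="inner", validate="one_to_one")
    if merged.empty:
        raise ValidationError("decisions and manifest share no ids")

    report: dict = {"n_records": int(len(merged)), "stations": {}}
    for station, (truth_fn, pred_fn, pred_col, truth_col) in _STATION_RULES.items():
        if pred_col not in merged.columns or truth_col not in merged.columns:
            continue
        y_true = truth_fn(merged).to_numpy()
        y_pred = pred_fn(merged).to_numpy()
        cm = classifiers.ConfusionMatrix.from_predictions(y_true, y_pred, True)
        entry: dict = {"confusion": cm.to_dict()}
        if cm.tp + cm.fn > 0:
            acc, rec = classifiers.metrics(cm)
            entry["accuracy"] = acc
            entry["accuracy_pct"] = classifiers.format_percent(acc)
            entry["recall"] = rec
            entry["recall_2dp"] = f"{classifiers.round_half_up(rec, 2):.2f}"
        report["stations"][station] = entry
    return report


def save_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
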