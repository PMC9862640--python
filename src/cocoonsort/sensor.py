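"""Photodiode-matrix data model and alive/dead pupa classification.

The dead-cocoon station shines an LED panel through each cocoon onto a 7 x 5
photodiode matrix read through a single 10-bit ADC (counts 0-1023), scanning
row first, then column.  Each cocoon yields one 35-element transmission
vector; the vectors are Z-scored and classified alive vs dead by logistic
regression with an 80/20 train/test split and 100-iteration Monte Carlo
cross-validation.  "Alignment" of the 35 signals is the fixed row-major
positional ordering - one static frame per cocoon, so there is nothing
temporal to register.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from . import classifiers
from .errors import SensorFormatError, SensorRangeError, ValidationError

N_ROWS, N_COLS = 7, 5
N_CHANNELS = N_ROWS * N_COLS
ADC_MAX = 1023  # 10-bit ADC: 1024 steps, 0..1023

#: CSV header: timestamp, progressive id, then p{row}{col} row-major.
CSV_HEADER = ["timestamp", "id"] + [
    f"p{r}{c}" for r in range(N_ROWS) for c in range(N_COLS)
]

ALIVE, DEAD = "alive", "dead"


@dataclass(frozen=True)
class SensorFrame:
    """One 7 x 5 ADC readout for one cocoon."""

    values: np.ndarray  # (7, 5) int
    timestamp: str
    cocoon_id: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != (N_ROWS, N_COLS):
            raise ValidationError(f"sensor frame must be {N_ROWS} x {N_COLS}, got {vals.shape}")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(vals == np.rint(vals)):
                raise ValidationError("ADC counts must be integers")
            vals = vals.astype(np.int64)
        if vals.min() < 0 or vals.max() > ADC_MAX:
            raise SensorRangeError(
                f"cocoon {self.cocoon_id}: ADC count outside [0, {ADC_MAX}]"
            )
        object.__setattr__(self, "values", vals.astype(np.int64))


def frame_to_features(frame: SensorFrame) -> np.ndarray:
    """Flatten a frame row-major: channel index = 5 * row + col."""
    return frame.values.reshape(N_CHANNELS).astype(np.float64)


def features_to_frame(
    vector: np.ndarray, timestamp: str = "", cocoon_id: int = 0
) -> SensorFrame:
    """Inverse of :func:`frame_to_features`."""
    vec = np.asarray(vector)
    if vec.shape != (N_CHANNELS,):
        raise ValidationError(f"feature vector must have length {N_CHANNELS}")
    return SensorFrame(
        values=vec.reshape(N_ROWS, N_COLS), timestamp=timestamp, cocoon_id=cocoon_id
    )


def frames_to_matrix(frames) -> np.ndarray:
    return np.stack([frame_to_features(f) for f in frames])


def read_sensor_csv(path) -> list[SensorFrame]:
    """Parse and validate a photodiode CSV; frames ordered by progressive id."""
    frames: list[SensorFrame] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != CSV_HEADER:
            raise SensorFormatError(f"{path}: bad header, expected {','.join(CSV_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CSV_HEADER):
                raise SensorFormatError(
                    f"{path}:{lineno}: expected {len(CSV_HEADER)} columns, got {len(row)}"
                )
            timestamp = row[0]
            try:
                cid = int(row[1])
                counts = np.array([int(v) for v in row[2:]], dtype=np.int64)
            except ValueError as exc:
                raise SensorFormatError(f"{path}:{lineno}: non-integer value") from exc
            if counts.min() < 0 or counts.max() > ADC_MAX:
                raise SensorRangeError(
                    f"{path}:{lineno}: ADC count outside [0, {ADC_MAX}]"
                )
            frames.append(
                SensorFrame(
                    values=counts.reshape(N_ROWS, N_COLS),
                    timestamp=timestamp,
                    cocoon_id=cid,
                )
            )
    frames.sort(key=lambda f: f.cocoon_id)
    return frames


def write_sensor_csv(path, frames) -> None:
    """Write frames in the canonical CSV dialect (bit-exact round trip)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for f in frames:
            writer.writerow(
                [f.timestamp, f.cocoon_id] + [int(v) for v in f.values.reshape(-1)]
            )


def fit_alive_dead(
    frames,
    labels,
    seed=None,
    train_fraction: float = 0.8,
) -> tuple[classifiers.LogisticModel, classifiers.Standardizer, dict]:
    """Train the alive/dead logistic model on sensor frames.

    Dead is the positive class (the station exists to discard dead cocoons).
    Returns the fitted model, its Z-score standardizer, and a report with the
    stratified 80/20 split sizes and train/test accuracy and recall.
    """
    x = frames_to_matrix(frames)
    y = np.asarray(labels)
    if x.shape[0] != y.shape[0]:
        raise ValidationError("frames and labels differ in length")
    rng = np.random.default_rng(seed)
    tr, te = classifiers.stratified_split(y, train_fraction, rng)
    std = classifiers.Standardizer.fit(x[tr], on_constant="drop")
    schema = [CSV_HEADER[2 + c] for c in std.kept_columns]
    model = classifiers.fit_logistic(
        std.apply(x[tr]), y[tr], positive_label=DEAD, feature_schema=schema
    )
    report = {}
    for split_name, idx in (("train", tr), ("test", te)):
        pred = model.predict(std.apply(x[idx]))
        cm = classifiers.ConfusionMatrix.from_predictions(y[idx], pred, DEAD)
        acc, rec = classifiers.metrics(cm)
        report[split_name] = {
            "n": int(idx.size),
            "accuracy": acc,
            "recall": rec,
            "confusion": cm.to_dict(),
        }
    return model, std, report
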