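"""Shared statistical layer: Z-score standardization, class balancing,
stratified splitting, logistic regression, Monte Carlo cross-validation, and
the accuracy/recall metrics used to report every station.

Both image-derived shape features and the 35-channel photodiode signals go
through the same path: standardize each feature to zero mean and unit
standard deviation on the training set, fit an unpenalized
maximum-likelihood logistic regression, and threshold the predicted
probability at 0.5.  Accuracy A = (Tp+Tn)/(Tp+Tn+Fp+Fn) and recall
R = Tp/(Tp+Fn) summarize each station, with defective cocoons as the
positive class.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .errors import StandardizationError, ValidationError

SEPARATION_RIDGE = 1e-8  # fallback L2 penalty when the MLE diverges


# ---------------------------------------------------------------------------
# Z-score standardization
# ---------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Per-feature Z-score transform (X - m) / s.

    The population standard deviation (ddof=0) is used by default;
    ``ddof=1`` is available for sample-style scaling.  Constant columns
    either raise (default) or are dropped with their indices recorded in
    ``kept_columns``.
    """

    means: np.ndarray
    sds: np.ndarray
    kept_columns: np.ndarray  # indices into the raw feature matrix

    @classmethod
    def fit(
        cls,
        features: np.ndarray,
        ddof: int = 0,
        on_constant: str = "error",
        feature_names: Sequence[str] | None = None,
    ) -> "Standardizer":
        x = np.asarray(features, dtype=np.float64)
        if x.ndim != 2 or x.shape[0] < 2:
            raise ValidationError("standardizer needs a 2-D matrix with >= 2 rows")
        means = x.mean(axis=0)
        sds = x.std(axis=0, ddof=ddof)
        constant = sds <= 0
        if constant.any():
            cols = np.flatnonzero(constant)
            names = (
                [feature_names[c] for c in cols]
                if feature_names is not None
                else cols.tolist()
            )
            if on_constant == "drop":
                keep = np.flatnonzero(~constant)
                return cls(means=means[keep], sds=sds[keep], kept_columns=keep)
            raise StandardizationError(f"constant feature column(s): {names}")
        return cls(means=means, sds=sds, kept_columns=np.arange(x.shape[1]))

    def apply(self, features: np.ndarray) -> np.ndarray:
        x = np.asarray(features, dtype=np.float64)
        squeeze = x.ndim == 1
        if squeeze:
            x = x[None, :]
        x = x[:, self.kept_columns]
        z = (x - self.means) / self.sds
        return z[0] if squeeze else z

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "kept_columns": self.kept_columns.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(
            means=np.asarray(d["means"], dtype=np.float64),
            sds=np.asarray(d["sds"], dtype=np.float64),
            kept_columns=np.asarray(d["kept_columns"], dtype=np.int64),
        )


# ---------------------------------------------------------------------------
# Balancing and splitting
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def balance_binary(
    features: np.ndarray, labels: np.ndarray, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly undersample the majority class to the minority size.

    Returns a shuffled copy of size 2 x minority count.  With the real
    shape data (773 well-shaped vs 178 bad-shaped) this yields the 356-sample
    balanced design.
    """
    x = np.asarray(features)
    y = np.asarray(labels)
    if x.shape[0] != y.shape[0]:
        raise ValidationError("features and labels differ in length")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValidationError(f"expected exactly two classes, got {classes.tolist()}")
    if counts.min() == 0:
        raise ValidationError("a class has zero samples")
    rng = _rng(seed)
    n_min = int(counts.min())
    keep: list[np.ndarray] = []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        if idx.size > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    sel = np.concatenate(keep)
    sel = sel[rng.permutation(sel.size)]
    return x[sel], y[sel]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(
    labels: np.ndarray, train_fraction: float, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random train/test partition; returns index arrays.

    The overall training size is the round-half-up of n * train_fraction
    (356 at 70% -> 249 train / 107 test; 366 at 80% -> 293 / 73) and is
    apportioned across classes by largest remainder, ties to the
    first-sorted class.
    """
    y = np.asarray(labels)
    n = y.shape[0]
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must be in (0, 1)")
    n_train = _round_half_up(n * train_fraction)
    if n_train == 0 or n_train == n:
        raise ValidationError("train_fraction produces an empty partition")
    classes = np.unique(y)
    ideal = {c: np.sum(y == c) * train_fraction for c in classes}
    base = {c: int(math.floor(ideal[c])) for c in classes}
    short = n_train - sum(base.values())
    order = sorted(classes, key=lambda c: (-(ideal[c] - base[c]), np.argmax(classes == c)))
    for c in order[:short]:
        base[c] += 1
    rng = _rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        perm = rng.permutation(idx.size)
        take = base[c]
        if take == 0 or take == idx.size:
            raise ValidationError(
                f"class {c!r} would have an empty train or test partition"
            )
        train_idx.append(idx[perm[:take]])
        test_idx.append(idx[perm[take:]])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticModel:
    """Logistic decision rule over standardized features.

    ``predict_proba`` returns P(positive); a sample is labeled positive when
    the probability is >= ``decision_threshold`` (ties at exactly 0.5 go to
    the positive class).
    """

    weights: np.ndarray
    intercept: float
    positive_label: object
    negative_label: object
    decision_threshold: float = 0.5
    feature_schema: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValidationError("decision_threshold must be in (0, 1)")
        if self.feature_schema and len(self.feature_schema) != self.weights.size:
            raise ValidationError("feature_schema length must match weights")

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, dtype=np.float64))
        z = x @ self.weights + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, features: np.ndarray) -> np.ndarray:
        p = self.predict_proba(features)
        return np.where(
            p >= self.decision_threshold, self.positive_label, self.negative_label
        )

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "positive_label": self.positive_label,
            "negative_label": self.negative_label,
            "decision_threshold": self.decision_threshold,
            "feature_schema": list(self.feature_schema),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticModel":
        return cls(
            weights=np.asarray(d["weights"], dtype=np.float64),
            intercept=float(d["intercept"]),
            positive_label=d["positive_label"],
            negative_label=d["negative_label"],
            decision_threshold=float(d.get("decision_threshold", 0.5)),
            feature_schema=list(d.get("feature_schema", [])),
        )


def fit_logistic(
    train: np.ndarray,
    labels: np.ndarray,
    positive_label=None,
    feature_schema: Sequence[str] | None = None,
    max_iter: int = 2000,
) -> LogisticModel:
    """Unpenalized maximum-likelihood logistic fit on standardized features.

    If the likelihood diverges (perfectly separable data), the fit falls back
    to a vanishingly small ridge penalty and emits a warning; predictions are
    unaffected in practice.
    """
    x = np.asarray(train, dtype=np.float64)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValidationError(f"logistic fit needs two classes, got {classes.tolist()}")
    if positive_label is None:
        positive_label = classes[1]
    elif positive_label not in classes:
        raise ValidationError(f"positive_label {positive_label!r} not present")
    negative_label = classes[classes != positive_label][0]
    y_bin = (y == positive_label).astype(int)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=max_iter)
        clf.fit(x, y_bin)
        diverged = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if diverged:
        warnings.warn(
            "unpenalized logistic fit did not converge (likely perfect "
            f"separation); refitting with ridge penalty {SEPARATION_RIDGE:g}",
            RuntimeWarning,
            stacklevel=2,
        )
        clf = LogisticRegression(
            penalty="l2", C=1.0 / SEPARATION_RIDGE, solver="lbfgs", max_iter=max_iter
        )
        clf.fit(x, y_bin)
    return LogisticModel(
        weights=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        positive_label=positive_label,
        negative_label=negative_label,
        feature_schema=list(feature_schema or []),
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive_label) -> "ConfusionMatrix":
        yt = np.asarray(y_true)
        yp = np.asarray(y_pred)
        if yt.shape != yp.shape:
            raise ValidationError("y_true and y_pred differ in shape")
        pos_t = yt == positive_label
        pos_p = yp == positive_label
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
        )

    def to_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn}


def metrics(cm: ConfusionMatrix) -> tuple[float, float]:
    """Overall accuracy A = (Tp+Tn)/total and recall R = Tp/(Tp+Fn)."""
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    if cm.tp + cm.fn == 0:
        raise ValidationError("recall undefined: no positive cases")
    accuracy = (cm.tp + cm.tn) / cm.total
    recall = cm.tp / (cm.tp + cm.fn)
    return accuracy, recall


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero, as used in the reports."""
    factor = 10.0**decimals
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


def format_percent(fraction: float, decimals: int = 1) -> str:
    """Format a fraction as a percentage string, round-half-up."""
    return f"{round_half_up(fraction * 100.0, decimals):.{decimals}f}"


# ---------------------------------------------------------------------------
# Monte Carlo cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVReport:
    n_iterations: int
    train_accuracies: np.ndarray
    test_accuracies: np.ndarray

    @property
    def mean_train(self) -> float:
        return float(np.mean(self.train_accuracies))

    @property
    def mean_test(self) -> float:
        return float(np.mean(self.test_accuracies))


def monte_carlo_cv(
    features: np.ndarray,
    labels: np.ndarray,
    train_fraction: float,
    n_iter: int = 100,
    seed=None,
    balance: str = "once",
    positive_label=None,
) -> CVReport:
    """Repeated balance/split/standardize/fit/evaluate cycles.

    ``balance="once"`` undersamples to a balanced set a single time and then
    re-splits it every iteration; ``"per_iteration"`` redraws the balanced
    subset each time (honest about undersampling variance); ``"none"`` skips
    balancing.  Per-iteration seeds are spawned deterministically from the
    master seed.
    """
    if balance not in ("once", "per_iteration", "none"):
        raise ValidationError(f"unknown balance mode {balance!r}")
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    ss = _seed_sequence(seed)
    children = ss.spawn(n_iter + 1)
    if balance == "once":
        x, y = balance_binary(x, y, np.random.default_rng(children[0]))

    train_acc = np.empty(n_iter)
    test_acc = np.empty(n_iter)
    for i in range(n_iter):
        rng = np.random.default_rng(children[i + 1])
        xi, yi = (balance_binary(x, y, rng) if balance == "per_iteration" else (x, y))
        tr, te = stratified_split(yi, train_fraction, rng)
        std = Standardizer.fit(xi[tr], on_constant="drop")
        model = fit_logistic(std.apply(xi[tr]), yi[tr], positive_label=positive_label)
        train_acc[i] = np.mean(model.predict(std.apply(xi[tr])) == yi[tr])
        test_acc[i] = np.mean(model.predict(std.apply(xi[te])) == yi[te])
    return CVReport(
        n_iterations=n_iter, train_accuracies=train_acc, test_accuracies=test_acc
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

MODEL_SCHEMA_VERSION = 1


def save_model_bundle(
    path, model: LogisticModel, standardizer: Standardizer, metadata: dict | None = None
) -> None:
    """Write a versioned JSON bundle: schema, Z-score parameters, weights."""
    payload = {
        "version": MODEL_SCHEMA_VERSION,
        "model": model.to_dict(),
        "standardizer": standardizer.to_dict(),
        "metadata": metadata or {},
    }

    def _jsonable(obj):
        if isinstance(obj, np.generic):
            return obj.item()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)


def load_model_bundle(path) -> tuple[LogisticModel, Standardizer, dict]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("version") != MODEL_SCHEMA_VERSION:
        raise ValidationError(f"unsupported model schema version {payload.get('version')}")
    return (
        LogisticModel.from_dict(payload["model"]),
        Standardizer.from_dict(payload["standardizer"]),
        payload.get("metadata", {}),
    )
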