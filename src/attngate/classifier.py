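"""Person-dependent two-class linear discriminant attention classifier.

The model is the classical LDA with Gaussian classes sharing a pooled
within-class covariance and empirical class priors — i.e. the standard
scikit-learn ``LinearDiscriminantAnalysis`` defaults, which this module
wraps for training while exposing the fitted discriminant explicitly
(weights, bias, class means, pooled covariance, priors) so the decision
rule is transparent and serialisable.

Decision convention: the discriminant score is positive for *internal*
attention; a score of exactly zero predicts *external*, consistent with
the downstream bias against pausing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .bands import FEATURE_COLUMNS
from .frames import FrameStream
from .plans import EXTERNAL, INTERNAL

__all__ = ["AttentionModel", "CalibrationResult", "train", "cross_validate"]

FORMAT_VERSION = 1


@dataclass
class AttentionModel:
    """Fitted two-class linear discriminant (internal vs external attention)."""

    weights: np.ndarray  # (d,)
    bias: float
    class_means: np.ndarray  # (2, d): [external, internal]
    covariance: np.ndarray  # (d, d) pooled within-class
    priors: np.ndarray  # (2,): [external, internal]
    feature_order: tuple[str, ...] = FEATURE_COLUMNS
    calibration: "CalibrationResult | None" = None

    def score(self, x: np.ndarray) -> np.ndarray:
        """Affine discriminant value(s); positive favours internal."""
        x = np.asarray(x, float)
        return x @ self.weights + self.bias

    def predict(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predict labels and scores for one vector or a batch.

        internal iff score > 0; a boundary score of exactly 0 goes to
        external (tie-break toward the non-pausing state).
        """
        x = np.atleast_2d(np.asarray(x, float))
        if x.shape[1] != len(self.weights):
            raise ValueError(
                f"feature dimension {x.shape[1]} != model dimension {len(self.weights)}"
            )
        s = self.score(x)
        labels = np.where(s > 0, INTERNAL, EXTERNAL).astype("<U8")
        return labels, s

    def predict_stream(self, stream: FrameStream) -> np.ndarray:
        if tuple(self.feature_order) != FEATURE_COLUMNS:
            raise ValueError("model feature order does not match the frame layout")
        labels, _ = self.predict(stream.features)
        return labels

    def to_dict(self) -> dict:
        d = {
            "format_version": FORMAT_VERSION,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "class_means": self.class_means.tolist(),
            "covariance": self.covariance.tolist(),
            "priors": self.priors.tolist(),
            "feature_order": list(self.feature_order),
        }
        if self.calibration is not None:
            d["calibration"] = self.calibration.to_dict()
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "AttentionModel":
        if d.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {d.get('format_version')}")
        cal = d.get("calibration")
        return cls(
            weights=np.asarray(d["weights"], float),
            bias=float(d["bias"]),
            class_means=np.asarray(d["class_means"], float),
            covariance=np.asarray(d["covariance"], float),
            priors=np.asarray(d["priors"], float),
            feature_order=tuple(d["feature_order"]),
            calibration=CalibrationResult.from_dict(cal) if cal else None,
        )

    @classmethod
    def load(cls, path: str | Path) -> "AttentionModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CalibrationResult:
    """K-fold cross-validated calibration accuracy of a training session."""

    fold_accuracies: tuple[float, ...]
    scheme: str
    n_vectors: int
    class_balance: float  # fraction internal

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": list(self.fold_accuracies),
            "mean_accuracy": self.mean_accuracy,
            "scheme": self.scheme,
            "n_vectors": self.n_vectors,
            "class_balance": self.class_balance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        return cls(
            fold_accuracies=tuple(d["fold_accuracies"]),
            scheme=d["scheme"],
            n_vectors=int(d["n_vectors"]),
            class_balance=float(d["class_balance"]),
        )


def _as_xy(
    features: FrameStream | np.ndarray, labels: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(features, FrameStream):
        return features.features, features.labels
    if labels is None:
        raise ValueError("labels required when passing a plain feature matrix")
    return np.asarray(features, float), np.asarray(labels, dtype="<U8")


def train(
    features: FrameStream | np.ndarray,
    labels: np.ndarray | None = None,
    feature_order: tuple[str, ...] | None = None,
) -> AttentionModel:
    """Fit the linear discriminant on a labelled feature table.

    Zero-variance features are dropped (with a warning) before fitting and
    their weights restored as zeros, so degenerate fixtures cannot make the
    pooled covariance singular; a still-singular covariance falls back to
    the SVD pseudo-inverse solution with a warning.
    """
    x, y = _as_xy(features, labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"training data contains a single class: {classes}")
    if set(classes) - {INTERNAL, EXTERNAL}:
        raise ValueError(f"unexpected labels: {set(classes) - {INTERNAL, EXTERNAL}}")
    for c in (EXTERNAL, INTERNAL):
        if (y == c).sum() < 2:
            raise ValueError(f"need at least 2 samples of class {c!r}")
    n, d = x.shape
    if n <= d:
        warnings.warn(f"only {n} samples for {d} features; estimates will be unstable")

    keep = x.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature(s) before fitting")
    xk = x[:, keep]

    lda = LinearDiscriminantAnalysis(solver="svd", store_covariance=True)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Variables are collinear")
        lda.fit(xk, y)
    # sklearn orders classes lexicographically: ['external', 'internal'];
    # its decision_function is positive for the second class (internal).
    assert list(lda.classes_) == [EXTERNAL, INTERNAL]

    weights = np.zeros(d)
    weights[keep] = lda.coef_[0]
    means = np.zeros((2, d))
    means[:, keep] = lda.means_
    cov = np.zeros((d, d))
    cov[np.ix_(keep, keep)] = lda.covariance_

    if feature_order is None:
        feature_order = (
            FEATURE_COLUMNS if d == len(FEATURE_COLUMNS) else tuple(f"f{i}" for i in range(d))
        )
    return AttentionModel(
        weights=weights,
        bias=float(lda.intercept_[0]),
        class_means=means,
        covariance=cov,
        priors=np.asarray(lda.priors_, float),
        feature_order=tuple(feature_order),
    )


def _fold_indices(n: int, k: int, scheme: str, seed: int) -> list[np.ndarray]:
    idx = np.arange(n)
    if scheme == "shuffled":
        rng = np.random.default_rng(seed)
        idx = rng.permutation(n)
    elif scheme != "contiguous":
        raise ValueError(f"unknown CV scheme {scheme!r}")
    return [np.sort(part) for part in np.array_split(idx, k)]


def cross_validate(
    features: FrameStream | np.ndarray,
    labels: np.ndarray | None = None,
    k: int = 5,
    scheme: str = "shuffled",
    seed: int = 0,
) -> CalibrationResult:
    """K-fold cross-validated calibration accuracy (default 5 folds).

    ``scheme="shuffled"`` mirrors the usual toolkit default; because
    neighbouring feature windows overlap by 90%, shuffled folds leak
    temporal information and over-estimate online accuracy — the
    ``"contiguous"`` (block) scheme is the leakage-safe alternative.
    Deterministic given ``seed``.
    """
    x, y = _as_xy(features, labels)
    n = len(y)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    folds = _fold_indices(n, k, scheme, seed)
    accs = []
    for test_idx in folds:
        train_mask = np.ones(n, bool)
        train_mask[test_idx] = False
        ytr = y[train_mask]
        if len(np.unique(ytr)) < 2:
            raise ValueError("a training fold contains a single class; use more data")
        model = train(x[train_mask], ytr)
        pred, _ = model.predict(x[test_idx])
        accs.append(float(np.mean(pred == y[test_idx])))
    return CalibrationResult(
        fold_accuracies=tuple(accs),
        scheme=scheme,
        n_vectors=n,
        class_balance=float(np.mean(y == INTERNAL)),
    )
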