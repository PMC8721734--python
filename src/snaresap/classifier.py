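"""Soft-margin kernel SVM: configuration, training, prediction, persistence.

The quadratic program is solved by scikit-learn's libsvm backend; this
module owns the kernel definitions, the decision contract and model
persistence. The decision value for a sample x is

    f(x) = sum_i alpha_i y_i K(x_i, x) + b

over the support vectors, and predictions are sign(f) with ties (f = 0)
resolved to +1 (SNARE). The stored model recomputes f with this module's
own kernel code, so a saved model does not depend on the solver.

Defaults follow the tuned pipeline: RBF kernel, C = 11, gamma = 0.1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .encoding import FeatureMatrix, NormalizationParams, apply_scaler

_KERNELS = ("linear", "polynomial", "rbf", "sigmoid")

#: Persistence format version; bumped on incompatible changes.
MODEL_FORMAT = "snare-sap-model"
MODEL_VERSION = 1


class ModelFormatError(ValueError):
    """A model file is corrupted or from an incompatible version."""


@dataclass
class SVMConfig:
    """Kernel SVM hyper-parameters.

    kernel: one of linear, polynomial, rbf, sigmoid.
    C: soft-margin penalty (> 0).
    gamma: kernel coefficient; required > 0 for polynomial/rbf/sigmoid.
        Always explicit — the LIBSVM convention of defaulting gamma to
        1/n_classes is documented but not used, since the tuned model
        fixes gamma = 0.1.
    coef0: additive constant of the polynomial and sigmoid kernels.
    degree: polynomial degree (>= 1).
    """

    kernel: str = "rbf"
    C: float = 11.0
    gamma: float = 0.1
    coef0: float = 0.0
    degree: int = 3
    class_weight: str | None = None

    def __post_init__(self):
        if self.kernel not in _KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}; expected one of {_KERNELS}")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.kernel != "linear" and self.gamma <= 0:
            raise ValueError(f"{self.kernel} kernel requires gamma > 0")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")

    def to_dict(self) -> dict:
        return {
            "kernel": self.kernel,
            "C": self.C,
            "gamma": self.gamma,
            "coef0": self.coef0,
            "degree": self.degree,
            "class_weight": self.class_weight,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVMConfig":
        return cls(**d)


def kernel_eval(cfg: SVMConfig, x_i, x_j) -> float:
    """Evaluate the configured kernel for a single pair of vectors.

    linear:      x_i . x_j
    polynomial:  (gamma * x_i . x_j + coef0) ** degree
    rbf:         exp(-gamma * ||x_i - x_j||^2)
    sigmoid:     tanh(gamma * x_i . x_j + coef0)
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ValueError(f"dimension mismatch: {x_i.shape} vs {x_j.shape}")
    if cfg.kernel == "linear":
        return float(x_i @ x_j)
    if cfg.kernel == "polynomial":
        return float((cfg.gamma * (x_i @ x_j) + cfg.coef0) ** cfg.degree)
    if cfg.kernel == "rbf":
        d = x_i - x_j
        return float(np.exp(-cfg.gamma * (d @ d)))
    if cfg.kernel == "sigmoid":
        return float(np.tanh(cfg.gamma * (x_i @ x_j) + cfg.coef0))
    raise ValueError(cfg.kernel)  # pragma: no cover


def kernel_matrix(cfg: SVMConfig, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise kernel values K[i, j] = K(A[i], B[j])."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    if cfg.kernel == "linear":
        return A @ B.T
    if cfg.kernel == "polynomial":
        return (cfg.gamma * (A @ B.T) + cfg.coef0) ** cfg.degree
    if cfg.kernel == "rbf":
        sq = (
            (A**2).sum(axis=1)[:, None]
            + (B**2).sum(axis=1)[None, :]
            - 2.0 * (A @ B.T)
        )
        return np.exp(-cfg.gamma * np.maximum(sq, 0.0))
    if cfg.kernel == "sigmoid":
        return np.tanh(cfg.gamma * (A @ B.T) + cfg.coef0)
    raise ValueError(cfg.kernel)  # pragma: no cover


@dataclass
class TrainedModel:
    """A fitted SVM plus everything needed to apply it to raw features.

    Carries the normalization parameters and the selected original
    feature ids it was trained with, so prediction from an unscaled
    full-width feature matrix reproduces the training-time transform.
    """

    config: SVMConfig
    support_vectors: np.ndarray
    dual_coefs: np.ndarray  # alpha_i * y_i per support vector
    bias: float
    selected_features: np.ndarray
    scaler: NormalizationParams = field(
        default_factory=lambda: NormalizationParams(method="none")
    )
    scaler_feature_ids: np.ndarray | None = None

    def __post_init__(self):
        self.support_vectors = np.asarray(self.support_vectors, dtype=float)
        self.dual_coefs = np.asarray(self.dual_coefs, dtype=float)
        self.selected_features = np.asarray(self.selected_features, dtype=int)
        if self.scaler_feature_ids is not None:
            self.scaler_feature_ids = np.asarray(self.scaler_feature_ids, dtype=int)


_SKLEARN_KERNEL = {"polynomial": "poly"}


def train(
    M: FeatureMatrix,
    cfg: SVMConfig | None = None,
    scaler: NormalizationParams | None = None,
    scaler_feature_ids=None,
) -> TrainedModel:
    """Fit the kernel SVM on an (already scaled, already selected) matrix.

    ``scaler``/``scaler_feature_ids`` record the preprocessing the matrix
    went through so the model can be applied to raw features later; they
    are stored, not applied here.
    """
    cfg = cfg or SVMConfig()
    if M.y is None or len(np.unique(M.y)) < 2:
        raise ValueError("training requires both classes")
    if not np.all(np.isfinite(M.X)):
        raise ValueError("training matrix contains non-finite values")
    svc = SVC(
        C=cfg.C,
        kernel=_SKLEARN_KERNEL.get(cfg.kernel, cfg.kernel),
        gamma=cfg.gamma,
        coef0=cfg.coef0,
        degree=cfg.degree,
        class_weight=cfg.class_weight,
    )
    svc.fit(M.X, M.y)
    return TrainedModel(
        config=cfg,
        support_vectors=svc.support_vectors_.copy(),
        dual_coefs=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        selected_features=M.feature_ids.copy(),
        scaler=scaler or NormalizationParams(method="none"),
        scaler_feature_ids=scaler_feature_ids,
    )


def decision_function(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """f(x) = sum_i alpha_i y_i K(x_i, x) + b via this module's kernels."""
    K = kernel_matrix(model.config, np.atleast_2d(X), model.support_vectors)
    return K @ model.dual_coefs + model.bias


def predict(model: TrainedModel, data) -> tuple[np.ndarray, np.ndarray]:
    """Predict ±1 labels and decision scores.

    ``data`` may be a :class:`FeatureMatrix` in the model's *raw* feature
    space (the stored scaler is applied, then the model's selected
    features are extracted — missing ids raise an error naming them), or
    a bare array already matching the model's selected features. Ties
    (score exactly 0) go to +1. Scores are suitable for ROC analysis.
    """
    if isinstance(data, FeatureMatrix):
        if model.scaler.method != "none" and model.scaler_feature_ids is not None:
            aligned = data.select_ids(model.scaler_feature_ids)
            scaled = apply_scaler(aligned, model.scaler)
            sub = scaled.select_ids(model.selected_features)
        else:
            sub = data.select_ids(model.selected_features)
        X = sub.X
    else:
        X = np.atleast_2d(np.asarray(data, dtype=float))
        if X.shape[1] != model.support_vectors.shape[1]:
            raise ValueError(
                f"feature mismatch: got {X.shape[1]} columns, model expects "
                f"{model.support_vectors.shape[1]} "
                f"(ids {model.selected_features.tolist()[:8]}...)"
            )
    scores = decision_function(model, X)
    labels = np.where(scores >= 0, 1, -1)
    return labels, scores


def save_model(model: TrainedModel, path) -> None:
    """Serialize a model losslessly to JSON."""
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "config": model.config.to_dict(),
        "support_vectors": model.support_vectors.tolist(),
        "dual_coefs": model.dual_coefs.tolist(),
        "bias": model.bias,
        "selected_features": model.selected_features.tolist(),
        "scaler": model.scaler.to_dict(),
        "scaler_feature_ids": (
            None
            if model.scaler_feature_ids is None
            else model.scaler_feature_ids.tolist()
        ),
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> TrainedModel:
    """Load a model saved by :func:`save_model`.

    Corrupted files and version mismatches raise :class:`ModelFormatError`.
    A model saved without scaling loads with the identity scaler.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as e:
        raise ModelFormatError(f"{path}: not a valid model file ({e})") from None
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
        raise ModelFormatError(f"{path}: not a {MODEL_FORMAT} file")
    if doc.get("version") != MODEL_VERSION:
        raise ModelFormatError(
            f"{path}: model version {doc.get('version')} is not supported "
            f"(expected {MODEL_VERSION})"
        )
    scaler_doc = doc.get("scaler")
    scaler = (
        NormalizationParams(method="none")
        if scaler_doc is None
        else NormalizationParams.from_dict(scaler_doc)
    )
    return TrainedModel(
        config=SVMConfig.from_dict(doc["config"]),
        support_vectors=np.array(doc["support_vectors"], dtype=float),
        dual_coefs=np.array(doc["dual_coefs"], dtype=float),
        bias=float(doc["bias"]),
        selected_features=np.array(doc["selected_features"], dtype=int),
        scaler=scaler,
        scaler_feature_ids=doc.get("scaler_feature_ids"),
    )
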