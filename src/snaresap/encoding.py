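"""PSSM-400 feature encoding and feature-matrix scaling.

The encoder maps a length-L profile to a fixed 400-dimensional
composition vector: cell (a, b) is the sum, over all positions occupied
by residue *a*, of the log-odds score in column *b*. Cells are flattened
as ``20*a + b`` with both axes in PSI-BLAST column order. Positions whose
residue is not one of the 20 canonical letters contribute to no cell.

Scaling supports min-max (the pipeline default, mapping features to
[0, 1] with clipping of out-of-range test values), z-score, and row-wise
L2. Scalers are fitted on the training split only and reused on test
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pssm_io import AA_INDEX, PSSMProfile

N_FEATURES = 400

_SCALER_METHODS = ("minmax", "zscore", "l2", "none")


class EncodingError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    """N samples × D features with ±1 labels and feature identity.

    ``feature_ids`` carries each column's original index so that feature
    selection remains reproducible at predict time. ``y`` may be ``None``
    for transform-only (unlabelled) use.
    """

    X: np.ndarray
    y: np.ndarray | None
    feature_ids: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.feature_ids = np.asarray(self.feature_ids, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.feature_ids.shape != (self.X.shape[1],):
            raise ValueError("feature_ids length must equal number of columns")
        if len(np.unique(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=int)
            if self.y.shape != (self.X.shape[0],):
                raise ValueError("y length must equal number of rows")
            if not np.all(np.isin(self.y, (-1, 1))):
                raise ValueError("labels must be +1 or -1")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select_ids(self, ids) -> "FeatureMatrix":
        """Restrict (and reorder) columns to the given original feature ids."""
        ids = np.asarray(ids, dtype=int)
        pos = {fid: j for j, fid in enumerate(self.feature_ids)}
        missing = [int(i) for i in ids if int(i) not in pos]
        if missing:
            raise KeyError(f"features not present in matrix: {missing}")
        cols = np.array([pos[int(i)] for i in ids])
        return FeatureMatrix(X=self.X[:, cols], y=self.y, feature_ids=ids.copy())


@dataclass
class NormalizationParams:
    """Fitted scaling state.

    For ``minmax`` the two slots hold per-feature min and max; for
    ``zscore`` they hold mean and standard deviation; ``l2`` and ``none``
    carry no fitted state.
    """

    method: str
    a: np.ndarray | None = None
    b: np.ndarray | None = None

    def __post_init__(self):
        if self.method not in _SCALER_METHODS:
            raise ValueError(f"unknown scaling method {self.method!r}")
        if self.a is not None:
            self.a = np.asarray(self.a, dtype=float)
        if self.b is not None:
            self.b = np.asarray(self.b, dtype=float)

    @property
    def n_features(self) -> int | None:
        return None if self.a is None else len(self.a)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "a": None if self.a is None else self.a.tolist(),
            "b": None if self.b is None else self.b.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(method=d["method"], a=d.get("a"), b=d.get("b"))


def encode_pssm_400(
    profile: PSSMProfile, length_normalize: bool = False
) -> np.ndarray:
    """Encode one profile as the 400-dimensional composition vector.

    The encoding is additive over positions, hence invariant to row order
    and additive over profile concatenation. With ``length_normalize`` the
    sums are divided by the number of canonical-residue positions.
    """
    # reorder score columns to canonical PSI-BLAST order once
    perm = np.array([AA_INDEX[c] for c in profile.column_order])
    scores = np.empty_like(profile.scores)
    scores[:, perm] = profile.scores
    row_idx = np.array([AA_INDEX.get(r, -1) for r in profile.residues])
    canonical = row_idx >= 0
    n_canonical = int(canonical.sum())
    cells = np.zeros((20, 20))
    np.add.at(cells, row_idx[canonical], scores[canonical])
    v = cells.ravel()
    if n_canonical == 0:
        raise EncodingError(
            f"profile {profile.sequence_id!r}: empty encodable sequence "
            "(no canonical residues)"
        )
    if length_normalize:
        v /= n_canonical
    return v


def encode_profiles(
    profiles, labels=None, length_normalize: bool = False
) -> FeatureMatrix:
    """Encode many profiles into one :class:`FeatureMatrix` (ids 0..399)."""
    X = np.vstack([encode_pssm_400(p, length_normalize) for p in profiles])
    y = None if labels is None else np.asarray(labels, dtype=int)
    return FeatureMatrix(X=X, y=y, feature_ids=np.arange(N_FEATURES))


def fit_scaler(M, method: str = "minmax") -> NormalizationParams:
    """Fit scaling parameters on a (training) matrix.

    ``l2`` and ``none`` are stateless; min-max stores per-feature min/max,
    z-score stores mean/stddev (population, ddof=0).
    """
    X = M.X if isinstance(M, FeatureMatrix) else np.asarray(M, dtype=float)
    if X.shape[0] < 1:
        raise ValueError("cannot fit a scaler on an empty matrix")
    if method in ("l2", "none"):
        return NormalizationParams(method=method)
    if method == "minmax":
        return NormalizationParams(method=method, a=X.min(axis=0), b=X.max(axis=0))
    if method == "zscore":
        return NormalizationParams(method=method, a=X.mean(axis=0), b=X.std(axis=0))
    raise ValueError(f"unknown scaling method {method!r}")


def apply_scaler(M, params: NormalizationParams):
    """Apply fitted scaling; returns the same container type as the input.

    min-max clips to [0, 1] (constant features map to 0); z-score maps
    zero-variance features to 0; L2 leaves all-zero rows unchanged.
    """
    is_matrix = isinstance(M, FeatureMatrix)
    X = M.X if is_matrix else np.asarray(M, dtype=float)
    if params.a is not None and X.shape[1] != len(params.a):
        raise ValueError(
            f"dimension mismatch: matrix has {X.shape[1]} features, "
            f"scaler was fitted on {len(params.a)}"
        )
    if params.method == "none":
        out = X.copy()
    elif params.method == "minmax":
        span = params.b - params.a
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (X - params.a) / span
        out[:, span == 0] = 0.0
        out = np.clip(out, 0.0, 1.0)
    elif params.method == "zscore":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (X - params.a) / params.b
        out[:, params.b == 0] = 0.0
    elif params.method == "l2":
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        out = X / norms
    else:  # pragma: no cover - guarded by NormalizationParams
        raise ValueError(params.method)
    if is_matrix:
        return FeatureMatrix(X=out, y=M.y, feature_ids=M.feature_ids.copy())
    return out
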