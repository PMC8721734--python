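"""SVM-RFE feature ranking with correlation-bias reduction (CBR).

Recursive feature elimination retrains a linear soft-margin SVM on the
surviving features each round, scores feature *i* by the squared primal
weight w_i², and eliminates the lowest-scoring features. Mutually
correlated features share discriminative weight, which depresses each
member's individual score and can unfairly eliminate a whole redundant
group at once; the CBR guard prevents this by partitioning survivors
into correlated groups — connected components of |Pearson r| >= tau —
and allowing at most one member of a group (its lowest-criterion member)
to leave per iteration.

With tau high enough that no correlations reach it, and step=1, the
procedure reduces exactly to vanilla SVM-RFE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.svm import SVC

from .encoding import FeatureMatrix


@dataclass
class RFEConfig:
    """Configuration for :func:`rank_features_rfe_cbr`.

    ranking_C
        Penalty of the internal linear ranking SVM (always linear,
        regardless of the final classifier's kernel, since the criterion
        needs a primal weight vector).
    corr_threshold
        tau in (0, 1]: absolute Pearson correlation at or above which two
        surviving features are considered members of one correlated group.
    step
        Features eliminated per iteration (before the CBR guard).
    """

    ranking_C: float = 1.0
    corr_threshold: float = 0.7
    step: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.corr_threshold <= 1.0):
            raise ValueError("corr_threshold must be in (0, 1]")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.ranking_C <= 0:
            raise ValueError("ranking_C must be > 0")


@dataclass
class FeatureRanking:
    """Full elimination trace of one RFE-CBR run.

    ``order`` lists original feature ids, best first (reverse elimination
    order). ``iteration_eliminated[i]`` and ``criterion[i]`` refer to
    ``order[i]``: the round in which it was eliminated and its w² score
    at that moment. Best-ranked features are eliminated last, so
    ``iteration_eliminated`` is non-increasing along ``order``.
    """

    order: np.ndarray
    iteration_eliminated: np.ndarray
    criterion: np.ndarray

    def __post_init__(self):
        self.order = np.asarray(self.order, dtype=int)
        self.iteration_eliminated = np.asarray(self.iteration_eliminated, dtype=int)
        self.criterion = np.asarray(self.criterion, dtype=float)
        n = len(self.order)
        if len(np.unique(self.order)) != n:
            raise ValueError("order must be a permutation (no repeats)")
        if self.iteration_eliminated.shape != (n,) or self.criterion.shape != (n,):
            raise ValueError("trace arrays must align with order")

    def surviving_at(self, iteration: int) -> np.ndarray:
        """Feature ids still alive at the *start* of the given iteration."""
        return self.order[self.iteration_eliminated >= iteration]


def _abs_correlation(X: np.ndarray) -> np.ndarray:
    """|Pearson r| between all feature pairs; constant features correlate
    with nothing (NaN -> 0)."""
    if X.shape[1] == 1:
        return np.ones((1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    return np.abs(r)


def rank_features_rfe_cbr(M: FeatureMatrix, cfg: RFEConfig | None = None) -> FeatureRanking:
    """Rank all features by SVM-RFE with the CBR guard.

    Each iteration: fit a linear SVM on the survivors, score each
    surviving feature by w_i², partition survivors into correlated groups
    (transitive closure of |r| >= tau), then eliminate up to ``step``
    features in ascending criterion order — skipping any feature whose
    group already lost a member this iteration. Ties in the criterion are
    broken toward the lower original feature index. Deterministic:
    identical inputs give a bit-identical trace.

    Pairwise Pearson correlations do not depend on which other features
    survive, so the correlation matrix is computed once and subset.
    """
    cfg = cfg or RFEConfig()
    if M.y is None or len(np.unique(M.y)) < 2:
        raise ValueError("ranking requires both classes")
    X, y, ids = M.X, M.y, M.feature_ids
    D = X.shape[1]
    corr = _abs_correlation(X)

    surviving = list(range(D))
    elim_order: list[int] = []
    elim_iter: list[int] = []
    elim_crit: list[float] = []
    iteration = 0
    while surviving:
        iteration += 1
        svc = SVC(kernel="linear", C=cfg.ranking_C)
        svc.fit(X[:, surviving], y)
        w2 = np.asarray(svc.coef_).ravel() ** 2

        adj = corr[np.ix_(surviving, surviving)] >= cfg.corr_threshold
        _, groups = connected_components(csr_matrix(adj), directed=False)

        candidates = sorted(
            range(len(surviving)), key=lambda j: (w2[j], ids[surviving[j]])
        )
        used_groups: set[int] = set()
        batch: list[int] = []
        for j in candidates:
            if groups[j] in used_groups:
                continue
            used_groups.add(groups[j])
            batch.append(j)
            if len(batch) == cfg.step:
                break
        for j in batch:
            elim_order.append(surviving[j])
            elim_iter.append(iteration)
            elim_crit.append(float(w2[j]))
        drop = set(batch)
        surviving = [s for k, s in enumerate(surviving) if k not in drop]

    rev = slice(None, None, -1)
    return FeatureRanking(
        order=ids[np.array(elim_order)][rev],
        iteration_eliminated=np.array(elim_iter)[rev],
        criterion=np.array(elim_crit)[rev],
    )


def select_top_k(M: FeatureMatrix, ranking: FeatureRanking, k: int) -> FeatureMatrix:
    """Restrict a matrix to the k best-ranked features (ids preserved)."""
    if not (1 <= k <= len(ranking.order)):
        raise ValueError(f"k={k} out of range [1, {len(ranking.order)}]")
    return M.select_ids(ranking.order[:k])


def sweep_top_k(
    M: FeatureMatrix,
    ranking: FeatureRanking,
    ks,
    cv_folds: int = 10,
    svm_cfg=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated accuracy of the classifier at each top-k cut.

    Returns a DataFrame with columns ``k``, ``mean_cv_accuracy`` and
    ``std_cv_accuracy`` (per-fold standard deviation). Deterministic
    given the seed.
    """
    from .classifier import SVMConfig
    from .evaluation import cross_validate

    ks = list(ks)
    if not ks:
        raise ValueError("ks must be non-empty")
    svm_cfg = svm_cfg or SVMConfig()
    rows = []
    for k in ks:
        sub = select_top_k(M, ranking, k)
        report = cross_validate(sub, svm_cfg, folds=cv_folds, seed=seed)
        accs = [f.acc for f in report.per_fold]
        rows.append(
            {
                "k": k,
                "mean_cv_accuracy": float(np.mean(accs)),
                "std_cv_accuracy": float(np.std(accs)),
            }
        )
    return pd.DataFrame(rows)
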