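"""SVM recursive feature elimination with correlation-bias reduction.

Plain SVM-RFE trains a linear SVM on the surviving features, scores each
feature by its squared weight, and discards the weakest fraction per
iteration. When several features are highly correlated the weight mass is
split among them, so informative but redundant features can be eliminated
early — the correlation bias. The reduction used here scores features in
groups: features whose absolute pairwise correlation exceeds a threshold
form connected components, and every member inherits the component's best
squared-weight score, so a correlated informative group sinks or survives
together.

The ranking SVM is linear because the squared-weight criterion needs an
explicit weight vector; the downstream classifier is free to use an RBF
kernel on the selected subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC, LinearSVC

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)


@dataclass
class RankedFeatureList:
    """Feature ranking produced by the elimination loop.

    ``order[k]`` is the feature index with rank k+1 (rank 1 = most
    important, i.e. eliminated last); ``ranks[i]`` is the rank of feature
    i. ``elimination_history`` records (iteration, removed indices, their
    criterion scores at removal).
    """

    order: np.ndarray
    elimination_history: list[tuple[int, np.ndarray, np.ndarray]] = field(default_factory=list)
    correlation_threshold: float = 0.9

    @property
    def ranks(self) -> np.ndarray:
        ranks = np.empty(self.order.size, dtype=int)
        ranks[self.order] = np.arange(1, self.order.size + 1)
        return ranks

    def top_k(self, k: int) -> np.ndarray:
        if not (1 <= k <= self.order.size):
            raise ConfigurationError(f"k must be in [1, {self.order.size}], got {k}")
        return np.sort(self.order[:k])


def _correlation_groups(X: np.ndarray, threshold: float) -> np.ndarray:
    """Component label per column of X under |corr| > threshold edges."""
    n = X.shape[1]
    if n == 1:
        return np.zeros(1, dtype=int)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    adj = (np.abs(corr) > threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


def svm_rfe_cbr(
    X: np.ndarray,
    y: np.ndarray,
    step_fraction: float = 0.1,
    corr_threshold: float = 0.9,
    C: float = 1.0,
    seed: int = 0,
) -> RankedFeatureList:
    """Rank all features by recursive elimination with correlation-grouped
    scoring.

    Constant-variance features cannot carry signal and destabilize the
    correlation graph; they are pre-filtered (logged) and assigned the
    worst ranks.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise InputError("feature ranking needs samples from both classes")
    if not (0 < step_fraction < 1):
        raise ConfigurationError("step_fraction must be in (0, 1)")
    n_features = X.shape[1]
    variances = X.var(axis=0)
    constant = np.flatnonzero(variances == 0.0)
    if constant.size:
        logger.warning("%d constant feature(s) excluded from ranking", constant.size)
    surviving = np.flatnonzero(variances > 0.0)
    eliminated: list[np.ndarray] = []  # chunks, first-removed first
    history: list[tuple[int, np.ndarray, np.ndarray]] = []
    iteration = 0
    while surviving.size > 1:
        iteration += 1
        Xs = X[:, surviving]
        scaler = StandardScaler().fit(Xs)
        model = LinearSVC(C=C, dual="auto", max_iter=20000, random_state=seed)
        model.fit(scaler.transform(Xs), y)
        scores = np.ravel(model.coef_) ** 2
        groups = _correlation_groups(Xs, corr_threshold)
        group_best = {}
        for g, sc in zip(groups, scores):
            group_best[g] = max(group_best.get(g, -np.inf), sc)
        effective = np.array([group_best[g] for g in groups])
        n_remove = max(1, int(round(step_fraction * surviving.size)))
        n_remove = min(n_remove, surviving.size - 1)
        # weakest first; ties broken by raw score, then by higher index
        order = np.lexsort((-surviving, scores, effective))
        removed_local = order[:n_remove]
        removed = surviving[removed_local]
        # record weakest-first within the chunk
        history.append((iteration, removed.copy(), scores[removed_local].copy()))
        eliminated.append(removed)
        keep = np.ones(surviving.size, dtype=bool)
        keep[removed_local] = False
        surviving = surviving[keep]
    # rank 1 = survivor; then chunks in reverse removal order, strongest first
    parts = [surviving]
    for chunk in reversed(eliminated):
        parts.append(chunk[::-1])
    if constant.size:
        parts.append(constant)
    order = np.concatenate(parts) if parts else np.array([], dtype=int)
    assert order.size == n_features
    return RankedFeatureList(
        order=order.astype(int),
        elimination_history=history,
        correlation_threshold=corr_threshold,
    )


def select_top_k(
    ranked: RankedFeatureList,
    k: int | str = "auto",
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
    inner_cv: int = 3,
    k_grid: list[int] | None = None,
    C: float = 1.0,
    gamma: float | str = "scale",
    seed: int = 0,
) -> tuple[np.ndarray, int, dict[int, float]]:
    """Select the top-k ranked features.

    With ``k='auto'`` the subset size is chosen from a logarithmic grid by
    inner stratified-CV AUC of an RBF SVM fit on the candidate subset;
    call this with training-fold data only. Returns (selected indices,
    chosen k, {k: mean inner AUC}).
    """
    n_features = ranked.order.size
    if isinstance(k, (int, np.integer)):
        return ranked.top_k(int(k)), int(k), {}
    if k != "auto":
        raise ConfigurationError(f"k must be an int or 'auto', got {k!r}")
    if X is None or y is None:
        raise ConfigurationError("k='auto' requires X and y")
    if k_grid is None:
        k_grid = sorted({int(round(v)) for v in np.geomspace(1, n_features, num=12)})
    cv_scores: dict[int, float] = {}
    skf = StratifiedKFold(n_splits=inner_cv, shuffle=True, random_state=seed)
    for kk in k_grid:
        cols = ranked.top_k(kk)
        aucs = []
        for tr, te in skf.split(X, y):
            pipe = Pipeline(
                [("scale", StandardScaler()), ("svc", SVC(C=C, gamma=gamma, kernel="rbf"))]
            )
            pipe.fit(X[np.ix_(tr, cols)], y[tr])
            scores = pipe.decision_function(X[np.ix_(te, cols)])
            aucs.append(roc_auc_score(y[te], scores))
        cv_scores[kk] = float(np.mean(aucs))
    best_k = max(k_grid, key=lambda kk: (cv_scores[kk], -kk))
    logger.info("auto k selection: chose k=%d (inner AUC %.4f)", best_k, cv_scores[best_k])
    return ranked.top_k(best_k), best_k, cv_scores
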