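"""RBF-SVM training, cross-validated evaluation, and novel-pair ranking.

The classifier is a soft-margin SVM with a radial basis kernel,
f(x) = sgn(sum_i y_i alpha_i K(x, x_i) + b), fit on z-scored pair
features. Evaluation runs stratified cross-validation; within each fold
the held-out positive edges are masked out of the network before profile
features are built, normalization statistics and (optionally) the
feature-selection ranking are fit on the training rows only, and the
test fold is scored by the decision function, so no step sees test
labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import metrics
from .datasets import PairDataset, assemble_features
from .errors import ConfigurationError, InputError
from .network import InteractionNetwork, mask_test_edges

logger = logging.getLogger(__name__)

#: Hyperparameter grid (powers of 4) used when tuning is requested.
C_GRID = [2.0**e for e in range(-5, 16, 2)]
GAMMA_GRID = [2.0**e for e in range(-15, 4, 2)]


@dataclass
class TrainedModel:
    """A fitted RBF-SVM plus everything needed to reproduce its scores:
    normalization statistics, selected feature indices and kernel
    parameters."""

    svc: SVC
    scaler: StandardScaler
    selected: np.ndarray | None
    C: float
    gamma: float | str
    feature_labels: list[str] | None = None
    metadata: dict = field(default_factory=dict)
    calibrated: CalibratedClassifierCV | None = None

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        if self.selected is not None:
            X = X[:, self.selected]
        return self.scaler.transform(X)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self._prepare(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_scores(X) > 0, 1, -1)

    def probabilities(self, X: np.ndarray) -> np.ndarray:
        """Platt-calibrated P(interaction); requires probability training."""
        if self.calibrated is None:
            raise ConfigurationError("model was trained without probability calibration")
        col = list(self.calibrated.classes_).index(1)
        return self.calibrated.predict_proba(self._prepare(X))[:, col]


def train(
    X: np.ndarray,
    y: np.ndarray,
    selected: np.ndarray | None = None,
    C: float | str = 1.0,
    gamma: float | str = "scale",
    probability: bool = False,
    inner_cv: int = 3,
    seed: int = 0,
    feature_labels: list[str] | None = None,
) -> TrainedModel:
    """Fit the RBF-SVM on (optionally feature-selected) z-scored data.

    ``C='grid'`` (or ``gamma='grid'``) runs an inner stratified-CV search
    over a log2 grid maximizing AUC; the chosen values are recorded in the
    model metadata.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise InputError("training fold contains a single class")
    if selected is not None:
        selected = np.asarray(selected, dtype=int)
        X = X[:, selected]
    scaler = StandardScaler().fit(X)
    # zero-variance columns scale to 1 so binary blocks pass through safely
    scaler.scale_[scaler.scale_ == 0.0] = 1.0
    Xs = scaler.transform(X)

    metadata: dict = {}
    if C == "grid" or gamma == "grid":
        c_grid = C_GRID if C == "grid" else [float(C)]
        g_grid = GAMMA_GRID if gamma == "grid" else [gamma]
        C, gamma, search = _grid_search(Xs, y, c_grid, g_grid, inner_cv, seed)
        metadata["grid_search"] = search
    svc = SVC(C=float(C), gamma=gamma, kernel="rbf", random_state=seed)
    svc.fit(Xs, y)
    calibrated = None
    if probability:
        # Platt scaling on training data only (sigmoid over decision values)
        calibrated = CalibratedClassifierCV(
            SVC(C=float(C), gamma=gamma, kernel="rbf", random_state=seed),
            method="sigmoid", cv=inner_cv, ensemble=False,
        )
        calibrated.fit(Xs, y)
    metadata.update({"C": float(C), "gamma": gamma, "n_train": int(y.size)})
    return TrainedModel(
        svc=svc, scaler=scaler, selected=selected, C=float(C), gamma=gamma,
        feature_labels=feature_labels, metadata=metadata, calibrated=calibrated,
    )


def _grid_search(Xs, y, c_grid, g_grid, inner_cv, seed):
    skf = StratifiedKFold(n_splits=inner_cv, shuffle=True, random_state=seed)
    results = []
    for c in c_grid:
        for g in g_grid:
            aucs = []
            for tr, te in skf.split(Xs, y):
                svc = SVC(C=c, gamma=g, kernel="rbf").fit(Xs[tr], y[tr])
                aucs.append(metrics.roc_auc(y[te], svc.decision_function(Xs[te])))
            results.append((float(np.mean(aucs)), c, g))
    best_auc, best_c, best_g = max(results, key=lambda r: (r[0], -r[1]))
    logger.info("grid search chose C=%g gamma=%g (inner AUC %.4f)", best_c, best_g, best_auc)
    return best_c, best_g, {"best_auc": best_auc, "C": best_c, "gamma": best_g}


@dataclass
class EvaluationReport:
    """Per-fold and aggregate cross-validation metrics."""

    fold_metrics: list[dict]
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    regime: str
    seed: int
    skipped_folds: int = 0

    METRIC_NAMES = ("acc", "sn", "spec", "auc", "aupr")

    def mean(self, name: str) -> float:
        return float(np.mean([m[name] for m in self.fold_metrics]))

    def sd(self, name: str) -> float:
        return float(np.std([m[name] for m in self.fold_metrics], ddof=1))

    def summary(self) -> dict:
        out = {}
        for name in self.METRIC_NAMES:
            out[name] = {"mean": self.mean(name), "sd": self.sd(name)}
        out["n_folds"] = len(self.fold_metrics)
        out["skipped_folds"] = self.skipped_folds
        return out

    def roc_points(self) -> np.ndarray:
        return metrics.roc_points(self.pooled_labels, self.pooled_scores)

    def pr_points(self) -> np.ndarray:
        return metrics.pr_points(self.pooled_labels, self.pooled_scores)


def _fold_metrics(y_true, scores) -> dict:
    c = metrics.confusion_counts(y_true, np.where(scores > 0, 1, -1))
    return {
        "acc": metrics.accuracy(c),
        "sn": metrics.sensitivity(c),
        "spec": metrics.specificity(c),
        "auc": metrics.roc_auc(y_true, scores),
        "aupr": metrics.aupr(y_true, scores),
        "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
    }


def evaluate_cv(
    dataset: PairDataset,
    network: InteractionNetwork,
    target_feats: dict,
    drug_fps: dict,
    n_folds: int = 5,
    seed: int = 0,
    selection: dict | None = None,
    C: float | str = 8.0,
    gamma: float | str = "scale",
    mask_network: bool = True,
    include_net: bool = True,
    regime: str = "balanced-5fold",
) -> EvaluationReport:
    """Stratified k-fold cross-validation of the full pipeline.

    ``selection``, if given, is a dict of :func:`dtiwave.selection.svm_rfe_cbr`
    / ``select_top_k`` options (``k``, ``step_fraction``, ``corr_threshold``)
    applied inside each training fold. ``mask_network=False`` reproduces the
    permissive protocol in which profiles see held-out edges.
    """
    from .selection import select_top_k, svm_rfe_cbr  # local: avoids cycle

    y = dataset.labels
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_metrics = []
    pooled_scores, pooled_labels = [], []
    skipped = 0
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(dataset)), y)):
        if np.unique(y[te]).size < 2 or np.unique(y[tr]).size < 2:
            logger.warning("fold %d has a single class; skipped", fold)
            skipped += 1
            continue
        test_pos = [dataset.pairs[i] for i in te if y[i] == 1]
        net = mask_test_edges(network, test_pos) if mask_network else network
        train_ds = PairDataset(pairs=[dataset.pairs[i] for i in tr], labels=y[tr])
        test_ds = PairDataset(pairs=[dataset.pairs[i] for i in te], labels=y[te])
        X_tr = assemble_features(train_ds, net, target_feats, drug_fps, include_net)
        X_te = assemble_features(test_ds, net, target_feats, drug_fps, include_net)
        selected = None
        if selection is not None:
            ranked = svm_rfe_cbr(
                X_tr, y[tr],
                step_fraction=selection.get("step_fraction", 0.1),
                corr_threshold=selection.get("corr_threshold", 0.9),
                C=selection.get("rfe_C", 1.0),
                seed=seed,
            )
            selected, _, _ = select_top_k(
                ranked, selection.get("k", "auto"), X_tr, y[tr], seed=seed,
            )
        model = train(X_tr, y[tr], selected=selected, C=C, gamma=gamma, seed=seed)
        scores = model.decision_scores(X_te)
        fold_metrics.append(_fold_metrics(y[te], scores))
        pooled_scores.append(scores)
        pooled_labels.append(y[te])
    if not fold_metrics:
        raise InputError("every fold was skipped; cannot evaluate")
    return EvaluationReport(
        fold_metrics=fold_metrics,
        pooled_scores=np.concatenate(pooled_scores),
        pooled_labels=np.concatenate(pooled_labels),
        regime=regime,
        seed=seed,
        skipped_folds=skipped,
    )


def rank_novel_pairs(
    model: TrainedModel,
    network: InteractionNetwork,
    target_feats: dict,
    drug_fps: dict,
    top_n: int = 5,
    use_probability: bool = False,
    include_net: bool = True,
):
    """Score every unknown pair with the trained model and rank descending.

    Ties are broken by (drug_id, target_id) lexicographic order. Returns a
    list of (drug_id, target_id, score), highest first, of length
    min(top_n, number of unknown pairs), plus the full table.
    """
    unknown = network.unknown_pairs()
    if not unknown:
        return [], []
    ds = PairDataset(pairs=unknown, labels=np.ones(len(unknown), int))
    X = assemble_features(ds, network, target_feats, drug_fps, include_net)
    scores = model.probabilities(X) if use_probability else model.decision_scores(X)
    rows = sorted(
        ((d, t, float(s)) for (d, t), s in zip(unknown, scores)),
        key=lambda r: (-r[2], r[0], r[1]),
    )
    return rows[: min(top_n, len(rows))], rows
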