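"""Two-stage pan-tissue framework: tissue classification, then routing.

Stage 1 classifies the tissue type of a slide from its embedding using a
multinomial L1-penalized logistic model on the top-k ANOVA-F discriminative
features. Stage 2 routes the slide to that tissue's pre-trained RIN and
autolysis models, but only when the classifier's confidence (max class
probability) meets a threshold (default 0.6, boundary inclusive); slides
below the threshold are left uncovered unless a fallback flag forces
argmax routing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .tissue_models import (
    QualityModel,
    SlideRecord,
    _target_vector,
    autolysis_class_accuracy,
    pearson_r,
    rmse,
    train_quality_model,
)

__all__ = [
    "TissueClassifier",
    "PanTissueModel",
    "RoutedPrediction",
    "PanTissueReport",
    "anova_f_select",
    "fit_tissue_classifier",
    "train_pan_tissue",
    "route_and_predict",
    "evaluate_pan",
]


def anova_f_select(X: np.ndarray, tissue_labels: Sequence[str], k: int = 500) -> np.ndarray:
    """Top-k features by one-way ANOVA F across tissue groups.

    Features that are constant (zero between-group variance, undefined F)
    rank last; ties break toward the lower index. If fewer than ``k``
    features exist, all are returned in rank order.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(tissue_labels)
    if np.unique(labels).size < 2:
        raise ValueError("ANOVA F selection needs at least two tissue classes")
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant features are expected and deliberately ranked last
        warnings.filterwarnings("ignore", message="Features .* are constant")
        f_vals, _ = f_classif(X, labels)
    f_vals = np.nan_to_num(f_vals, nan=0.0, posinf=np.finfo(float).max)
    order = np.argsort(-f_vals, kind="stable")
    return order[: min(k, X.shape[1])]


@dataclass
class TissueClassifier:
    """Multinomial L1 logistic model with internal standardization.

    ``C`` is the inverse penalty strength selected by stratified CV at the
    minimum mean held-out deviance (log loss).
    """

    model: LogisticRegression
    feature_means: np.ndarray
    feature_sds: np.ndarray
    C: float
    cv_accuracy: float
    cv_deviance: float

    @property
    def classes(self) -> np.ndarray:
        return self.model.classes_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.feature_means) / self.feature_sds
        return self.model.predict_proba(Z)


def _make_logreg(C: float, seed: int) -> LogisticRegression:
    # pure L1 penalty; l1_ratio is the non-deprecated spelling on recent sklearn
    try:
        return LogisticRegression(
            l1_ratio=1.0, C=C, solver="saga", max_iter=2000, tol=1e-3,
            random_state=seed,
        )
    except TypeError:  # older sklearn without bare l1_ratio support
        return LogisticRegression(
            penalty="l1", C=C, solver="saga", max_iter=2000, tol=1e-3,
            random_state=seed,
        )


def fit_tissue_classifier(
    X_selected: np.ndarray,
    tissue_labels: Sequence[str],
    n_folds: int = 5,
    seed: int = 0,
    Cs: Sequence[float] = (0.01, 0.1, 1.0, 10.0),
) -> TissueClassifier:
    """Fit the multinomial lasso tissue classifier with stratified k-fold CV.

    The penalty is chosen by minimum mean held-out deviance over ``Cs``;
    the winning model is refit on all rows. Class probabilities come from
    the softmax and sum to one for any input.
    """
    X = np.asarray(X_selected, dtype=float)
    labels = np.asarray(tissue_labels)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < n_folds]
    if small.size:
        raise ValueError(
            f"classes with fewer than n_folds={n_folds} slides: {list(small)}; "
            "merge these tissues, drop them, or reduce n_folds"
        )

    sds = X.std(axis=0, ddof=0)
    sds[sds == 0] = 1.0
    means = X.mean(axis=0)
    Z = (X - means) / sds

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Z, labels))
    mean_dev = []
    mean_acc = []
    for C in Cs:
        devs, accs = [], []
        for tr, te in splits:
            clf = _make_logreg(C, seed).fit(Z[tr], labels[tr])
            proba = clf.predict_proba(Z[te])
            devs.append(log_loss(labels[te], proba, labels=list(clf.classes_)))
            accs.append(float(np.mean(clf.predict(Z[te]) == labels[te])))
        mean_dev.append(float(np.mean(devs)))
        mean_acc.append(float(np.mean(accs)))
    best = int(np.argmin(mean_dev))
    final = _make_logreg(Cs[best], seed).fit(Z, labels)
    return TissueClassifier(
        model=final, feature_means=means, feature_sds=sds,
        C=float(Cs[best]), cv_accuracy=mean_acc[best], cv_deviance=mean_dev[best],
    )


@dataclass
class PanTissueModel:
    """The complete two-stage pan-tissue predictor.

    ``selected_features`` indexes the embedding columns fed to the tissue
    classifier; ``tissue_registry`` maps each tissue to its RIN and
    autolysis models (trained on all embedding features). A slide is
    covered when the classifier's max probability is at least
    ``confidence_threshold``.
    """

    selected_features: np.ndarray
    classifier: TissueClassifier
    tissue_registry: dict[str, dict[str, QualityModel]]
    confidence_threshold: float = 0.6

    def __post_init__(self) -> None:
        missing = set(self.classifier.classes) - set(self.tissue_registry)
        if missing:
            raise ValueError(f"registry missing tissues: {sorted(missing)}")


@dataclass
class RoutedPrediction:
    """Routing outcome for one slide."""

    slide_id: str
    predicted_tissue: str
    confidence: float
    covered: bool
    rin_pred: float | None = None
    autolysis_pred: float | None = None
    fallback_used: bool = False
    probabilities: np.ndarray | None = None


def route_and_predict(
    embedding: np.ndarray,
    model: PanTissueModel,
    slide_id: str = "",
    fallback: bool = False,
) -> RoutedPrediction:
    """Classify a slide's tissue and, if confident, predict its quality.

    ``covered`` is True iff confidence >= the threshold (inclusive).
    Uncovered slides receive no quality predictions unless ``fallback``
    routes them by argmax anyway (flagged in the result).
    """
    embedding = np.asarray(embedding, dtype=float).ravel()
    proba = model.classifier.predict_proba(embedding[model.selected_features][None, :])[0]
    best = int(np.argmax(proba))
    tissue = str(model.classifier.classes[best])
    confidence = float(proba[best])
    covered = confidence >= model.confidence_threshold
    if tissue not in model.tissue_registry:
        raise KeyError(f"predicted tissue {tissue!r} absent from registry")

    rin_pred = autolysis_pred = None
    if covered or fallback:
        reg = model.tissue_registry[tissue]
        rin_pred = float(reg["rin"].predict(embedding[None, :])[0])
        autolysis_pred = float(reg["autolysis"].predict(embedding[None, :])[0])
    return RoutedPrediction(
        slide_id=slide_id,
        predicted_tissue=tissue,
        confidence=confidence,
        covered=covered,
        rin_pred=rin_pred,
        autolysis_pred=autolysis_pred,
        fallback_used=(not covered) and fallback,
        probabilities=proba,
    )


def train_pan_tissue(
    records: Sequence[SlideRecord],
    X: np.ndarray,
    k: int = 500,
    confidence_threshold: float = 0.6,
    n_folds: int = 5,
    seed: int = 0,
    top_fraction: float = 0.05,
) -> PanTissueModel:
    """Train the full two-stage model on slides with complete quality labels.

    ANOVA-F feature selection and the classifier penalty search run on the
    supplied rows; per-tissue RIN and autolysis models are trained on all
    embedding features with stratified (binned-target) fold assignment for
    their lambda search.
    """
    X = np.asarray(X, dtype=float)
    complete = [
        i for i, r in enumerate(records) if r.rin is not None and r.autolysis is not None
    ]
    if not complete:
        raise ValueError("no slides with complete RIN and autolysis labels")
    recs = [records[i] for i in complete]
    Xc = X[complete]
    labels = np.array([r.tissue for r in recs])

    sel = anova_f_select(Xc, labels, k=k)
    classifier = fit_tissue_classifier(Xc[:, sel], labels, n_folds=n_folds, seed=seed)

    registry: dict[str, dict[str, QualityModel]] = {}
    for tissue in np.unique(labels):
        rows = np.flatnonzero(labels == tissue)
        registry[tissue] = {}
        for target in ("rin", "autolysis"):
            y = _target_vector([recs[i] for i in rows], target)
            registry[tissue][target] = train_quality_model(
                Xc[rows], y, tissue=tissue, target=target,
                n_folds=n_folds, seed=seed, top_fraction=top_fraction,
            )
    return PanTissueModel(
        selected_features=sel,
        classifier=classifier,
        tissue_registry=registry,
        confidence_threshold=confidence_threshold,
    )


@dataclass
class PanTissueReport:
    """Slide-level evaluation of the two-stage framework."""

    accuracy: float
    macro_f1: float
    macro_auc: float
    pairwise_auc: dict[tuple[str, str], float]
    coverage: float
    rin_r: float
    rin_rmse: float
    autolysis_r: float
    autolysis_accuracy: float
    per_tissue: dict[str, dict[str, float]] = field(default_factory=dict)


def evaluate_pan(
    routed: Sequence[RoutedPrediction],
    truth: Sequence[SlideRecord],
) -> PanTissueReport:
    """Score routed predictions against the manifest ground truth.

    Classification metrics (accuracy, macro F1, macro one-vs-rest AUC, all
    pairwise one-vs-one AUCs) use every slide; coverage is the fraction at
    or above the confidence threshold; quality metrics (Pearson R and RMSE
    for RIN, Pearson R and rounded-class accuracy for autolysis) are
    computed on covered slides only.
    """
    truth_by_id = {r.slide_id: r for r in truth}
    missing = [r.slide_id for r in routed if r.slide_id not in truth_by_id]
    if missing:
        raise ValueError(f"routed slides missing from truth: {missing[:5]}")

    y_true = np.array([truth_by_id[r.slide_id].tissue for r in routed])
    y_pred = np.array([r.predicted_tissue for r in routed])
    accuracy = float(np.mean(y_true == y_pred))
    macro_f1 = float(f1_score(y_true, y_pred, average="macro", zero_division=0))

    proba = None
    if all(r.probabilities is not None for r in routed):
        proba = np.vstack([r.probabilities for r in routed])
    macro_auc = float("nan")
    pairwise: dict[tuple[str, str], float] = {}
    if proba is not None:
        # class order follows the classifier; recover it from any covered record
        # via the probabilities' argmax consistency is fragile, so we require
        # the caller's classifier ordering: sorted unique labels (sklearn).
        class_order = np.unique(y_true)
        if proba.shape[1] == class_order.size and class_order.size > 1:
            if class_order.size == 2:
                macro_auc = float(roc_auc_score(y_true, proba[:, 1]))
            else:
                macro_auc = float(
                    roc_auc_score(y_true, proba, multi_class="ovr", average="macro",
                                  labels=list(class_order))
                )
            for i, a in enumerate(class_order):
                for j, b in enumerate(class_order):
                    if j <= i:
                        continue
                    pair_mask = (y_true == a) | (y_true == b)
                    if np.unique(y_true[pair_mask]).size < 2:
                        continue
                    sub = proba[pair_mask][:, [i, j]]
                    sub = sub / sub.sum(axis=1, keepdims=True)
                    pairwise[(str(a), str(b))] = float(
                        roc_auc_score((y_true[pair_mask] == b).astype(int), sub[:, 1])
                    )

    covered = [r for r in routed if r.covered]
    coverage = len(covered) / len(routed)

    def _quality(target: str):
        pred, obs, tissues = [], [], []
        for r in covered:
            val = truth_by_id[r.slide_id].get_target(target)
            p = r.rin_pred if target == "rin" else r.autolysis_pred
            if val is not None and p is not None:
                pred.append(p)
                obs.append(float(val))
                tissues.append(truth_by_id[r.slide_id].tissue)
        return np.array(pred), np.array(obs), np.array(tissues)

    rin_pred, rin_obs, rin_tis = _quality("rin")
    auto_pred, auto_obs, auto_tis = _quality("autolysis")
    rin_r = pearson_r(rin_pred, rin_obs) if rin_pred.size else float("nan")
    rin_rmse = rmse(rin_pred, rin_obs) if rin_pred.size else float("nan")
    auto_r = pearson_r(auto_pred, auto_obs) if auto_pred.size else float("nan")
    auto_acc = (
        autolysis_class_accuracy(auto_pred, auto_obs) if auto_pred.size else float("nan")
    )

    per_tissue: dict[str, dict[str, float]] = {}
    for tissue in np.unique(np.concatenate([rin_tis, auto_tis])) if rin_tis.size or auto_tis.size else []:
        entry: dict[str, float] = {}
        m = rin_tis == tissue
        if m.sum() >= 2:
            entry["rin_r"] = pearson_r(rin_pred[m], rin_obs[m])
            entry["rin_rmse"] = rmse(rin_pred[m], rin_obs[m])
        m = auto_tis == tissue
        if m.sum() >= 2:
            entry["autolysis_r"] = pearson_r(auto_pred[m], auto_obs[m])
            entry["autolysis_accuracy"] = autolysis_class_accuracy(auto_pred[m], auto_obs[m])
        per_tissue[str(tissue)] = entry

    return PanTissueReport(
        accuracy=accuracy,
        macro_f1=macro_f1,
        macro_auc=macro_auc,
        pairwise_auc=pairwise,
        coverage=coverage,
        rin_r=rin_r,
        rin_rmse=rin_rmse,
        autolysis_r=auto_r,
        autolysis_accuracy=auto_acc,
        per_tissue=per_tissue,
    )
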