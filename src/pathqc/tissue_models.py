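"""Tissue-specific L1-penalized regression of quality metrics on slide embeddings.

For each tissue and each target (RIN on the continuous 1-10 scale, autolysis
on the ordinal 0-3 scale treated as a regression target) the model is

    beta* = argmin_beta  1/(2N) ||y - X beta||^2  +  lambda ||beta||_1

with the penalty lambda chosen by k-fold cross-validation at the minimum
mean held-out squared error (lambda_min) over a 100-point log-spaced grid
descending from lambda_max (where every coefficient vanishes) to
lambda_max * 1e-4. Before fitting, features are z-scored (zero-variance
columns dropped) and the top 5% of features most correlated with the target
are pre-selected; both steps are refit inside every cross-validation fold so
no information leaks from held-out slides.

Evaluation is at the slide level: pooled held-out predictions across folds,
summarized by Pearson R and RMSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "SlideRecord",
    "QualityModel",
    "FoldResult",
    "LassoFit",
    "stratified_split",
    "Standardizer",
    "standardize_features",
    "select_top_correlated",
    "lambda_grid",
    "fit_lasso",
    "train_quality_model",
    "cross_validate_tissue",
    "train_final_and_test",
    "autolysis_class_accuracy",
    "pearson_r",
    "rmse",
]


@dataclass
class SlideRecord:
    """One manifest row: slide identity, tissue, quality labels, covariates.

    ``rin`` lives in [1, 10]; ``autolysis`` is the ordinal pathologist score
    0 (none) / 1 (slight) / 2 (moderate) / 3 (severe); ``hardy`` is the
    ordinal death-circumstance scale. Missing values are ``None``; a slide
    missing a target is excluded from that target's task only.
    """

    slide_id: str
    donor_id: str
    tissue: str
    rin: float | None = None
    autolysis: int | None = None
    hardy: int | None = None
    age: float | None = None
    sex: str | None = None

    def get_target(self, target: str) -> float | None:
        if target not in ("rin", "autolysis"):
            raise ValueError(f"unknown target {target!r}")
        return getattr(self, target)


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


# ---------------------------------------------------------------------------
# train/test splitting


def _rin_quartile_bins(rins: np.ndarray) -> np.ndarray:
    """Quartile bin (0-3) of each RIN value, cut points from the full cohort;
    NaN maps to bin -1."""
    finite = rins[np.isfinite(rins)]
    if finite.size == 0:
        return np.full(rins.shape, -1, dtype=int)
    cuts = np.percentile(finite, [25, 50, 75])
    bins = np.searchsorted(cuts, rins, side="right")
    bins[~np.isfinite(rins)] = -1
    return bins.astype(int)


def stratified_split(
    records: Sequence[SlideRecord],
    test_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Train/test split stratified by tissue type and RIN quartile.

    RIN quartile cut points are computed on the full labeled cohort before
    splitting. Within each tissue, quartile strata with fewer than two
    members are merged into the nearest (by quartile index) sufficiently
    large stratum of the same tissue; slides with missing RIN form their own
    stratum per tissue. Each stratum is split to within one slide of the
    requested test fraction; the result is reproducible for a fixed seed.
    """
    if not records:
        raise ValueError("no records to split")
    rng = np.random.default_rng(seed)
    rins = np.array(
        [r.rin if r.rin is not None else np.nan for r in records], dtype=float
    )
    bins = _rin_quartile_bins(rins)

    # group record positions by (tissue, quartile bin)
    strata: dict[tuple[str, int], list[int]] = {}
    for i, rec in enumerate(records):
        strata.setdefault((rec.tissue, int(bins[i])), []).append(i)

    # merge undersized strata into the nearest quartile within the tissue
    for (tissue, b) in sorted(list(strata)):
        members = strata.get((tissue, b))
        if members is None or len(members) >= 2:
            continue
        candidates = [
            (abs(b2 - b), b2)
            for (t2, b2) in strata
            if t2 == tissue and b2 != b and len(strata[(t2, b2)]) >= 2
        ]
        if candidates:
            _, b_near = min(candidates)
            strata[(tissue, b_near)].extend(members)
            del strata[(tissue, b)]
        # a tissue consisting of a single slide stays its own stratum

    # largest-remainder apportionment: per-stratum test counts within one
    # slide of the stratum's target, totals matching round(N * fraction)
    keys = sorted(strata)
    targets = np.array([len(strata[k]) * test_fraction for k in keys])
    counts = np.floor(targets).astype(int)
    n_total = int(round(len(records) * test_fraction))
    shortfall = n_total - counts.sum()
    if shortfall > 0:
        order = np.argsort(-(targets - counts), kind="stable")
        for j in order[:shortfall]:
            counts[j] += 1

    train_ids: list[str] = []
    test_ids: list[str] = []
    for key, n_test in zip(keys, counts):
        idx = np.array(strata[key])
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            (test_ids if pos < n_test else train_ids).append(records[i].slide_id)
    return sorted(train_ids), sorted(test_ids)


# ---------------------------------------------------------------------------
# feature standardization and screening


@dataclass
class Standardizer:
    """Z-scoring parameters fit on training data, reusable on new data.

    ``kept`` holds the original column indices that survived the
    zero-variance filter; ``means``/``sds`` are aligned to ``kept``.
    """

    kept: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X[:, self.kept] - self.means) / self.sds


def standardize_features(X: np.ndarray) -> tuple[np.ndarray, Standardizer]:
    """Drop zero-variance columns and z-score the rest (sample SD).

    Returns the standardized matrix and the fitted parameters; on the
    fitting data every kept column has mean 0 and sample SD 1.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two rows to standardize")
    sds = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(sds > 0)
    if kept.size == 0:
        raise ValueError("all features have zero variance")
    means = X[:, kept].mean(axis=0)
    scaler = Standardizer(kept=kept, means=means, sds=sds[kept])
    return scaler.transform(X), scaler


def select_top_correlated(
    X: np.ndarray, y: np.ndarray, fraction: float = 0.05
) -> np.ndarray:
    """Indices of the ceil(fraction * F) features most |Pearson|-correlated
    with the target, in decreasing |r| order; ties broken by lower index.
    Constant features get r = 0."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-d with at least one feature")
    if np.ptp(y) == 0:
        raise ValueError("target has zero variance")
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    x_norm = np.linalg.norm(Xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (x_norm * np.linalg.norm(yc))
    abs_r = np.nan_to_num(np.abs(r), nan=0.0)
    k = math.ceil(fraction * X.shape[1])
    order = np.argsort(-abs_r, kind="stable")  # stable => ties keep lower index
    return order[:k]


# ---------------------------------------------------------------------------
# lasso with cross-validated penalty


def lambda_grid(
    X: np.ndarray, y: np.ndarray, n_lambdas: int = 100, min_ratio: float = 1e-4
) -> np.ndarray:
    """Descending log-spaced penalty grid from lambda_max (smallest penalty
    at which every coefficient is zero) down to lambda_max * min_ratio."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    lam_max = np.max(np.abs(Xc.T @ yc)) / n
    if lam_max <= 0:
        raise ValueError("target is uncorrelated with every feature")
    return np.logspace(np.log10(lam_max), np.log10(lam_max * min_ratio), n_lambdas)


@dataclass
class LassoFit:
    """Result of a cross-validated lasso fit on a fixed design."""

    coefficients: np.ndarray
    intercept: float
    lambda_min: float
    grid: np.ndarray
    cv_mse: np.ndarray  # mean held-out MSE per grid value


def fit_lasso(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> LassoFit:
    """Fit the lasso with lambda chosen by k-fold CV at minimum mean MSE.

    The regularization path is solved per fold over the shared descending
    grid (warm-started coordinate descent); the final coefficients are refit
    on all rows at lambda_min. Among tied MSE minima the largest lambda
    (sparsest model) wins, matching the descending-grid convention.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} rows, got {n}")
    if grid is None:
        grid = lambda_grid(X, y)
    grid = np.asarray(grid, dtype=float)

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    sse = np.zeros(grid.size)
    for train_idx, test_idx in kf.split(X):
        Xt, yt = X[train_idx], y[train_idx]
        xm, ym = Xt.mean(axis=0), yt.mean()
        alphas, coefs, _ = lasso_path(Xt - xm, yt - ym, alphas=grid)
        # lasso_path returns alphas in descending order; align to our grid
        order = np.argsort(-grid, kind="stable")
        pred = (X[test_idx] - xm) @ coefs + ym  # (n_test, n_alphas)
        fold_sse = ((pred - y[test_idx][:, None]) ** 2).sum(axis=0)
        aligned = np.empty_like(fold_sse)
        aligned[order] = fold_sse
        sse += aligned
    cv_mse = sse / n

    best = int(np.argmin(cv_mse))
    lam = float(grid[best])
    final = Lasso(alpha=lam, max_iter=50_000)
    final.fit(X, y)
    return LassoFit(
        coefficients=final.coef_.copy(),
        intercept=float(final.intercept_),
        lambda_min=lam,
        grid=grid,
        cv_mse=cv_mse,
    )


# ---------------------------------------------------------------------------
# the full per-tissue model


@dataclass
class QualityModel:
    """A fitted tissue-specific quality predictor.

    ``selected_features`` are indices into the original embedding feature
    space; ``feature_means``/``feature_sds`` are the training z-scoring
    parameters aligned to the selected features, and ``coefficients`` is the
    L1-sparse weight vector over them. ``alpha`` = 1 records that the
    penalty is pure L1.
    """

    tissue: str
    target: str
    feature_means: np.ndarray
    feature_sds: np.ndarray
    selected_features: np.ndarray
    coefficients: np.ndarray
    intercept: float
    lambda_: float
    alpha: float = 1.0
    n_training_slides: int = 0
    fold_correlations: list[float] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X[:, self.selected_features] - self.feature_means) / self.feature_sds
        return Z @ self.coefficients + self.intercept


def train_quality_model(
    X: np.ndarray,
    y: np.ndarray,
    tissue: str = "",
    target: str = "rin",
    n_folds: int = 5,
    seed: int = 0,
    top_fraction: float = 0.05,
) -> QualityModel:
    """Standardize, screen the top correlated features, and fit the lasso.

    All three steps are fit on the supplied rows only, so calling this
    inside a CV fold keeps held-out data untouched. A constant target
    yields the degenerate intercept-only model (infinite penalty kills all
    coefficients) rather than an error, so small tissues with no label
    spread still produce a usable predictor.
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        return QualityModel(
            tissue=tissue, target=target,
            feature_means=np.empty(0), feature_sds=np.empty(0),
            selected_features=np.empty(0, dtype=int), coefficients=np.empty(0),
            intercept=float(y.mean()), lambda_=float("inf"),
            n_training_slides=X.shape[0],
        )
    Xz, scaler = standardize_features(X)
    sel_local = select_top_correlated(Xz, y, fraction=top_fraction)
    fit = fit_lasso(Xz[:, sel_local], y, n_folds=n_folds, seed=seed)
    return QualityModel(
        tissue=tissue,
        target=target,
        feature_means=scaler.means[sel_local],
        feature_sds=scaler.sds[sel_local],
        selected_features=scaler.kept[sel_local],
        coefficients=fit.coefficients,
        intercept=fit.intercept,
        lambda_=fit.lambda_min,
        n_training_slides=X.shape[0],
    )


@dataclass
class FoldResult:
    """Held-out predictions of one cross-validation fold."""

    fold_index: int
    held_out_slide_ids: list[str]
    predictions: np.ndarray
    pearson: float
    model: QualityModel


def _target_vector(records: Sequence[SlideRecord], target: str) -> np.ndarray:
    return np.array(
        [np.nan if r.get_target(target) is None else float(r.get_target(target))
         for r in records]
    )


def cross_validate_tissue(
    records: Sequence[SlideRecord],
    X: np.ndarray,
    target: str,
    n_folds: int = 5,
    seed: int = 0,
    top_fraction: float = 0.05,
    stratify: bool = False,
) -> tuple[list[FoldResult], float, float]:
    """Pooled k-fold cross-validation of a tissue's quality model.

    Within each fold, standardization, top-correlated screening and the
    lambda search are all refit on that fold's training rows only. Held-out
    predictions are pooled across folds (one prediction per slide) and
    summarized by pooled Pearson R and RMSE. With ``stratify`` the fold
    assignment is stratified on the quartile-binned target.
    """
    y_all = _target_vector(records, target)
    labeled = np.flatnonzero(np.isfinite(y_all))
    if labeled.size == 0:
        raise ValueError(f"target {target!r} missing for all slides")
    if labeled.size < n_folds:
        raise ValueError(f"need >= {n_folds} labeled slides, got {labeled.size}")
    X = np.asarray(X, dtype=float)
    Xl, yl = X[labeled], y_all[labeled]

    if stratify:
        bins = _rin_quartile_bins(yl)
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(Xl, bins)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(Xl)

    fold_results: list[FoldResult] = []
    pooled_pred = np.full(labeled.size, np.nan)
    for fold_index, (tr, te) in enumerate(splits):
        model = train_quality_model(
            Xl[tr], yl[tr], target=target, n_folds=n_folds,
            seed=seed + fold_index, top_fraction=top_fraction,
        )
        pred = model.predict(Xl[te])
        pooled_pred[te] = pred
        fold_results.append(
            FoldResult(
                fold_index=fold_index,
                held_out_slide_ids=[records[labeled[i]].slide_id for i in te],
                predictions=pred,
                pearson=pearson_r(pred, yl[te]),
                model=model,
            )
        )
    assert np.isfinite(pooled_pred).all(), "folds must partition the slides"
    return fold_results, pearson_r(pooled_pred, yl), rmse(pooled_pred, yl)


def train_final_and_test(
    train_records: Sequence[SlideRecord],
    X_train: np.ndarray,
    test_records: Sequence[SlideRecord],
    X_test: np.ndarray,
    target: str,
    tissue: str = "",
    n_folds: int = 5,
    seed: int = 0,
    top_fraction: float = 0.05,
) -> tuple[QualityModel, float, float]:
    """Train on the full training split, evaluate once on the held-out test set.

    Every fitting decision (z-scoring, feature screening, lambda) derives
    from the training split only; test Pearson R and RMSE are computed on
    labeled test slides.
    """
    overlap = {r.slide_id for r in train_records} & {r.slide_id for r in test_records}
    if overlap:
        raise ValueError(f"train and test splits overlap: {sorted(overlap)[:5]}")
    y_tr = _target_vector(train_records, target)
    mask_tr = np.isfinite(y_tr)
    model = train_quality_model(
        np.asarray(X_train, dtype=float)[mask_tr], y_tr[mask_tr],
        tissue=tissue, target=target, n_folds=n_folds, seed=seed,
        top_fraction=top_fraction,
    )
    y_te = _target_vector(test_records, target)
    mask_te = np.isfinite(y_te)
    pred = model.predict(np.asarray(X_test, dtype=float)[mask_te])
    return model, pearson_r(pred, y_te[mask_te]), rmse(pred, y_te[mask_te])


def autolysis_class_accuracy(predictions: np.ndarray, observed: np.ndarray) -> float:
    """Fraction of continuous autolysis predictions that round (and clip to
    the 0-3 scale) to the observed ordinal class."""
    predictions = np.asarray(predictions, dtype=float)
    observed = np.asarray(observed)
    if predictions.shape != observed.shape:
        raise ValueError("predictions and observed must have the same length")
    classes = np.clip(np.rint(predictions), 0, 3).astype(int)
    return float(np.mean(classes == observed.astype(int)))
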