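"""Descriptive and diagnostic analyses around the quality models.

Covers: variance explained by technical confounders, the per-tissue
RIN-autolysis (Spearman) coupling, cross-tissue feature-importance/sharing,
fold-stability via the coefficient of variation, and the
preservation-percentile robustness curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .tissue_models import QualityModel, SlideRecord, pearson_r

__all__ = [
    "VarianceReport",
    "StabilityReport",
    "variance_explained",
    "rin_autolysis_correlation",
    "significance_stars",
    "feature_importance_matrix",
    "hierarchical_cluster",
    "stability_cv",
    "preservation_percentile",
]

@dataclass
class VarianceReport:
    """Fraction of target variance explained by each covariate, assessed
    independently (univariate R^2 per covariate; fractions need not sum
    to one). Covariates entirely missing are absent from ``fractions``."""

    target: str
    fractions: dict[str, float]
    method: str = "univariate"


def _design_matrix(values: np.ndarray, categorical: bool) -> np.ndarray:
    if categorical:
        levels = pd.unique(values)
        return (values[:, None] == levels[None, :]).astype(float)
    return np.column_stack([np.ones(values.size), values.astype(float)])


def _r_squared(y: np.ndarray, design: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return float("nan")
    return 1.0 - float((resid**2).sum()) / tss


def variance_explained(
    records: Sequence[SlideRecord],
    target: str,
    covariates: Sequence[str] = ("tissue", "hardy", "other_metric", "age", "sex"),
    method: str = "univariate",
) -> VarianceReport:
    """Variance decomposition of a quality metric over technical covariates.

    For each covariate independently, the explained fraction is the R^2 of
    a linear model of the target on that covariate alone (categoricals
    one-hot encoded; rows with the covariate missing dropped pairwise).
    ``other_metric`` denotes the complementary quality score (autolysis for
    the RIN target and vice versa). ``method='joint'`` instead reports each
    covariate's incremental R^2 over all the others in a joint model
    (type-II-style attribution).
    """
    y_all = np.array(
        [np.nan if r.get_target(target) is None else float(r.get_target(target))
         for r in records]
    )
    if np.unique(y_all[np.isfinite(y_all)]).size < 2:
        raise ValueError("target needs at least two distinct values")
    other = "autolysis" if target == "rin" else "rin"

    def _covariate_values(name: str):
        attr = other if name == "other_metric" else name
        raw = [getattr(r, attr) for r in records]
        present = np.array([v is not None for v in raw])
        vals = np.array([v if p else None for v, p in zip(raw, present)], dtype=object)
        # the complementary quality metric enters numerically; tissue/hardy/sex one-hot
        categorical = attr in {"tissue", "hardy", "sex"}
        return vals, present, categorical

    if method not in ("univariate", "joint"):
        raise ValueError("method must be 'univariate' or 'joint'")

    fractions: dict[str, float] = {}
    if method == "univariate":
        for name in covariates:
            vals, present, categorical = _covariate_values(name)
            mask = present & np.isfinite(y_all)
            if mask.sum() < 3:
                continue  # covariate (effectively) missing: absent, not zero
            design = _design_matrix(np.array(list(vals[mask])), categorical)
            fractions[name] = max(0.0, _r_squared(y_all[mask], design))
        return VarianceReport(target=target, fractions=fractions, method=method)

    # joint: incremental R^2 of each covariate over the others
    usable, designs = [], {}
    mask = np.isfinite(y_all)
    for name in covariates:
        vals, present, categorical = _covariate_values(name)
        if present.sum() < 3:
            continue
        usable.append(name)
        mask &= present
    for name in usable:
        vals, _, categorical = _covariate_values(name)
        designs[name] = _design_matrix(np.array(list(vals[mask])), categorical)
    y = y_all[mask]
    ones = np.ones((y.size, 1))
    full = np.hstack([ones] + [designs[n] for n in usable])
    r2_full = _r_squared(y, full)
    for name in usable:
        reduced = np.hstack([ones] + [designs[n] for n in usable if n != name])
        fractions[name] = max(0.0, r2_full - _r_squared(y, reduced))
    return VarianceReport(target=target, fractions=fractions, method=method)


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star label (ns for p >= 0.05)."""
    if not np.isfinite(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def rin_autolysis_correlation(
    records: Sequence[SlideRecord], min_pairs: int = 4
) -> pd.DataFrame:
    """Per-tissue Spearman correlation between RIN and autolysis.

    Uses average ranks for ties and a two-sided p-value; tissues with fewer
    than ``min_pairs`` complete pairs, or with an all-tied variable (rho
    undefined), report missing values. Returns a DataFrame with columns
    tissue, n, rho, p_value, stars.
    """
    rows = []
    by_tissue: dict[str, list[tuple[float, float]]] = {}
    for r in records:
        if r.rin is not None and r.autolysis is not None:
            by_tissue.setdefault(r.tissue, []).append((float(r.rin), float(r.autolysis)))
    for tissue in sorted(by_tissue):
        pairs = by_tissue[tissue]
        n = len(pairs)
        rho = p = np.nan
        if n >= min_pairs:
            a = np.array([x for x, _ in pairs])
            b = np.array([y for _, y in pairs])
            if np.ptp(a) > 0 and np.ptp(b) > 0:
                res = stats.spearmanr(a, b)
                rho, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {"tissue": tissue, "n": n, "rho": rho, "p_value": p,
             "stars": significance_stars(p) if np.isfinite(p) else ""}
        )
    return pd.DataFrame(rows, columns=["tissue", "n", "rho", "p_value", "stars"])


def feature_importance_matrix(
    models: Mapping[str, Mapping[str, QualityModel]],
    top_n: int = 20,
) -> tuple[dict[str, pd.DataFrame], dict[str, list[int]], set[int]]:
    """Cross-tissue feature selection frequencies and the shared top set.

    ``models`` maps target -> tissue -> fitted model. For each target, a
    features x tissues 0/1 matrix marks whether the tissue's model assigns
    a nonzero coefficient to the feature; a feature's frequency is its row
    sum. Returns the per-target matrices (rows restricted to ever-selected
    features), the global top-``top_n`` features per target (ties toward
    the lower feature index) and the overlap between the targets' top sets.
    """
    matrices: dict[str, pd.DataFrame] = {}
    tops: dict[str, list[int]] = {}
    for target, per_tissue in models.items():
        counts: dict[int, dict[str, int]] = {}
        tissues = sorted(per_tissue)
        for tissue in tissues:
            model = per_tissue[tissue]
            nonzero = model.selected_features[model.coefficients != 0]
            for f in nonzero:
                counts.setdefault(int(f), {})[tissue] = 1
        feats = sorted(counts)
        mat = pd.DataFrame(0, index=feats, columns=tissues, dtype=int)
        for f, row in counts.items():
            for tissue in row:
                mat.loc[f, tissue] = 1
        matrices[target] = mat
        freq = mat.sum(axis=1)
        order = sorted(feats, key=lambda f: (-freq[f], f))
        tops[target] = order[:top_n]
    targets = list(models)
    overlap: set[int] = (
        set(tops[targets[0]]).intersection(*(set(tops[t]) for t in targets[1:]))
        if targets else set()
    )
    return matrices, tops, overlap


def hierarchical_cluster(matrix: pd.DataFrame | np.ndarray):
    """Complete-linkage Euclidean clustering of rows and columns.

    Returns ``(row_order, col_order, row_linkage, col_linkage)`` where the
    orders are leaf orders of the respective dendrograms.
    """
    values = matrix.values if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    if np.isnan(values).any():
        raise ValueError("matrix contains NaN entries")
    row_link = linkage(values, method="complete", metric="euclidean")
    col_link = linkage(values.T, method="complete", metric="euclidean")
    return leaves_list(row_link), leaves_list(col_link), row_link, col_link


@dataclass
class StabilityReport:
    """Fold-to-fold stability of a tissue model's correlation."""

    tissue: str
    fold_correlations: list[float]
    mean: float
    sd: float
    cv: float
    label: str


def stability_cv(
    fold_correlations: Sequence[float], tissue: str = ""
) -> StabilityReport:
    """Coefficient of variation of per-fold correlations, CV = sigma / mu.

    mu is the mean and sigma the sample SD across folds. CV < 0.2 is
    labeled stable, CV > 0.5 unstable, otherwise intermediate. A
    non-positive mean makes the ratio meaningless: CV is reported as NaN
    and the model labeled unstable, with a warning.
    """
    vals = np.asarray(fold_correlations, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two folds")
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=1))
    if mu <= 0:
        warnings.warn(
            f"mean fold correlation {mu:.3f} <= 0: CV undefined, labeling unstable",
            stacklevel=2,
        )
        return StabilityReport(tissue, list(vals), mu, sigma, float("nan"), "unstable")
    cv = sigma / mu
    label = "stable" if cv < 0.2 else ("unstable" if cv > 0.5 else "intermediate")
    return StabilityReport(tissue, list(vals), mu, sigma, cv, label)


def preservation_percentile(
    predicted: np.ndarray,
    observed: np.ndarray,
    percentile_steps: Sequence[float] = (100, 90, 80, 70, 60, 50, 40, 30),
    min_subset: int = 5,
) -> pd.DataFrame:
    """Prediction-observation correlation as top-quality samples are removed.

    For each preservation percentile q, samples whose observed value is at
    or below the q-th percentile of the observed distribution are retained
    (q = 100 keeps everyone and reproduces the full-sample R exactly) and
    the Pearson correlation is recomputed on the subset. Subsets smaller
    than ``min_subset`` or with a constant observed value report NaN.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have the same length")
    if predicted.size < 10:
        raise ValueError("need at least 10 pairs")
    rows = []
    for q in percentile_steps:
        cutoff = np.percentile(observed, q)
        keep = observed <= cutoff
        n = int(keep.sum())
        r = np.nan
        if n >= min_subset and np.ptp(observed[keep]) > 0:
            r = pearson_r(predicted[keep], observed[keep])
        rows.append({"percentile": float(q), "n": n, "pearson_r": r})
    return pd.DataFrame(rows, columns=["percentile", "n", "pearson_r"])
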