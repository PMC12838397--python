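"""Confounder variance, RIN-autolysis coupling, feature sharing, stability,
and preservation-percentile analyses."""

import numpy as np
import pandas as pd
import pytest

from pathqc.analysis import (
    feature_importance_matrix,
    hierarchical_cluster,
    preservation_percentile,
    rin_autolysis_correlation,
    significance_stars,
    stability_cv,
    variance_explained,
)
from pathqc.tissue_models import QualityModel, SlideRecord, pearson_r


def _rec(i, tissue="t0", **kw):
    return SlideRecord(f"s{i}", f"d{i}", tissue, **kw)


class TestVarianceExplained:
    def test_tissue_lookup_target_fully_explained(self, rng):
        means = {"a": 3.0, "b": 6.0, "c": 9.0}
        records = [_rec(i, tissue=t, rin=means[t])
                   for i, t in enumerate(rng.choice(list(means), 90))]
        rep = variance_explained(records, "rin", covariates=("tissue",))
        assert rep.fractions["tissue"] == pytest.approx(1.0)

    def test_independent_covariate_explains_nothing(self, rng):
        n = 1000
        rins = rng.uniform(1, 10, n)
        ages = rng.permutation(rng.uniform(20, 70, n))
        records = [_rec(i, rin=float(rins[i]), age=float(ages[i])) for i in range(n)]
        rep = variance_explained(records, "rin", covariates=("age",))
        assert rep.fractions["age"] <= 0.02  # null R^2 ~ (k-1)/(n-1)

    def test_two_group_hand_decomposition(self):
        # groups {0: (1,3), 1: (5,7)}: between-SS 8 of total 10 -> R^2 = 0.8
        records = [
            _rec(0, tissue="g0", rin=1.0), _rec(1, tissue="g0", rin=3.0),
            _rec(2, tissue="g1", rin=5.0), _rec(3, tissue="g1", rin=7.0),
        ]
        rep = variance_explained(records, "rin", covariates=("tissue",))
        assert rep.fractions["tissue"] == pytest.approx(0.8)

    def test_numeric_covariate_affine_invariance(self, rng):
        n = 200
        ages = rng.uniform(20, 70, n)
        rins = 2 + 0.05 * ages + rng.normal(0, 1, n)
        recs_raw = [_rec(i, rin=float(rins[i]), age=float(ages[i])) for i in range(n)]
        recs_aff = [_rec(i, rin=float(rins[i]), age=float(3.5 * ages[i] - 40))
                    for i in range(n)]
        f_raw = variance_explained(recs_raw, "rin", covariates=("age",)).fractions["age"]
        f_aff = variance_explained(recs_aff, "rin", covariates=("age",)).fractions["age"]
        assert f_raw == pytest.approx(f_aff, abs=1e-10)

    def test_missing_covariate_reported_absent(self):
        records = [_rec(i, rin=float(i % 7 + 2)) for i in range(30)]
        rep = variance_explained(records, "rin", covariates=("age", "sex"))
        assert rep.fractions == {}

    def test_other_metric_covariate_and_joint_method(self, rng):
        records = [_rec(i, rin=float(rng.uniform(2, 9)),
                        autolysis=int(rng.integers(0, 4)),
                        age=float(rng.uniform(20, 70))) for i in range(150)]
        uni = variance_explained(records, "rin", covariates=("other_metric", "age"))
        joint = variance_explained(records, "rin", covariates=("other_metric", "age"),
                                   method="joint")
        assert set(uni.fractions) == {"other_metric", "age"}
        assert set(joint.fractions) == {"other_metric", "age"}
        assert all(0 <= v <= 1 for v in uni.fractions.values())


class TestRinAutolysisCorrelation:
    def test_perfect_monotone_decreasing(self):
        records = [_rec(i, rin=float(10 - 2 * i), autolysis=i) for i in range(4)]
        out = rin_autolysis_correlation(records)
        assert out.loc[0, "rho"] == pytest.approx(-1.0)

    def test_printed_rank_example(self):
        # ranks (1,2,3,4) vs (2,1,4,3): rho = 1 - 6*4/(4*15) = 0.6
        records = [_rec(i, rin=float(r), autolysis=a)
                   for i, (r, a) in enumerate(zip([1, 2, 3, 4], [1, 0, 3, 2]))]
        out = rin_autolysis_correlation(records)
        assert out.loc[0, "rho"] == pytest.approx(0.6)

    def test_star_mapping(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.05) == "ns"  # boundary: ns means p >= 0.05

    def test_all_tied_variable_reported_missing(self):
        records = [_rec(i, rin=5.0, autolysis=i % 4) for i in range(12)]
        out = rin_autolysis_correlation(records)
        assert np.isnan(out.loc[0, "rho"])

    def test_too_few_pairs_reported_missing(self):
        records = [_rec(i, rin=float(i + 1), autolysis=i % 4) for i in range(3)]
        out = rin_autolysis_correlation(records)
        assert np.isnan(out.loc[0, "rho"]) and out.loc[0, "n"] == 3


def _sparse_model(tissue, target, features, coefs):
    features = np.asarray(features)
    coefs = np.asarray(coefs, float)
    return QualityModel(
        tissue=tissue, target=target,
        feature_means=np.zeros(features.size), feature_sds=np.ones(features.size),
        selected_features=features, coefficients=coefs, intercept=0.0, lambda_=0.1,
    )


class TestFeatureImportance:
    def test_frequencies_match_counting_loop(self, rng):
        tissues = [f"t{i}" for i in range(6)]
        models = {"rin": {}, "autolysis": {}}
        truth_counts = {"rin": {}, "autolysis": {}}
        for target in models:
            for t in tissues:
                feats = rng.choice(50, size=8, replace=False)
                coefs = rng.normal(size=8)
                coefs[rng.random(8) < 0.3] = 0.0
                models[target][t] = _sparse_model(t, target, feats, coefs)
                for f, c in zip(feats, coefs):
                    if c != 0:
                        truth_counts[target][int(f)] = truth_counts[target].get(int(f), 0) + 1
        matrices, tops, overlap = feature_importance_matrix(models, top_n=10)
        for target in models:
            freq = matrices[target].sum(axis=1).to_dict()
            assert freq == truth_counts[target]

    def test_universal_feature_ranks_first(self):
        models = {"rin": {f"t{i}": _sparse_model(f"t{i}", "rin", [4, 10 + i], [1.0, 0.5])
                          for i in range(5)},
                  "autolysis": {f"t{i}": _sparse_model(f"t{i}", "autolysis", [4], [2.0])
                                for i in range(5)}}
        matrices, tops, overlap = feature_importance_matrix(models, top_n=3)
        assert tops["rin"][0] == 4 and tops["autolysis"][0] == 4
        assert 4 in overlap

    def test_identical_models_give_full_overlap(self):
        per_tissue = {f"t{i}": _sparse_model(f"t{i}", "rin", [1, 2, 3], [1, -1, 2])
                      for i in range(4)}
        models = {"rin": per_tissue, "autolysis": per_tissue}
        _, tops, overlap = feature_importance_matrix(models, top_n=3)
        assert overlap == set(tops["rin"]) and len(overlap) == 3


class TestHierarchicalCluster:
    def test_identical_rows_merge_first_at_zero(self):
        m = np.array([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
        _, _, row_link, _ = hierarchical_cluster(m)
        assert row_link[0, 2] == 0.0
        assert {int(row_link[0, 0]), int(row_link[0, 1])} == {0, 1}

    def test_three_point_line_complete_linkage(self):
        m = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0]])
        _, _, row_link, _ = hierarchical_cluster(m)
        assert row_link[0, 2] == pytest.approx(1.0)
        assert row_link[1, 2] == pytest.approx(10.0)  # complete: farthest pair

    def test_row_permutation_equivariance(self, rng):
        m = rng.normal(size=(6, 4))
        _, _, link_a, _ = hierarchical_cluster(m)
        perm = rng.permutation(6)
        _, _, link_b, _ = hierarchical_cluster(m[perm])
        np.testing.assert_allclose(sorted(link_a[:, 2]), sorted(link_b[:, 2]))

    def test_nan_rejected(self):
        m = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError):
            hierarchical_cluster(m)


class TestStabilityCV:
    def test_constant_folds_are_stable(self):
        rep = stability_cv([0.5] * 5)
        assert rep.cv == 0.0 and rep.label == "stable"

    def test_hand_computed_unstable_example(self):
        rep = stability_cv([0.1, 0.6, 0.2])
        assert rep.mean == pytest.approx(0.3)
        assert rep.sd == pytest.approx(0.26458, abs=1e-4)
        assert rep.cv == pytest.approx(0.8819, abs=1e-3)
        assert rep.label == "unstable"

    def test_label_boundaries(self):
        assert stability_cv([1.0, 1.1]).label == "stable"  # CV ~ 0.067
        assert stability_cv([0.4, 0.8]).label == "intermediate"  # CV ~ 0.47
        assert stability_cv([0.1, 0.9]).label == "unstable"  # CV ~ 1.13

    def test_scale_invariance(self):
        a = stability_cv([0.2, 0.3, 0.4])
        b = stability_cv([0.4, 0.6, 0.8])
        assert a.cv == pytest.approx(b.cv)
        assert a.label == b.label

    def test_non_positive_mean_flags_unstable(self):
        with pytest.warns(UserWarning):
            rep = stability_cv([-0.2, 0.1])
        assert rep.label == "unstable" and np.isnan(rep.cv)


class TestPreservationPercentile:
    def test_identity_predictions_stay_perfect(self):
        obs = np.linspace(1, 10, 40)
        out = preservation_percentile(obs, obs)
        assert np.allclose(out["pearson_r"].dropna(), 1.0)

    def test_full_percentile_reproduces_pooled_r_exactly(self, rng):
        obs = rng.uniform(1, 10, 200)
        pred = obs + rng.normal(0, 1, 200)
        out = preservation_percentile(pred, obs, percentile_steps=[100])
        assert out.loc[0, "pearson_r"] == pearson_r(pred, obs)  # bit-for-bit

    def test_truncated_correlation_matches_large_sample_oracle(self):
        # construction: obs = latent + noise, pred = latent; the "analytic"
        # reference is the same construction evaluated at very large n
        def simulate(n, seed):
            g = np.random.default_rng(seed)
            latent = g.normal(0, 1, n)
            obs = latent + g.normal(0, 1, n)
            return latent, obs

        big_latent, big_obs = simulate(400_000, 0)
        keep = big_obs <= np.percentile(big_obs, 50)
        oracle = np.corrcoef(big_latent[keep], big_obs[keep])[0, 1]

        latent, obs = simulate(5000, 1)
        out = preservation_percentile(latent, obs, percentile_steps=[50])
        assert out.loc[0, "pearson_r"] == pytest.approx(oracle, abs=0.05)

    def test_small_subsets_reported_missing(self, rng):
        obs = np.concatenate([np.full(3, 1.0), rng.uniform(5, 10, 17)])
        pred = rng.normal(size=20)
        out = preservation_percentile(pred, obs, percentile_steps=[10])
        assert np.isnan(out.loc[0, "pearson_r"])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            preservation_percentile(np.ones(5), np.ones(5))
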