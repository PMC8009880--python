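import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import neostrat as ns
from neostrat.deconfounder import ProbabilisticPCA
from neostrat.errors import AnalysisError, DataError
from neostrat.simulations import (deconfounding_bias, effect_recovery,
                                  simulate_association_design,
                                  simulate_confounded_design, type_i_error)


@pytest.fixture(scope="module")
def study_labels(study_cohort, study_model):
    cohort, _, _ = study_cohort
    return study_model.predict(cohort.matrix)


class TestBuildDesign:
    def _pick_clusters(self, labels):
        sizes = pd.Series(labels).value_counts()
        return sizes.index[0], sizes.index[1]

    def test_eligibility_excludes_deaths_and_pre36_discharges(
            self, study_cohort, study_labels):
        cohort, _, _ = study_cohort
        c1, c0 = self._pick_clusters(study_labels)
        design = ns.build_design(cohort.infants, study_labels, c1, c0,
                                 "w36_zscore")
        eligible = cohort.infants.loc[design.covariates.index]
        assert (eligible["mortality"] == 0).all()
        assert (eligible["in_care_at_36w"] == 1).all()

    def test_covariates_centred(self, study_cohort, study_labels):
        cohort, _, _ = study_cohort
        c1, c0 = self._pick_clusters(study_labels)
        design = ns.build_design(cohort.infants, study_labels, c1, c0,
                                 "w36_zscore")
        np.testing.assert_allclose(design.covariates.mean(axis=0), 0.0,
                                   atol=1e-10)

    def test_london_is_reference_region(self, study_cohort, study_labels):
        cohort, _, _ = study_cohort
        c1, c0 = self._pick_clusters(study_labels)
        design = ns.build_design(cohort.infants, study_labels, c1, c0,
                                 "w36_zscore")
        assert set(["Midlands", "North", "South"]) <= set(design.covariates)
        assert "London" not in design.covariates.columns

    def test_same_cluster_rejected(self, study_cohort, study_labels):
        cohort, _, _ = study_cohort
        with pytest.raises(AnalysisError):
            ns.build_design(cohort.infants, study_labels, 1, 1, "w36_zscore")

    def test_empty_arm_rejected(self, study_cohort, study_labels):
        cohort, _, _ = study_cohort
        c1, _ = self._pick_clusters(study_labels)
        missing_cluster = max(study_labels) + 7
        with pytest.raises(AnalysisError):
            ns.build_design(cohort.infants, study_labels, c1, missing_cluster,
                            "w36_zscore")

    def test_binary_outcome_selects_logistic_family(self, study_cohort,
                                                    study_labels):
        cohort, _, _ = study_cohort
        c1, c0 = self._pick_clusters(study_labels)
        design = ns.build_design(cohort.infants, study_labels, c1, c0, "bpd")
        assert design.family == "logistic"
        assert set(design.outcome.unique()) <= {0.0, 1.0}


class TestProbabilisticPCA:
    def test_exact_low_rank_data_has_zero_noise(self, rng):
        W = rng.normal(size=(6, 3))
        Z = rng.normal(size=(200, 3))
        X = Z @ W.T
        model = ProbabilisticPCA(3).fit(X)
        assert model.noise_variance_ == pytest.approx(0.0, abs=1e-20)

    def test_log_likelihood_matches_eigendecomposition_oracle(self, rng):
        """Closed-form check on a small matrix: build the PPCA covariance
        directly from the eigen-decomposition and evaluate the Gaussian."""
        X = np.array([[1.0, 2.0, 0.5, -1.0],
                      [0.0, 1.0, 1.5, 2.0],
                      [2.0, -1.0, 0.0, 0.5],
                      [1.5, 0.5, -0.5, 1.0],
                      [-1.0, 1.5, 2.5, 0.0],
                      [0.5, 0.0, 1.0, -0.5]])
        k = 2
        model = ProbabilisticPCA(k).fit(X)
        mu = X.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(X.T, bias=True))
        evals, evecs = evals[::-1], evecs[:, ::-1]
        sigma2 = evals[k:].mean()
        W = evecs[:, :k] * np.sqrt(evals[:k] - sigma2)
        C = W @ W.T + sigma2 * np.eye(4)
        oracle = multivariate_normal(mu, C).logpdf(X)
        np.testing.assert_allclose(model.score_samples(X), oracle, atol=1e-10)

    def test_matches_sklearn_pca_probabilistic_view(self, rng):
        """Independent cross-check: scikit-learn's PCA implements the same
        ML solution (up to its n-1 covariance convention)."""
        from sklearn.decomposition import PCA

        X = rng.normal(size=(400, 6)) @ rng.normal(size=(6, 6)) * 0.4
        mine = ProbabilisticPCA(3).fit(X)
        theirs = PCA(3).fit(X)
        n = len(X)
        assert mine.noise_variance_ == pytest.approx(
            theirs.noise_variance_ * (n - 1) / n, rel=1e-9)
        np.testing.assert_allclose(mine.get_covariance(),
                                   theirs.get_covariance() * (n - 1) / n,
                                   atol=1e-10)

    def test_k_at_or_above_rank_rejected(self, rng):
        Z = rng.normal(size=(50, 2))
        X = Z @ rng.normal(size=(2, 5))          # rank 2
        with pytest.raises(DataError):
            ProbabilisticPCA(3).fit(X)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(DataError):
            ProbabilisticPCA(3).fit(rng.normal(size=(4, 6)))

    def test_transform_recovers_planted_latents_up_to_rotation(self, rng):
        W = np.array([[2.0, 0.0], [0.0, 1.5], [1.0, 1.0], [0.5, -0.5]])
        Z = rng.normal(size=(3000, 2))
        X = Z @ W.T + rng.normal(0, 0.1, (3000, 4))
        model = ProbabilisticPCA(2).fit(X)
        latents = model.transform(X)
        # latents span the planted factor space: regression recovers Z well
        resid = Z - latents @ np.linalg.lstsq(latents, Z, rcond=None)[0]
        assert resid.var() / Z.var() < 0.05


class TestFitPPCA:
    def test_latents_cover_all_rows_and_split_is_seeded(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 6)))
        fit1 = ns.fit_ppca(X, k=3, seed=5, n_reps=5)
        fit2 = ns.fit_ppca(X, k=3, seed=5, n_reps=5)
        assert len(fit1.latents) == 200
        assert fit1.train_index.equals(fit2.train_index)
        assert len(fit1.train_index) == 160

    def test_ppc_calibrated_within_family(self):
        """Data truly generated by a k=3 PPCA model: the held-out PPC p-value
        averages near 1/2 over seeds."""
        rng = np.random.default_rng(7)
        W = rng.normal(size=(8, 3))
        ps = []
        for s in range(10):
            r = np.random.default_rng(100 + s)
            Z = r.normal(size=(1500, 3))
            X = pd.DataFrame(Z @ W.T + r.normal(0, 0.5, (1500, 8)))
            ps.append(ns.fit_ppca(X, k=3, seed=s, n_reps=60).ppc_pvalue)
        assert 0.3 <= np.mean(ps) <= 0.7


class TestAssociationRegression:
    def test_outcome_equal_to_covariate_recovered_exactly(self):
        design = simulate_association_design(n=500, effect=0.0, seed=0)
        design.outcome = design.covariates["bw_zscore"] \
            + design.covariates["bw_zscore"].mean()
        result = ns.association_regression(design)
        assert result.table.loc["bw_zscore", "coef"] == pytest.approx(1.0)
        assert result.fit_quality > 0.999

    def test_ci_and_p_are_consistent(self):
        design = simulate_association_design(n=400, effect=-0.4, seed=3)
        result = ns.association_regression(design)
        for _, row in result.table.iterrows():
            excludes_zero = row["ci_low"] > 0 or row["ci_high"] < 0
            assert (row["p"] < 0.05) == excludes_zero

    def test_logistic_coefficient_is_log_odds(self):
        rng = np.random.default_rng(4)
        n = 4000
        t = rng.binomial(1, 0.5, n).astype(float)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-0.5 + 1.2 * t)))).astype(float)
        idx = pd.RangeIndex(n)
        design = ns.DeconfounderDesign(
            covariates=pd.DataFrame(index=idx),
            treatment=pd.Series(t, index=idx, name="treatment"),
            outcome=pd.Series(y, index=idx), outcome_name="bpd",
            family="logistic", c1=1, c0=0)
        result = ns.association_regression(design)
        assert result.table.loc["Nutritional Treatment", "coef"] \
            == pytest.approx(1.2, abs=0.25)

    def test_perfect_separation_flagged_and_refit(self):
        n = 40
        t = np.repeat([0.0, 1.0], n // 2)
        idx = pd.RangeIndex(n)
        design = ns.DeconfounderDesign(
            covariates=pd.DataFrame(index=idx),
            treatment=pd.Series(t, index=idx, name="treatment"),
            outcome=pd.Series(t, index=idx), outcome_name="bpd",
            family="logistic", c1=1, c0=0)
        with pytest.warns(UserWarning):
            result = ns.association_regression(design)
        assert result.separation_flag
        assert np.isfinite(result.table["coef"]).all()

    def test_latents_leave_treatment_estimate_unchanged_when_collinear(self):
        """PPCA latents are affine in the covariates, so adding them to a
        regression already containing every covariate cannot move the
        treatment coefficient (the design span is unchanged)."""
        design = simulate_association_design(n=600, effect=-0.33, seed=9)
        factor = ns.fit_ppca(design.covariates, k=3, seed=9, n_reps=1)
        without = ns.association_regression(design)
        with_z = ns.association_regression(design, latents=factor.latents)
        assert with_z.table.loc["Nutritional Treatment", "coef"] \
            == pytest.approx(without.table.loc["Nutritional Treatment", "coef"],
                             abs=1e-8)


class TestRecoveryProperties:
    def test_effect_recovery_coverage(self):
        result = effect_recovery(n_replicates=40, seed=100)
        assert result["coverage"] >= 0.85

    def test_null_rejection_near_alpha(self):
        result = type_i_error(n_replicates=120, seed=200)
        assert 0.0 < result["rate"] <= 0.11

    def test_latent_augmentation_reduces_confounding_bias(self):
        result = deconfounding_bias(n_replicates=40, seed=300)
        assert result["median_abs_bias_augmented"] \
            < result["median_abs_bias_unaugmented"]
        assert result["median_abs_bias_unaugmented"] > 0.3

    def test_confounded_design_plants_real_confounding(self):
        design = simulate_confounded_design(n=2000, effect=0.0, seed=1)
        naive = ns.association_regression(design, include_covariates=False)
        assert abs(naive.table.loc["Nutritional Treatment", "coef"]) > 0.3


def test_end_to_end_deconfound_on_study_cohort(study_cohort, study_labels):
    """The planted between-archetype contrast on the 36-week weight z-score
    is recovered by the full design + factor model + regression path."""
    cohort, labels_true, truth = study_cohort
    sizes = pd.Series(study_labels).value_counts()
    c1, c0 = sizes.index[0], sizes.index[1]
    design, factor, result = ns.deconfound(cohort.infants, study_labels,
                                           c1, c0, "w36_zscore", seed=0)
    name1 = pd.Series(labels_true[study_labels == c1]).mode()[0]
    name0 = pd.Series(labels_true[study_labels == c0]).mode()[0]
    effects = {a.name: a.outcome_effects.get("w36_zscore", 0.0)
               for a in truth.archetypes}
    planted = effects[name1] - effects[name0]
    row = result.table.loc["Nutritional Treatment"]
    assert row["ci_low"] - 0.1 <= planted <= row["ci_high"] + 0.1
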