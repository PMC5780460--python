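"""Evaluation toolkit: sample splits, order sweeps, perturbation
robustness, null models, and spectral similarity."""

import numpy as np
import pytest

import spectralmap as sm


@pytest.fixture
def ar_series():
    S = sm.make_structural(sm.SyntheticSpec(n=20, density=0.3, seed=8))
    ts = sm.make_bold_series(S, 1200, 0.9, seed=3)
    return S, ts


class TestSplitTimeSeries:
    def test_sizes_disjoint_exhaustive(self, ar_series):
        _, ts = ar_series
        sp = sm.split_time_series(ts, seed=0)
        assert len(sp.in_indices) == 600 and len(sp.out_indices) == 600
        assert set(sp.in_indices) | set(sp.out_indices) == set(range(1200))
        assert not (set(sp.in_indices) & set(sp.out_indices))

    def test_deterministic(self, ar_series):
        _, ts = ar_series
        a, b = sm.split_time_series(ts, 5), sm.split_time_series(ts, 5)
        np.testing.assert_array_equal(a.in_indices, b.in_indices)
        np.testing.assert_array_equal(a.in_sample.values, b.in_sample.values)

    def test_identical_regions_give_all_ones(self, rng):
        base = rng.standard_normal(100)
        jitter = rng.standard_normal(100) * 1e-9  # avoid exact zero variance
        ts = sm.BoldSeries(np.vstack([base, base, base + jitter]))
        sp = sm.split_time_series(ts, 2)
        np.testing.assert_allclose(sp.in_sample.values, 1.0, atol=1e-6)
        np.testing.assert_allclose(sp.out_sample.values, 1.0, atol=1e-6)

    def test_pooled_halves_recover_full_matrix(self, ar_series):
        _, ts = ar_series
        sp = sm.split_time_series(ts, seed=1)
        pooled = np.concatenate([sp.in_indices, sp.out_indices])
        F_pooled = sm.correlation_matrix(sm.BoldSeries(ts.signals[:, np.sort(pooled)]))
        F_full = sm.correlation_matrix(ts)
        np.testing.assert_allclose(F_pooled.values, F_full.values, atol=1e-12)

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError, match="8"):
            sm.split_time_series(sm.BoldSeries(rng.standard_normal((3, 6))), 0)


class TestSweepOrder:
    def test_in_sample_non_decreasing(self, ar_series):
        S, ts = ar_series
        sp = sm.split_time_series(ts, 4)
        tab = sm.sweep_order(S, sp, range(1, 11))
        assert (np.diff(tab["ucorr_in"].to_numpy()) >= -1e-12).all()

    def test_recovery_data_saturates_at_true_order(self):
        spec = sm.SyntheticSpec(n=20, true_k=3, seed=13)
        S, F, _ = sm.make_planted_pair(spec)
        # wrap the exact functional matrix as both halves of a split
        sp = sm.SplitPair(
            in_sample=F, out_sample=F,
            in_indices=np.array([0]), out_indices=np.array([1]), seed=0,
        )
        tab = sm.sweep_order(S, sp, [1, 2, 3, 4, 5])
        sat = tab[tab.k >= 3]
        assert (np.abs(sat["ucorr_in"] - 1.0) <= 1e-8).all()
        assert tab[tab.k == 1]["ucorr_in"].iloc[0] < 1.0 - 1e-6

    def test_k0_flagged_nan(self, ar_series):
        S, ts = ar_series
        sp = sm.split_time_series(ts, 4)
        tab = sm.sweep_order(S, sp, [0, 1])
        assert np.isnan(tab[tab.k == 0]["ucorr_in"].iloc[0])
        assert np.isfinite(tab[tab.k == 1]["ucorr_in"].iloc[0])


class TestPerturbStructural:
    def test_zero_rho_exact(self, planted_pair):
        S, _, _ = planted_pair
        pert, spec = sm.perturb_structural(S, 0.0, seed=1)
        np.testing.assert_array_equal(pert.values, S.values)
        assert spec.rho == 0.0

    def test_support_preserved(self, planted_pair):
        S, _, _ = planted_pair
        pert, _ = sm.perturb_structural(S, 0.5, seed=2)
        np.testing.assert_array_equal(pert.values == 0, S.values == 0)

    def test_bounded_relative_change(self, planted_pair):
        S, _, _ = planted_pair
        rho = 0.1
        pert, spec = sm.perturb_structural(S, rho, seed=3)
        nz = S.values != 0
        rel = np.abs(pert.values[nz] / S.values[nz] - 1.0)
        assert rel.max() < rho
        assert np.abs(spec.delta).max() < rho
        np.testing.assert_array_equal(spec.delta, spec.delta.T)

    def test_negative_rho_rejected(self, planted_pair):
        S, _, _ = planted_pair
        with pytest.raises(ValueError, match="rho"):
            sm.perturb_structural(S, -0.1, seed=0)


class TestPerturbationQuality:
    def test_exact_one_at_zero(self, planted_pair):
        S, F, _ = planted_pair
        res = sm.fit_individual(S, F, 2)
        assert sm.perturbation_quality(res, S, 0.0, seed=0) == 1.0

    def test_median_monotone_in_rho(self):
        spec = sm.SyntheticSpec(n=25, true_k=3, seed=17)
        S, F, _ = sm.make_planted_pair(spec)
        res = sm.fit_individual(S, F, 3)
        rng = np.random.default_rng(0)
        meds = []
        for rho in (0.01, 0.05, 0.1, 0.2):
            q = [
                sm.perturbation_quality(res, S, rho, int(rng.integers(2**31)))
                for _ in range(50)
            ]
            meds.append(np.median(q))
        assert (np.diff(meds) <= 1e-12).all()

    def test_decoupled_nodes_near_linear(self):
        # diagonal-only structural matrix: decoupled nodes, tiny sensitivity
        S = np.diag(np.linspace(0.5, 1.0, 10))
        rng = np.random.default_rng(1)
        U = np.linalg.qr(rng.standard_normal((10, 10)))[0]
        F = U @ np.diag(np.linspace(0.2, 0.9, 10)[::-1]) @ U.T
        res = sm.fit_individual(S, (F + F.T) / 2, 2)
        q = [sm.perturbation_quality(res, S, 0.01, s) for s in range(50)]
        assert min(q) >= 0.99


class TestNullModelReport:
    def test_identical_subjects_exchangeable(self, planted_pair):
        S, F, _ = planted_pair
        cohort = sm.Cohort([(S, F)] * 3)
        models = [sm.fit_individual(S, F, 2)] * 3
        rep = sm.null_model_report(cohort, models)
        np.testing.assert_allclose(rep.tables["S_S_cross"], 1.0, atol=1e-12)
        np.testing.assert_allclose(
            rep.tables["Fhat_cross_Fj"],
            np.mean(rep.tables["Fhat_self"]),
            atol=1e-8,
        )

    def test_table_counts(self, small_cohort):
        cohort, _ = small_cohort
        models = [sm.fit_individual(S, F, 2) for S, F in cohort]
        rep = sm.null_model_report(cohort, models)
        N = cohort.n_subjects
        assert rep.tables["F_S_same"].size == N
        assert rep.tables["F_S_cross"].size == N * (N - 1)
        assert rep.tables["F_F_cross"].size == N * (N - 1) // 2
        assert rep.tables["S_S_cross"].size == N * (N - 1) // 2
        assert rep.tables["Fhat_cross_Fi"].size == N * (N - 1)
        assert rep.tables["Fhat_cross_Fj"].size == N * (N - 1)

    def test_independent_functionals_uncorrelated(self, rng):
        n, N = 40, 5
        S = sm.make_structural(sm.SyntheticSpec(n=n, seed=2))
        subjects = []
        for _ in range(N):
            E = rng.standard_normal((n, n)) * 0.2
            F = np.clip((E + E.T) / 2, -1, 1)
            np.fill_diagonal(F, 1.0)
            subjects.append((S, sm.FunctionalMatrix(F)))
        cohort = sm.Cohort(subjects)
        models = [sm.fit_individual(S, F, 2) for S, F in cohort]
        rep = sm.null_model_report(cohort, models)
        bound = 4 / np.sqrt(n * (n - 1) / 2)
        assert np.abs(np.mean(rep.tables["F_F_cross"])) <= bound

    def test_misaligned_models_rejected(self, small_cohort):
        cohort, _ = small_cohort
        models = [sm.fit_individual(S, F, 2) for S, F in cohort]
        with pytest.raises(ValueError, match="models"):
            sm.null_model_report(cohort, models[:-1])

    def test_separation_with_individual_mappings(self, small_cohort):
        # each subject has its own planted mapping: the self-mapped quality
        # must exceed the swapped-parameter quality
        cohort, _ = small_cohort
        models = [sm.fit_individual(S, F, 2) for S, F in cohort]
        rep = sm.null_model_report(cohort, models)
        assert np.median(rep.tables["Fhat_self"]) > np.median(
            rep.tables["Fhat_cross_Fj"]
        )


class TestSpectralSimilarity:
    def test_pair_counts(self, small_cohort):
        cohort, _ = small_cohort
        tables = sm.spectral_similarity(cohort)
        l = cohort.n_subjects
        corr = tables["eigenvector_correlations"]
        for modality in ("structural", "functional"):
            for rank in (1, 2):
                sub = corr[(corr.modality == modality) & (corr["rank"] == rank)]
                assert len(sub) == l * (l - 1) // 2

    def test_identical_cohort_perfect_alignment(self, planted_pair):
        S, F, _ = planted_pair
        tables = sm.spectral_similarity(sm.Cohort([(S, F)] * 4))
        assert np.allclose(
            tables["eigenvector_correlations"]["abs_correlation"], 1.0
        )
        eig = tables["eigenvalues"]
        assert np.allclose(eig["q1"], eig["q3"])

    def test_shared_leading_mode_alignment_improves_as_noise_shrinks(self, rng):
        n, l = 30, 6
        v = rng.standard_normal(n)
        v /= np.linalg.norm(v)
        means = []
        for sigma in (0.5, 0.05):
            subjects = []
            for _ in range(l):
                E = rng.standard_normal((n, n)) * sigma
                X = 5.0 * np.outer(v, v) + (E + E.T) / 2
                X = np.abs(X)
                subjects.append((sm.StructuralMatrix((X + X.T) / 2), sm.FunctionalMatrix(np.eye(n))))
            tab = sm.spectral_similarity(sm.Cohort(subjects))
            corr = tab["eigenvector_correlations"]
            sub = corr[(corr.modality == "structural") & (corr["rank"] == 1)]
            means.append(sub["abs_correlation"].mean())
        assert means[1] > means[0]
        assert means[1] > 0.99

    def test_single_subject_rejected(self, planted_pair):
        S, F, _ = planted_pair
        with pytest.raises(ValueError, match="2 subjects"):
            sm.spectral_similarity(sm.Cohort([(S, F)]))
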