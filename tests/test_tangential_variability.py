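import numpy as np
import pytest

import laminarsim as ls


@pytest.fixture(scope="module")
def sim_patch():
    return ls.make_flat_patch(3.0, 20.0, resolution_mm=0.05)


class TestBuildTrialMatrix:
    def test_identical_noiseless_trials_give_identical_rows(self, sim_patch):
        m = ls.TimecourseModel(trial_amplitude_sd=0.0)
        sim = ls.simulate_trials(m, sim_patch, 3, 0.0, 1)
        stack = ls.build_trial_matrix(sim)
        assert np.array_equal(stack.matrix[0], stack.matrix[1])
        assert np.array_equal(stack.matrix[0], stack.matrix[2])

    def test_no_modulation_no_noise_gives_constant_columns(self, sim_patch):
        m = ls.TimecourseModel(trial_amplitude_sd=0.0, tangential_sd=0.0)
        sim = ls.simulate_trials(m, sim_patch, 3, 0.0, 1)
        stack = ls.build_trial_matrix(sim)
        assert np.allclose(stack.matrix, stack.matrix[0, 0])

    def test_row_means_match_noiseless_generator(self, sim_patch):
        # 10 noisy trials: the across-trial mean tangential profile agrees
        # with the noiseless generator profile within 3 standard errors
        m = ls.TimecourseModel(trial_amplitude_sd=0.0)
        noisy = ls.simulate_trials(m, sim_patch, 10, 1.0, 7)
        clean = ls.simulate_trials(m, sim_patch, 2, 0.0, 7)
        got = ls.build_trial_matrix(noisy).matrix
        want = ls.build_trial_matrix(clean).matrix[0]
        n_eff = got.shape[0] * 30 * np.sum(
            (noisy.times >= m.stimulus_onset_s + 2.0)
            & (noisy.times <= m.stimulus_onset_s + m.stimulus_duration_s)
        )
        se = 1.0 / np.sqrt(n_eff)
        # bound the max over all tangential positions, hence 4 SE
        assert np.all(np.abs(got.mean(axis=0) - want) < 4 * se)

    def test_minimum_two_trials(self):
        with pytest.raises(ValueError):
            ls.TrialStack(positions=np.arange(5.0), matrix=np.ones((1, 5)))


class TestPCA:
    def test_rank_one_stack_explains_everything(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(size=30)
        gains = np.array([0.5, 1.0, 1.5, 2.0])
        stack = ls.TrialStack(positions=np.arange(30.0), matrix=np.outer(gains, profile))
        res = ls.pca_explained_variance(stack)
        assert res.explained_variance_pct[0] == pytest.approx(100.0, abs=1e-9)

    def test_percentages_sum_to_100_components_orthonormal(self):
        rng = np.random.default_rng(1)
        stack = ls.TrialStack(positions=np.arange(20.0), matrix=rng.normal(size=(8, 20)))
        res = ls.pca_explained_variance(stack)
        assert res.explained_variance_pct.sum() == pytest.approx(100.0, abs=1e-9)
        G = res.components @ res.components.T
        assert np.allclose(G, np.eye(G.shape[0]), atol=1e-8)

    def test_matches_covariance_eigendecomposition(self):
        # independent oracle: eigenvalues of the empirical covariance matrix
        rng = np.random.default_rng(42)
        base = np.sin(np.linspace(0, 3 * np.pi, 20))
        X = 1.0 + np.outer(1 + 0.3 * rng.normal(size=6), base) + 0.2 * rng.normal(size=(6, 20))
        stack = ls.TrialStack(positions=np.arange(20.0), matrix=X)
        res = ls.pca_explained_variance(stack)
        Xc = X - X.mean(axis=0)
        evals = np.linalg.eigvalsh(Xc.T @ Xc)[::-1][: res.explained_variance_pct.size]
        oracle = 100.0 * evals / evals.sum()
        assert np.allclose(res.explained_variance_pct, oracle, atol=1e-8)

    def test_matches_sklearn_pca(self):
        # independent library cross-check of the explained-variance path
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(11)
        X = rng.normal(size=(7, 16)) + np.outer(rng.normal(size=7), np.ones(16))
        res = ls.pca_explained_variance(ls.TrialStack(positions=np.arange(16.0), matrix=X))
        ref = PCA().fit(X)
        k = min(res.explained_variance_pct.size, ref.explained_variance_ratio_.size)
        assert np.allclose(
            res.explained_variance_pct[:k], 100.0 * ref.explained_variance_ratio_[:k], atol=1e-8
        )

    def test_scaling_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 12))
        a = ls.pca_explained_variance(ls.TrialStack(positions=np.arange(12.0), matrix=X))
        b = ls.pca_explained_variance(ls.TrialStack(positions=np.arange(12.0), matrix=7.5 * X))
        assert np.allclose(a.explained_variance_pct, b.explained_variance_pct, rtol=1e-10)

    def test_pc1_sign_follows_mean_profile(self, sim_patch):
        m = ls.TimecourseModel()
        sim = ls.simulate_trials(m, sim_patch, 8, 0.5, 5)
        res = ls.pca_explained_variance(ls.build_trial_matrix(sim))
        mean_profile = ls.build_trial_matrix(sim).matrix.mean(axis=0)
        assert np.corrcoef(res.pc1, mean_profile)[0, 1] >= 0

    def test_zero_variance_rejected(self):
        stack = ls.TrialStack(positions=np.arange(4.0), matrix=np.ones((3, 4)))
        with pytest.raises(ValueError):
            ls.pca_explained_variance(stack)

    def test_noise_to_zero_limit_explains_everything(self, sim_patch):
        m = ls.TimecourseModel()  # trial gains vary, pattern fixed
        sim = ls.simulate_trials(m, sim_patch, 8, 1e-6, 2)
        res = ls.pca_explained_variance(ls.build_trial_matrix(sim))
        assert res.explained_variance_pct[0] > 99.9


class TestPC1Similarity:
    def test_self_and_negated_self(self):
        rng = np.random.default_rng(4)
        stack = ls.TrialStack(positions=np.arange(15.0), matrix=rng.normal(size=(6, 15)))
        res = ls.pca_explained_variance(stack)
        assert ls.pc1_similarity(res, res.pc1) == pytest.approx(1.0)
        assert ls.pc1_similarity(res, -res.pc1) == pytest.approx(-1.0)

    def test_constant_reference_rejected(self):
        rng = np.random.default_rng(5)
        stack = ls.TrialStack(positions=np.arange(10.0), matrix=rng.normal(size=(4, 10)))
        res = ls.pca_explained_variance(stack)
        with pytest.raises(ValueError):
            ls.pc1_similarity(res, np.ones(10))

    def test_structured_stacks_beat_matched_noise(self, sim_patch):
        # with a shared tangential pattern present, PC1 explains more than
        # in matched pure-noise stacks (same noise SD, no modulation)
        m_sig = ls.TimecourseModel()
        m_noise = ls.TimecourseModel(tangential_sd=0.0, trial_amplitude_sd=0.0)
        ev_sig, ev_noise = [], []
        for seed in range(25):
            s1 = ls.simulate_trials(m_sig, sim_patch, 8, 2.0, seed)
            s0 = ls.simulate_trials(m_noise, sim_patch, 8, 2.0, seed)
            ev_sig.append(
                ls.pca_explained_variance(ls.build_trial_matrix(s1)).explained_variance_pct[0]
            )
            ev_noise.append(
                ls.pca_explained_variance(ls.build_trial_matrix(s0)).explained_variance_pct[0]
            )
        assert np.mean(ev_sig) > np.mean(ev_noise) + 10.0


def test_trial_stack_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    stack = ls.TrialStack(
        positions=np.linspace(0.25, 9.75, 20), matrix=rng.normal(size=(5, 20))
    )
    path = tmp_path / "trials.tsv"
    stack.to_tsv(path)
    back = ls.TrialStack.from_tsv(path)
    assert np.allclose(back.positions, stack.positions)
    assert np.allclose(back.matrix, stack.matrix)
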