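"""Surprise regression, smoothing, Shapley decomposition, cluster inference."""

import itertools
import numpy as np
import pandas as pd
import pytest

from eegsurprise import encoding
from eegsurprise.exceptions import CollinearityError, EEGSurpriseError, InferenceError


class TestFitSurpriseRegression:
    def test_construct_and_recover_linear_combination(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.standard_normal((40, 3)), columns=["a", "b", "c"])
        sds = x.std(ddof=0)
        y = (2.0 * x["b"] - 1.0 * x["c"] + 7.0).to_numpy()[:, None] * np.ones((1, 5))
        betas = encoding.fit_surprise_regression(y, x)
        # standardized-scale betas equal planted values times raw-regressor SDs
        np.testing.assert_allclose(betas[0], 0.0, atol=1e-10)
        np.testing.assert_allclose(betas[1], 2.0 * sds["b"], atol=1e-10)
        np.testing.assert_allclose(betas[2], -1.0 * sds["c"], atol=1e-10)

    def test_residualized_noise_gives_zero_betas(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((30, 2))
        y = rng.standard_normal(30)
        # project out columns and intercept -> exactly zero sample covariance
        design = np.column_stack([np.ones(30), x])
        y = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        betas = encoding.fit_surprise_regression(y[:, None], x)
        np.testing.assert_allclose(betas, 0.0, atol=1e-10)

    def test_matches_hand_normal_equations(self):
        x = pd.DataFrame({"u": [0.0, 1, 2, 3, 4, 5], "v": [1.0, 0, 2, 1, 3, 2]})
        y = np.array([0.5, 1.0, 2.5, 2.0, 4.0, 3.5])
        xz = (x - x.mean()) / x.std(ddof=0)
        design = np.column_stack([np.ones(6), xz])
        oracle = np.linalg.solve(design.T @ design, design.T @ y)[1:]
        betas = encoding.fit_surprise_regression(y, x)
        np.testing.assert_allclose(betas[:, 0], oracle, atol=1e-12)

    def test_intercept_absorbs_shift_and_betas_scale_with_y(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((25, 3))
        y = rng.standard_normal((25, 4))
        b = encoding.fit_surprise_regression(y, x)
        np.testing.assert_allclose(
            encoding.fit_surprise_regression(y + 11.3, x), b, atol=1e-10
        )
        np.testing.assert_allclose(
            encoding.fit_surprise_regression(y * -2.5, x), -2.5 * b, atol=1e-10
        )

    def test_collinearity_error_names_columns(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame({"a": rng.standard_normal(20)})
        x["b"] = 2 * x["a"]
        with pytest.raises(CollinearityError):
            encoding.fit_surprise_regression(rng.standard_normal(20), x)

    def test_too_few_trials_errors(self):
        with pytest.raises(EEGSurpriseError):
            encoding.fit_surprise_regression(np.zeros(3), np.zeros((3, 3)))


class TestSavgol:
    def test_quadratic_reproduced_exactly(self):
        t = np.linspace(0, 1, 50)
        series = 3 * t**2 - 2 * t + 0.5
        np.testing.assert_allclose(encoding.savgol_smooth(series), series, atol=1e-10)

    def test_impulse_matches_analytic_kernel(self):
        # closed-form SG coefficients: e_0 row of (A^T A)^-1 A^T for A_ik = k^i
        k = np.arange(-4, 5)
        a = np.vander(k, 3, increasing=True)
        coef = np.linalg.pinv(a)[0]  # smoothing weights for the center sample
        x = np.zeros(31)
        x[15] = 1.0
        out = encoding.savgol_smooth(x)
        np.testing.assert_allclose(out[11:20], coef[::-1], atol=1e-12)

    def test_defaults_are_order2_window9(self):
        assert (encoding.SAVGOL_ORDER, encoding.SAVGOL_WINDOW) == (2, 9)

    @pytest.mark.parametrize("order,window", [(2, 8), (3, 3), (2, 1)])
    def test_bad_parameters_error(self, order, window):
        with pytest.raises(ValueError):
            encoding.savgol_smooth(np.zeros(50), order=order, window=window)


class TestShapley:
    def test_orthogonal_regressors_get_marginal_r2(self):
        rng = np.random.default_rng(4)
        q, _ = np.linalg.qr(rng.standard_normal((40, 3)))
        x = q - q.mean(axis=0)  # exactly orthogonal after centering? re-orth:
        q, _ = np.linalg.qr(x)
        x = q
        y = 1.5 * x[:, 0] + 0.5 * x[:, 2] + 0.05 * rng.standard_normal(40)
        phi = encoding.shapley_r2(y, x)
        from numpy.linalg import lstsq

        for j in range(3):
            d = np.column_stack([np.ones(40), x[:, j]])
            res = y - d @ lstsq(d, y, rcond=None)[0]
            marg = 1 - (res**2).sum() / ((y - y.mean()) ** 2).sum()
            assert phi[j] == pytest.approx(marg, abs=1e-8)

    def test_efficiency_sum_equals_full_r2(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((30, 4)) @ rng.standard_normal((4, 4))  # correlated
        y = x @ [1.0, -0.5, 0.2, 0.0] + rng.standard_normal(30)
        phi = encoding.shapley_r2(y, x)
        full = encoding._r2(y, x, tuple(range(4)))
        assert phi.sum() == pytest.approx(full, abs=1e-10)

    def test_matches_ordering_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal((25, 3))
        x = base @ np.array([[1, 0.6, 0.3], [0, 1, 0.5], [0, 0, 1]])  # correlated
        y = x @ [0.8, -1.2, 0.4] + rng.standard_normal(25)
        phi = encoding.shapley_r2(y, x)
        oracle = np.zeros(3)
        for perm in itertools.permutations(range(3)):
            r2_prev = 0.0
            chosen = []
            for j in perm:
                chosen.append(j)
                r2 = encoding._r2(y, x, tuple(sorted(chosen)))
                oracle[j] += (r2 - r2_prev) / 6
                r2_prev = r2
        np.testing.assert_allclose(phi, oracle, atol=1e-10)

    def test_symmetry_and_dummy(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal(40)
        dummy = rng.standard_normal(40)
        d = np.column_stack([np.ones(40), z, z])
        # make dummy exactly orthogonal to everything incl. intercept
        dummy -= d @ np.linalg.lstsq(d, dummy, rcond=None)[0]
        x = np.column_stack([z, z, dummy])
        y = z + 0.1 * rng.standard_normal(40)
        y -= (y @ dummy) / (dummy @ dummy) * dummy
        phi = encoding.shapley_r2(y, x)
        assert phi[0] == pytest.approx(phi[1], abs=1e-10)  # exchangeable twins
        assert abs(phi[2]) < 1e-10  # zero-covariance regressor

    def test_p_too_large_errors(self):
        with pytest.raises(EEGSurpriseError):
            encoding.shapley_r2(np.zeros(40), np.zeros((40, 13)))


class TestClusterPermutation:
    def test_all_zero_data_yields_empty_result(self):
        res = encoding.cluster_permutation_onesample(np.zeros((10, 50)), n_perm=200)
        assert res.clusters == []
        assert res.t_max == 0.0

    def test_identical_nonzero_participants_error(self):
        with pytest.raises(InferenceError):
            encoding.cluster_permutation_onesample(np.ones((10, 50)), n_perm=200)

    def test_planted_window_detected(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((38, 120))
        data[:, 50:71] += 1.0  # mean 1.0, SD 1.0 confined to samples 50-70
        res = encoding.cluster_permutation_onesample(data, n_perm=2000, seed=0)
        sig = res.significant(0.05)
        assert sig, "planted effect not detected"
        best = max(sig, key=lambda c: abs(c.mass))
        assert best.sign == 1
        assert best.i_start <= 55 and best.i_end >= 65  # covers the planted core
        assert best.p_cluster < 0.05

    def test_pvalues_monotone_in_effect_size(self):
        rng = np.random.default_rng(9)
        noise = rng.standard_normal((20, 80))
        pvals = []
        for dose in (0.2, 0.5, 0.9, 1.4):
            data = noise.copy()
            data[:, 30:46] += dose
            res = encoding.cluster_permutation_onesample(data, n_perm=1000, seed=1)
            sig = [c.p_cluster for c in res.clusters if c.sign == 1
                   and c.i_start < 46 and c.i_end >= 30]
            pvals.append(min(sig) if sig else 1.0)
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_p_floor_is_one_over_nperm_plus_one(self):
        rng = np.random.default_rng(10)
        data = 5.0 + 0.3 * rng.standard_normal((30, 40))
        res = encoding.cluster_permutation_onesample(data, n_perm=500, seed=2)
        assert min(c.p_cluster for c in res.clusters) == pytest.approx(1 / 501)

    def test_matches_mne_cluster_test(self):
        """Independent cross-check against MNE's sign-flip cluster test."""
        mne_stats = pytest.importorskip("mne.stats")
        rng = np.random.default_rng(11)
        data = rng.standard_normal((15, 90))
        data[:, 40:61] += 0.9
        res = encoding.cluster_permutation_onesample(data, n_perm=800, seed=3)
        t_thresh = res.threshold
        t_obs, clusters, pvals, _ = mne_stats.permutation_cluster_1samp_test(
            data, threshold=t_thresh, n_permutations=800, tail=0, seed=1,
            out_type="mask", verbose=False,
        )
        np.testing.assert_allclose(t_obs, res.t_obs, atol=1e-8)
        mne_windows = sorted((c[0].start, c[0].stop - 1) for c in clusters)
        ours = sorted((c.i_start, c.i_end) for c in res.clusters)
        assert ours == mne_windows
        # p-values agree approximately (independent permutation draws)
        our_best = min(c.p_cluster for c in res.clusters)
        assert min(pvals) == pytest.approx(our_best, abs=0.02)


class TestRunErpScaling(object):
    def test_planted_highlevel_recovered_lowlevel_null(self, small_cohort):
        spec, _, rdms, _, epochs = small_cohort
        bt, results, prov = encoding.run_erp_scaling(
            iter(epochs), rdms, n_perm=1000, seed=5
        )
        sig_high = [c for c in results["highlevel"].significant(0.05) if c.sign == 1]
        assert any(c.t_start <= 0.262 and c.t_end >= 0.188 for c in sig_high)
        assert not results["lowlevel"].significant(0.05)
        assert prov["n_perm"] == 1000 and prov["standardized_regressors"]

    def test_window_beta_matches_planted_coefficient(self, small_cohort):
        from eegsurprise import synthetic_data as sd

        spec, _, rdms, _, epochs = small_cohort
        bt, _, _ = encoding.run_erp_scaling(iter(epochs), rdms, n_perm=100 * 2,
                                            seed=5)
        w = (bt.times >= 0.188) & (bt.times <= 0.262)
        recovered = bt.for_model("highlevel")[:, w].mean()
        planted = spec.planted_beta["highlevel"][0]
        gain = sd.effect_window_gain(spec, "highlevel")
        assert recovered == pytest.approx(planted * gain, rel=0.10)
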