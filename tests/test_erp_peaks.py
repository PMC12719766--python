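"""ERP peak detection and group statistics (t, d_z, BF10, FDR/Holm, rmANOVA)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from eegsurprise import erp_peaks as ep
from eegsurprise.exceptions import EEGSurpriseError, InferenceError


def bump(times, center, width, amp=1.0):
    return amp * np.exp(-0.5 * ((times - center) / width) ** 2)


TIMES = np.arange(-0.1, 0.7, 1 / 256)


class TestDetectPeaks:
    def test_single_positive_bump_is_p2(self):
        erp = bump(TIMES, 0.210, 0.02)[None, :]
        peaks = ep.detect_peaks(erp, TIMES)
        p2 = peaks[peaks["component"] == "P2"].iloc[0]
        assert p2["peak_latency_ms"] == pytest.approx(210.0, abs=1000 / 256)

    def test_two_bump_signal_p1_and_n1(self):
        erp = (bump(TIMES, 0.100, 0.012) - bump(TIMES, 0.160, 0.012))[None, :]
        peaks = ep.detect_peaks(erp, TIMES).set_index("component")
        assert peaks.loc["P1", "peak_latency_ms"] == pytest.approx(100.0, abs=1000 / 256)
        assert peaks.loc["N1", "peak_latency_ms"] == pytest.approx(160.0, abs=1000 / 256)

    def test_canonical_windows(self):
        assert ep.COMPONENT_WINDOWS == {
            "P1": (0.080, 0.130, +1), "N1": (0.130, 0.190, -1),
            "P2": (0.180, 0.250, +1), "N2": (0.200, 0.300, -1),
            "P3": (0.300, 0.600, +1),
        }

    def test_shift_equivariance_within_windows(self):
        base = bump(TIMES, 0.100, 0.01) + bump(TIMES, 0.210, 0.02) \
            - bump(TIMES, 0.155, 0.012)
        shift = 4  # samples (~15.6 ms)
        shifted = np.roll(base, shift)
        a = ep.detect_peaks(base[None], TIMES).set_index("component")
        b = ep.detect_peaks(shifted[None], TIMES).set_index("component")
        dt = shift / 256 * 1000
        for comp in ("P1", "N1", "P2"):
            assert b.loc[comp, "peak_latency_ms"] - a.loc[comp, "peak_latency_ms"] \
                == pytest.approx(dt, abs=1e-9)

    def test_window_outside_epoch_errors(self):
        with pytest.raises(EEGSurpriseError):
            ep.detect_peaks(np.zeros((1, 20)), np.arange(20) / 256.0,
                            windows={"P3": (0.3, 0.6, 1)})


class TestWindowAverage:
    def test_constant_series(self):
        assert ep.window_average(np.full_like(TIMES, 3.3), TIMES, 0.2) == pytest.approx(3.3)

    def test_linear_series_gives_center_value(self):
        series = 5.0 * TIMES
        out = ep.window_average(series, TIMES, 0.2, 0.010)
        assert out == pytest.approx(5.0 * 0.2, abs=5.0 / 256)

    def test_clipped_at_epoch_edge(self):
        out = ep.window_average(TIMES, TIMES, TIMES[-1], 0.010)
        assert out <= TIMES[-1]


class TestGroupOnesample:
    def test_all_zero_values(self):
        res = ep.group_onesample(np.zeros(8), with_bf=False)
        assert res.t == 0.0 and res.d_z == 0.0

    def test_matches_textbook_formula(self):
        x = np.array([2.1, 1.4, 3.3, 0.2, 1.9])
        res = ep.group_onesample(x, with_bf=False)
        m, sd = x.mean(), x.std(ddof=1)
        t = m / (sd / np.sqrt(5))
        p = 2 * sstats.t.sf(abs(t), 4)
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.p_raw == pytest.approx(p, abs=1e-12)
        assert res.d_z == pytest.approx(m / sd, abs=1e-12)
        assert res.df == 4

    def test_zero_variance_nonzero_mean_errors(self):
        with pytest.raises(InferenceError):
            ep.group_onesample(np.full(5, 2.0), with_bf=False)


class TestBayesFactor:
    def test_t_zero_favors_null(self):
        for n in (5, 10, 40):
            assert ep.bayes_ttest_onesample(t=0.0, n=n) < 1.0

    @pytest.mark.parametrize("t,n", [(0.0, 10), (1.0, 10), (2.5, 20), (4.0, 38),
                                     (-2.0, 15), (1.5, 50)])
    def test_matches_pingouin_g_prior_oracle(self, t, n):
        pingouin = pytest.importorskip("pingouin")
        ours = ep.bayes_ttest_onesample(t=t, n=n)
        theirs = float(pingouin.bayesfactor_ttest(t, n, paired=True, r=0.707))
        assert ours == pytest.approx(theirs, rel=0.01)

    def test_null_evidence_grows_with_n(self):
        rng = np.random.default_rng(0)
        meds = []
        for n in (10, 40, 160):
            bfs = [ep.bayes_ttest_onesample(rng.standard_normal(n))
                   for _ in range(40)]
            meds.append(np.median(bfs))
        assert meds[0] > meds[1] > meds[2]

    def test_values_interface_matches_t_interface(self):
        x = np.array([0.3, -0.1, 0.5, 0.9, 0.2, 0.4, -0.2, 0.6])
        t = x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))
        assert ep.bayes_ttest_onesample(x) == pytest.approx(
            ep.bayes_ttest_onesample(t=t, n=len(x)), rel=1e-9
        )


class TestMultipleComparisons:
    def test_single_p_unchanged(self):
        assert ep.fdr_bh([0.03])[0] == pytest.approx(0.03)
        assert ep.holm([0.03])[0] == pytest.approx(0.03)

    def test_bh_hand_example(self):
        np.testing.assert_allclose(ep.fdr_bh([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_holm_hand_example(self):
        np.testing.assert_allclose(ep.holm([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04])

    def test_adjusted_at_least_raw_and_order_preserving(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.001, 0.9, size=12)
        for adj in (ep.fdr_bh(p), ep.holm(p)):
            assert np.all(adj >= p - 1e-12)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-12)


class TestRmAnova:
    def test_two_conditions_epsilon_exactly_one(self):
        rng = np.random.default_rng(2)
        res = ep.rm_anova_gg(rng.standard_normal((12, 2)))
        assert res.gg_epsilon == pytest.approx(1.0)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        base = rng.standard_normal((10, 1))
        data = base + rng.standard_normal((10, 3)) * [1.0, 0.5, 2.0] + [0, 0.4, 0.8]
        res = ep.rm_anova_gg(data)
        df = pd.DataFrame(data, columns=list("abc")).reset_index().melt(
            id_vars="index", var_name="cond", value_name="y"
        )
        pg = pingouin.rm_anova(data=df, dv="y", within="cond", subject="index",
                               correction=True, effsize="np2", detailed=True)
        assert res.f == pytest.approx(float(pg["F"].iloc[0]), rel=1e-9)
        assert res.gg_epsilon == pytest.approx(float(pg["eps"].iloc[0]), rel=1e-9)
        assert res.p_raw == pytest.approx(float(pg["p_GG_corr"].iloc[0]), rel=1e-6)
        assert res.eta_p2 == pytest.approx(float(pg["np2"].iloc[0]), rel=1e-9)

    def test_corrected_df_reporting_style(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((38, 3)) * [1.0, 0.3, 2.5]  # nonspherical
        res = ep.rm_anova_gg(data)
        assert 1.0 < res.df1 < 2.0  # (k-1)·ε with ε < 1, e.g. F(1.6, 59.8)
        assert res.df2 == pytest.approx(res.df1 * 37, rel=1e-9)

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(5)
        rejections = sum(
            ep.rm_anova_gg(rng.standard_normal((12, 3))).p_raw < 0.05
            for _ in range(400)
        )
        # binomial 95% band around 0.05 for 400 runs: [0.029, 0.071]
        assert 0.029 <= rejections / 400 <= 0.071

    def test_incomplete_design_errors(self):
        data = np.ones((5, 3)) + np.random.default_rng(6).standard_normal((5, 3))
        data[2, 1] = np.nan
        with pytest.raises(EEGSurpriseError):
            ep.rm_anova_gg(data)


class TestBehavioralSummary:
    def _cohort_trials(self, n_participants=6, rt_shift=(0.0, 5.0, 15.0), seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n_participants):
            for cond, shift in zip(ep.BEHAVIOR_CONDITIONS, rt_shift):
                for k in range(20):
                    rows.append({
                        "participant": p, "block": 0, "trial": k, "cue": "b",
                        "image": "x", "expected_image": "x", "expectedness": cond,
                        "nogo": False, "response": "animate",
                        "correct": bool(rng.random() < 0.96),
                        "rt_ms": 500 + shift + 40 * rng.standard_normal(),
                    })
            rows.append({"participant": p, "block": 0, "trial": 99, "cue": "a",
                         "image": "x", "expected_image": "", "expectedness": "nogo",
                         "nogo": True, "response": "none", "correct": True,
                         "rt_ms": np.nan})
        return pd.DataFrame(rows)

    def test_all_correct_gives_full_accuracy(self):
        trials = self._cohort_trials()
        trials["correct"] = True
        out = ep.behavioral_summary(trials)
        np.testing.assert_allclose(out["accuracy"]["means"], 1.0)

    def test_rt_exclusion_bounds(self):
        trials = self._cohort_trials(n_participants=3)
        # plant one too-fast and one too-slow RT; both must drop from RT means
        loud = trials[(trials["participant"] == 0)
                      & (trials["expectedness"] == "expected")].index[:3]
        trials.loc[loud[0], "rt_ms"] = 90.0
        trials.loc[loud[1], "rt_ms"] = 1600.0
        trials.loc[loud[2], "rt_ms"] = 500.0
        trials.loc[loud, "correct"] = True
        out = ep.behavioral_summary(trials)
        surviving = trials.loc[(trials["participant"] == 0)
                               & (trials["expectedness"] == "expected")]
        kept = surviving[surviving["correct"]
                         & surviving["rt_ms"].between(100, 1500)]["rt_ms"]
        assert out["rt_ms"]["per_participant"][0, 0] == pytest.approx(kept.mean())

    def test_condition_taxonomy_and_contrast_family(self):
        out = ep.behavioral_summary(self._cohort_trials())
        assert out["conditions"] == list(ep.BEHAVIOR_CONDITIONS)
        assert len(out["rt_ms"]["contrasts"]) == 3  # all pairwise, Holm corrected
        for c in out["rt_ms"]["contrasts"]:
            assert c["result"].p_adjusted >= c["result"].p_raw - 1e-12

    def test_planted_rt_gradient_detected(self):
        out = ep.behavioral_summary(self._cohort_trials(n_participants=20,
                                                        rt_shift=(0, 10, 30), seed=1))
        means = out["rt_ms"]["means"]
        assert means[0] < means[1] < means[2]
        assert out["rt_ms"]["anova"].p_raw < 0.05
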