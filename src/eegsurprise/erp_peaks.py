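"""Individual ERP peak analysis and group statistics.

Participant-specific P1/N1/P2/N2/P3 peaks are detected on the ROI-averaged
ERP in canonical latency windows; surprise betas are averaged in a 20 ms
window around each peak and tested against zero with one-sample t-tests
(Benjamini-Hochberg correction across the ERP × model family), complemented
by JZS Bayes factors (Cauchy prior, scale 0.707). Behavioral RT/accuracy
analyses use one-way repeated-measures ANOVA with Greenhouse-Geisser
correction and Holm-corrected paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats
from statsmodels.stats.multitest import multipletests

from eegsurprise.exceptions import EEGSurpriseError, InferenceError

#: canonical post-stimulus component windows (s) and polarity (+1 max, -1 min)
COMPONENT_WINDOWS: dict[str, tuple[float, float, int]] = {
    "P1": (0.080, 0.130, +1),
    "N1": (0.130, 0.190, -1),
    "P2": (0.180, 0.250, +1),
    "N2": (0.200, 0.300, -1),
    "P3": (0.300, 0.600, +1),
}

#: default Cauchy prior scale for the JZS Bayes factor
BF_CAUCHY_SCALE = 0.707

#: RT exclusion bounds (ms) for behavioral analyses
RT_BOUNDS_MS = (100.0, 1500.0)

BEHAVIOR_CONDITIONS = (
    "expected",
    "unexpected_same_response",
    "unexpected_different_response",
)


@dataclass
class GroupStatResult:
    """Group-level statistic: t-test or repeated-measures ANOVA summary."""

    estimate: float
    t: float | None = None
    df: float | None = None
    p_raw: float | None = None
    p_adjusted: float | None = None
    d_z: float | None = None
    bf10: float | None = None
    f: float | None = None
    df1: float | None = None
    df2: float | None = None
    eta_p2: float | None = None
    gg_epsilon: float | None = None


# ---------------------------------------------------------------------------
# Peak detection and windowed aggregation
# ---------------------------------------------------------------------------


def detect_peaks(
    erp: np.ndarray,
    times: np.ndarray,
    windows: dict[str, tuple[float, float, int]] = COMPONENT_WINDOWS,
) -> pd.DataFrame:
    """Participant-specific peak latencies per ERP component.

    ``erp`` is (participants, timepoints) ROI-averaged mean amplitude. For
    each component, the extremum of the matching polarity is located within
    the canonical window (ties break to the earliest sample). Returns a tidy
    frame with participant, component, peak_latency_ms and polarity.
    """
    erp = np.atleast_2d(np.asarray(erp, dtype=float))
    times = np.asarray(times, dtype=float)
    rows = []
    for name, (t0, t1, pol) in windows.items():
        mask = (times >= t0 - 1e-12) & (times <= t1 + 1e-12)
        if not mask.any():
            raise EEGSurpriseError(f"window for {name} ({t0}-{t1} s) outside the epoch")
        idx = np.flatnonzero(mask)
        seg = erp[:, idx] * pol
        peak_ix = idx[np.argmax(seg, axis=1)]  # argmax takes the earliest tie
        for p, ix in enumerate(peak_ix):
            rows.append(
                {
                    "participant": p,
                    "component": name,
                    "peak_latency_ms": float(times[ix] * 1000.0),
                    "polarity": pol,
                }
            )
    return pd.DataFrame(rows)


def window_average(
    values: np.ndarray, times: np.ndarray, peak_s: float, half_width_s: float = 0.010
) -> float:
    """Unweighted mean of samples within ±``half_width_s`` of the peak.

    The window is clipped to the epoch rather than erroring at the edges.
    """
    times = np.asarray(times, dtype=float)
    mask = (times >= peak_s - half_width_s - 1e-12) & (times <= peak_s + half_width_s + 1e-12)
    if not mask.any():
        raise EEGSurpriseError("window around peak contains no samples after clipping")
    return float(np.asarray(values, dtype=float)[mask].mean())


def peak_beta_table(
    betas: np.ndarray,
    times: np.ndarray,
    peaks: pd.DataFrame,
    model_names: tuple[str, ...],
    half_width_s: float = 0.010,
) -> pd.DataFrame:
    """Average each participant's beta timecourses around their own ERP peaks.

    ``betas`` is (participants, models, timepoints). Returns a tidy frame with
    participant, component, model, beta.
    """
    rows = []
    for _, pk in peaks.iterrows():
        p = int(pk["participant"])
        for mi, m in enumerate(model_names):
            rows.append(
                {
                    "participant": p,
                    "component": pk["component"],
                    "model": m,
                    "beta": window_average(
                        betas[p, mi], times, pk["peak_latency_ms"] / 1000.0, half_width_s
                    ),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------


def group_onesample(values: np.ndarray, with_bf: bool = True) -> GroupStatResult:
    """One-sample t-test against zero with Cohen's d_z and JZS BF10.

    Multiple-testing adjustment is the caller's responsibility (the peak
    analysis corrects across the full ERP × model family).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise EEGSurpriseError("need at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        if np.allclose(x, 0):
            return GroupStatResult(estimate=0.0, t=0.0, df=x.size - 1, p_raw=1.0, d_z=0.0)
        raise InferenceError("zero variance with nonzero mean: t undefined")
    t, p = stats.ttest_1samp(x, 0.0)
    res = GroupStatResult(
        estimate=float(x.mean()), t=float(t), df=float(x.size - 1),
        p_raw=float(p), d_z=float(x.mean() / sd),
    )
    if with_bf:
        res.bf10 = bayes_ttest_onesample(x)
    return res


def paired_t(a: np.ndarray, b: np.ndarray) -> GroupStatResult:
    """Paired t-test reported like the one-sample test on the differences."""
    return group_onesample(np.asarray(a, dtype=float) - np.asarray(b, dtype=float),
                           with_bf=False)


def bayes_ttest_onesample(
    values: np.ndarray | None = None,
    t: float | None = None,
    n: int | None = None,
    r: float = BF_CAUCHY_SCALE,
) -> float:
    """JZS Bayes factor BF10 for a one-sample t-test (two-sided alternative).

    The marginal likelihood under H1 places a Cauchy(0, r) prior on the
    standardized effect size δ and integrates the noncentral-t likelihood of
    the observed t statistic over δ; H0 is the point null δ = 0. Computed by
    adaptive quadrature.
    """
    if values is not None:
        x = np.asarray(values, dtype=float)
        n = x.size
        sd = x.std(ddof=1)
        if n < 3 or not np.isfinite(sd) or sd == 0:
            raise EEGSurpriseError("need >= 3 values with finite nonzero variance")
        t = float(x.mean() / (sd / np.sqrt(n)))
    if t is None or n is None:
        raise ValueError("provide either values or (t, n)")
    df = n - 1

    def integrand(delta: float) -> float:
        like = stats.nct.pdf(t, df, delta * np.sqrt(n))
        if not np.isfinite(like):  # scipy underflow band far from the peak
            like = 0.0
        return like * stats.cauchy.pdf(delta, 0.0, r)

    # split at the likelihood peak: its width shrinks as 1/sqrt(n) and an
    # unsplit infinite-range quadrature can miss the mass entirely
    center = t / np.sqrt(n)
    n1, e1 = integrate.quad(integrand, -np.inf, center, limit=200)
    n2, e2 = integrate.quad(integrand, center, np.inf, limit=200)
    num, err = n1 + n2, e1 + e2
    if not np.isfinite(num) or num <= 0 or err / num > 1e-4:
        raise InferenceError(f"BF10 quadrature did not converge (value={num}, err={err})")
    den = stats.t.pdf(t, df)
    return float(num / den)


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvals, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def holm(pvals) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values (monotone)."""
    p = np.asarray(pvals, dtype=float)
    return multipletests(p, method="holm")[1]


def rm_anova_gg(data: np.ndarray) -> GroupStatResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``data`` is a complete (participants, conditions) table. Epsilon is
    computed from the double-centered sample covariance of the conditions;
    the F test uses corrected degrees of freedom (k−1)ε and (k−1)(n−1)ε.
    Partial eta squared is SS_cond / (SS_cond + SS_error).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise EEGSurpriseError("need a (participants, conditions >= 2) table")
    if not np.all(np.isfinite(x)):
        raise EEGSurpriseError("incomplete design: non-finite cells")
    n, k = x.shape
    grand = x.mean()
    ss_cond = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        raise InferenceError("zero error variance in repeated-measures ANOVA")
    f = ms_cond / ms_err
    # Greenhouse-Geisser epsilon from the double-centered covariance matrix.
    s = np.cov(x, rowvar=False, ddof=1)
    j = np.eye(k) - np.ones((k, k)) / k
    sc = j @ s @ j
    eps = float(np.trace(sc) ** 2 / ((k - 1) * np.sum(sc**2)))
    eps = min(max(eps, 1.0 / (k - 1)), 1.0)
    p = float(stats.f.sf(f, df1 * eps, df2 * eps))
    return GroupStatResult(
        estimate=float(np.ptp(x.mean(axis=0))),
        f=float(f), df1=float(df1 * eps), df2=float(df2 * eps), p_raw=p,
        eta_p2=float(ss_cond / (ss_cond + ss_err)), gg_epsilon=eps,
    )


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------


def morey_within_ci(means: np.ndarray, confidence: float = 0.95) -> np.ndarray:
    """Within-subject CIs: participant-mean-centered with the Morey correction."""
    x = np.asarray(means, dtype=float)
    n, k = x.shape
    centered = x - x.mean(axis=1, keepdims=True) + x.mean()
    sd = centered.std(axis=0, ddof=1) * np.sqrt(k / (k - 1))
    tcrit = stats.t.ppf(0.5 + confidence / 2, n - 1)
    return tcrit * sd / np.sqrt(n)


def behavioral_summary(trials: pd.DataFrame, rt_bounds_ms=RT_BOUNDS_MS) -> dict:
    """Condition-wise RT and accuracy with rmANOVA and Holm-corrected contrasts.

    Expects a trial table with a ``participant`` column and response-congruency
    labels. RTs use correct go trials within the exclusion bounds; accuracy is
    the fraction of correct go trials. Both are analyzed across the three
    expectedness conditions; paired contrasts are Holm corrected within each
    measure, and Morey-corrected within-subject 95% CIs are returned for
    plotting.
    """
    if "participant" not in trials.columns:
        raise EEGSurpriseError("trial table needs a 'participant' column")
    go = trials.loc[~trials["nogo"].astype(bool)].copy()
    go["correct"] = go["correct"].fillna(False).astype(bool)
    lo, hi = rt_bounds_ms
    rt_ok = go["correct"] & go["rt_ms"].between(lo, hi)

    participants = sorted(go["participant"].unique())
    rt_means = np.full((len(participants), len(BEHAVIOR_CONDITIONS)), np.nan)
    acc_means = np.full_like(rt_means, np.nan)
    for pi, p in enumerate(participants):
        for ci, cond in enumerate(BEHAVIOR_CONDITIONS):
            cell = go[(go["participant"] == p) & (go["expectedness"] == cond)]
            if cell.empty:
                raise EEGSurpriseError(f"empty cell: participant {p}, condition {cond}")
            acc_means[pi, ci] = cell["correct"].mean()
            rts = cell.loc[rt_ok.loc[cell.index], "rt_ms"]
            rt_means[pi, ci] = rts.mean() if len(rts) else np.nan
    if not np.all(np.isfinite(rt_means)):
        raise EEGSurpriseError("empty RT cell after exclusions")

    out = {"conditions": list(BEHAVIOR_CONDITIONS), "participants": participants}
    for name, table in (("rt_ms", rt_means), ("accuracy", acc_means)):
        try:
            anova = rm_anova_gg(table)
        except InferenceError:
            anova = None  # degenerate (e.g. ceiling accuracy in every cell)
        contrasts = []
        for i in range(len(BEHAVIOR_CONDITIONS)):
            for j in range(i + 1, len(BEHAVIOR_CONDITIONS)):
                res = paired_t(table[:, i], table[:, j])
                contrasts.append(
                    {
                        "pair": (BEHAVIOR_CONDITIONS[i], BEHAVIOR_CONDITIONS[j]),
                        "result": res,
                    }
                )
        p_adj = holm([c["result"].p_raw for c in contrasts])
        for c, pa in zip(contrasts, p_adj):
            c["result"].p_adjusted = float(pa)
        out[name] = {
            "means": table.mean(axis=0),
            "per_participant": table,
            "anova": anova,
            "contrasts": contrasts,
            "ci95_within": morey_within_ci(table),
        }
    return out
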