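"""Time-resolved representational similarity analysis and onset latencies.

Per timepoint, a neural RDM is built from trial-averaged stimulus patterns
(1 - Pearson over channels, concatenated across recording blocks) and rank-
correlated (Kendall's tau-a) with each model RDM. Group inference reuses the
one-sample cluster permutation machinery; onset latencies (50% of the
in-window maximum) are estimated with a jackknife whose leave-one-out scores
are retransformed into individual estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from eegsurprise._utils import lower_tri
from eegsurprise.eeg_preprocess import Epochs
from eegsurprise.encoding import (
    ClusterResult,
    SAVGOL_ORDER,
    SAVGOL_WINDOW,
    cluster_permutation_onesample,
    savgol_smooth,
)
from eegsurprise.exceptions import DegenerateInputError, EEGSurpriseError
from eegsurprise.feature_models import RDM


@dataclass
class RSATimecourse:
    """Participant × model × timepoint Kendall correlations."""

    tau: np.ndarray
    times: np.ndarray
    model_names: tuple[str, ...]
    tau_variant: str = "a"

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        if np.nanmax(np.abs(self.tau)) > 1 + 1e-9:
            raise ValueError("tau outside [-1, 1]")

    def for_model(self, name: str) -> np.ndarray:
        return self.tau[:, self.model_names.index(name), :]


@dataclass
class LatencyEstimate:
    """Jackknife onset latencies for one condition/timecourse family.

    ``onsets_ms`` are the retransformed per-participant estimates (NaN where a
    leave-one-out curve never crossed the criterion); ``group_mean_ms`` is the
    mean of the leave-one-out scores, to which the restored estimates average
    exactly.
    """

    onsets_ms: np.ndarray
    loo_onsets_ms: np.ndarray
    group_mean_ms: float
    grand_average_onset_ms: float
    criterion: float
    window_s: tuple[float, float]


def neural_rdm_timecourse(
    e: Epochs,
    stimulus_ids: list[str],
    include_nogo: bool = False,
    per_block_average: bool = False,
) -> np.ndarray:
    """Per-timepoint neural RDMs from block-wise trial-averaged patterns.

    For each stimulus and block, go trials showing that stimulus are averaged
    into a channel pattern; patterns are concatenated across blocks (blocks x
    channels dimensions) and the RDM entry is 1 - Pearson between the
    concatenated vectors. All go trials enter irrespective of expectedness;
    set ``include_nogo`` to also admit no-go trials. With
    ``per_block_average`` the RDM is instead computed within each block and
    averaged across blocks. Returns (timepoints, n_stim, n_stim).
    """
    trials = e.trials
    keep = np.ones(len(trials), dtype=bool) if include_nogo else ~trials["nogo"].to_numpy(dtype=bool)
    blocks = sorted(trials["block"].unique())
    n_stim, n_t = len(stimulus_ids), len(e.times)
    patterns = np.empty((n_stim, len(blocks), len(e.channels), n_t))
    for bi, b in enumerate(blocks):
        for si, stim in enumerate(stimulus_ids):
            mask = keep & (trials["block"] == b).to_numpy() & (trials["image"] == stim).to_numpy()
            if not mask.any():
                raise EEGSurpriseError(f"stimulus {stim!r} has no usable trial in block {b}")
            patterns[si, bi] = e.data[mask].mean(axis=0)
    out = np.empty((n_t, n_stim, n_stim))
    if per_block_average:
        for t in range(n_t):
            acc = np.zeros((n_stim, n_stim))
            for bi in range(len(blocks)):
                acc += 1.0 - np.corrcoef(patterns[:, bi, :, t])
            out[t] = acc / len(blocks)
            np.fill_diagonal(out[t], 0.0)
    else:
        flat = patterns.reshape(n_stim, -1, n_t)  # blocks x channels concatenated
        for t in range(n_t):
            out[t] = 1.0 - np.corrcoef(flat[:, :, t])
            np.fill_diagonal(out[t], 0.0)
    return out


def kendall_tau(a: np.ndarray, b: np.ndarray, variant: str = "a") -> float:
    """Kendall rank correlation between two vectors.

    ``variant='a'`` (default, standard for RDM comparison): concordant minus
    discordant pairs over n(n-1)/2, ties counting as neither. ``variant='b'``
    applies the tie correction and is undefined for constant input.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    sa = np.sign(a[:, None] - a[None, :])
    sb = np.sign(b[:, None] - b[None, :])
    iu = np.triu_indices(a.size, k=1)
    prod = sa[iu] * sb[iu]
    n_pairs = a.size * (a.size - 1) // 2
    if variant == "a":
        return float(prod.sum()) / n_pairs
    if variant == "b":
        ta = float((sa[iu] != 0).sum())
        tb = float((sb[iu] != 0).sum())
        if ta == 0 or tb == 0:
            raise DegenerateInputError("tau-b undefined for constant input")
        return float(prod.sum()) / np.sqrt(ta * tb)
    raise ValueError(f"unknown tau variant {variant!r}")


def rsa_timecourse(
    participants,
    model_rdms,
    model_order: tuple[str, ...] | None = None,
    variant: str = "a",
    smooth: tuple[int, int] = (SAVGOL_ORDER, SAVGOL_WINDOW),
    include_nogo: bool = False,
) -> RSATimecourse:
    """Kendall tau between neural and model RDMs per participant/model/timepoint.

    ``model_rdms`` is a model-name → RDM dict shared by the cohort or one
    such dict per participant. Model RDMs are vectorized by their lower
    triangle (diagonal excluded, so a semantic RDM's nonzero self-distances
    are never consumed). Timecourses are Savitzky-Golay smoothed before group
    inference.
    """
    from eegsurprise.encoding import _per_participant_rdms

    taus = []
    times = None
    model_order_out = model_order
    for e, e_rdms in _per_participant_rdms(model_rdms, participants):
        if model_order_out is None:
            model_order_out = tuple(e_rdms)
        items = e_rdms[model_order_out[0]].items
        model_vecs = {m: lower_tri(e_rdms[m].d) for m in model_order_out}
        if times is None:
            times = e.times
        elif len(times) != len(e.times) or not np.allclose(times, e.times):
            raise EEGSurpriseError("participants must share a common time axis")
        neural = neural_rdm_timecourse(e, items, include_nogo=include_nogo)
        tc = np.empty((len(model_order_out), len(times)))
        for t in range(len(times)):
            nv = lower_tri(neural[t])
            for mi, m in enumerate(model_order_out):
                tc[mi, t] = kendall_tau(nv, model_vecs[m], variant=variant)
        taus.append(savgol_smooth(tc, order=smooth[0], window=smooth[1]))
    if not taus:
        raise EEGSurpriseError("empty participant iterable")
    tau = np.clip(np.stack(taus), -1.0, 1.0)  # smoothing can nudge past the bound
    return RSATimecourse(tau=tau, times=times, model_names=tuple(model_order_out),
                         tau_variant=variant)


def rsa_group_inference(
    tc: RSATimecourse, n_perm: int = 100_000, alpha_form: float = 0.05, seed: int = 0
) -> dict[str, ClusterResult]:
    """Cluster permutation test of each model's tau timecourse against zero."""
    return {
        m: cluster_permutation_onesample(
            tc.for_model(m), n_perm=n_perm, alpha_form=alpha_form,
            seed=seed + 2000 + i, times=tc.times,
        )
        for i, m in enumerate(tc.model_names)
    }


# ---------------------------------------------------------------------------
# Jackknife onset latency
# ---------------------------------------------------------------------------


def _onset_from_curve(
    curve: np.ndarray, times: np.ndarray, window: tuple[float, float], criterion: float
) -> float:
    """First crossing of criterion × in-window max, linearly interpolated (s)."""
    mask = (times >= window[0] - 1e-12) & (times <= window[1] + 1e-12)
    idx = np.flatnonzero(mask)
    seg = curve[idx]
    mx = seg.max()
    if mx <= 0:
        return np.nan
    thr = criterion * mx
    above = np.flatnonzero(seg >= thr)
    if above.size == 0:
        return np.nan
    i = above[0]
    if i == 0:
        return float(times[idx[0]])
    t0, t1 = times[idx[i - 1]], times[idx[i]]
    v0, v1 = seg[i - 1], seg[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (thr - v0) / (v1 - v0) * (t1 - t0))


def jackknife_onset(
    timecourses: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float] = (0.0, 0.2),
    criterion: float = 0.5,
) -> LatencyEstimate:
    """Jackknife onset latency with retransformed individual estimates.

    Onsets are measured on each leave-one-out grand average as the first
    crossing of ``criterion`` × the in-window maximum. Individual estimates
    are restored as o_i = n·ō − (n−1)·O_(−i), with ō the mean of the
    leave-one-out scores, so the restored estimates average exactly to ō.
    """
    data = np.asarray(timecourses, dtype=float)
    n = data.shape[0]
    if n < 3:
        raise EEGSurpriseError("jackknife needs at least 3 participants")
    total = data.sum(axis=0)
    loo = np.array([
        _onset_from_curve((total - data[i]) / (n - 1), times, window, criterion)
        for i in range(n)
    ])
    grand = _onset_from_curve(total / n, times, window, criterion)
    if np.all(np.isnan(loo)):
        raise EEGSurpriseError("no leave-one-out curve crosses the onset criterion")
    obar = float(np.nanmean(loo))
    restored = n * obar - (n - 1) * loo
    return LatencyEstimate(
        onsets_ms=restored * 1000.0,
        loo_onsets_ms=loo * 1000.0,
        group_mean_ms=obar * 1000.0,
        grand_average_onset_ms=float(grand * 1000.0) if np.isfinite(grand) else np.nan,
        criterion=criterion,
        window_s=tuple(window),
    )


def compare_onsets(a: LatencyEstimate, b: LatencyEstimate) -> dict:
    """Paired t-test on the retransformed individual onset estimates."""
    x, y = a.onsets_ms, b.onsets_ms
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise EEGSurpriseError("fewer than 3 complete pairs for onset comparison")
    t, p = stats.ttest_rel(x[ok], y[ok])
    diff = x[ok] - y[ok]
    return {
        "t": float(t), "p": float(p), "df": int(ok.sum() - 1),
        "mean_difference_ms": float(diff.mean()),
        "d_z": float(diff.mean() / diff.std(ddof=1)) if diff.std(ddof=1) > 0 else np.inf,
    }
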