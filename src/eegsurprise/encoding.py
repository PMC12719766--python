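"""ERP scaling analysis: trial-wise surprise regression and cluster inference.

For each participant and timepoint, single-trial ROI-averaged EEG amplitude is
regressed onto the five standardized surprise regressors; the resulting beta
timecourses (one per model) are smoothed and contrasted against zero at the
group level with one-sample cluster-based permutation tests (random
per-participant sign flips, max-|summed-t| cluster statistic over both signs).
A Shapley-value decomposition of the regression R² is provided as a control
for correlated regressors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd
from scipy import signal, stats

from eegsurprise._utils import child_rng
from eegsurprise.eeg_preprocess import Epochs, PARIETO_OCCIPITAL_ROI, roi_average
from eegsurprise.exceptions import CollinearityError, EEGSurpriseError, InferenceError
from eegsurprise.feature_models import MODEL_ORDER, RDM, build_surprise_design

#: Savitzky-Golay defaults: order 2, 9 samples (~35 ms at 256 Hz)
SAVGOL_ORDER = 2
SAVGOL_WINDOW = 9

#: permutation-test defaults
N_PERMUTATIONS = 100_000
CLUSTER_FORMING_ALPHA = 0.05


@dataclass
class BetaTimecourse:
    """Participant × model × timepoint regression coefficients."""

    betas: np.ndarray
    times: np.ndarray
    model_names: tuple[str, ...]
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.betas.ndim != 3:
            raise ValueError("betas must be (participants, models, timepoints)")
        if self.betas.shape[1] != len(self.model_names):
            raise ValueError("model axis does not match model names")
        if self.betas.shape[2] != len(self.times):
            raise ValueError("time axis does not match times")
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("non-finite beta coefficients")

    def for_model(self, name: str) -> np.ndarray:
        return self.betas[:, self.model_names.index(name), :]


@dataclass
class Cluster:
    """One suprathreshold cluster: time extent, sign, mass and p-value."""

    t_start: float
    t_end: float
    sign: int
    mass: float
    p_cluster: float
    t_extreme: float
    i_start: int
    i_end: int  # inclusive sample indices


@dataclass
class ClusterResult:
    """Cluster-permutation outcome for one model timecourse."""

    clusters: list[Cluster]
    t_max: float  # signed t at the largest |t| over all timepoints
    n_permutations: int
    threshold: float
    times: np.ndarray
    t_obs: np.ndarray = field(repr=False, default=None)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_cluster < alpha]


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------


def standardize_design(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize design columns to mean 0 / SD 1 across trials.

    Returns (standardized X, means, sds); sds are recorded so betas can be
    mapped back to the raw regressor scale.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise CollinearityError(f"constant regressor column(s): {bad.tolist()}")
    return (x - mu) / sd, mu, sd


def fit_surprise_regression(
    y: np.ndarray,
    x: pd.DataFrame | np.ndarray,
    standardize: bool = True,
) -> np.ndarray:
    """Per-timepoint OLS of single-trial amplitude on surprise regressors.

    ``y`` is (trials, timepoints), ``x`` is (trials, models). Regressors are
    standardized across trials, an intercept is included, and the returned
    (models, timepoints) coefficients exclude the intercept.
    """
    names = list(x.columns) if isinstance(x, pd.DataFrame) else None
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] != x.shape[0]:
        raise ValueError("rows of y and X must correspond")
    n, p = x.shape
    if n <= p + 1:
        raise EEGSurpriseError(f"need more trials ({n}) than regressors + 1 ({p + 1})")
    if standardize:
        x, _, _ = standardize_design(x)
    design = np.column_stack([np.ones(n), x])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        # identify dependent columns via the diagonal of R in a pivoted QR
        r = np.linalg.qr(design, mode="r")
        small = np.flatnonzero(np.abs(np.diag(r)) < 1e-8 * np.abs(np.diag(r)).max())
        cols = [names[i - 1] if names and i > 0 else f"col{i - 1}" for i in small]
        raise CollinearityError(f"rank-deficient design; dependent columns: {cols}")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef[1:]


def savgol_smooth(
    series: np.ndarray, order: int = SAVGOL_ORDER, window: int = SAVGOL_WINDOW
) -> np.ndarray:
    """Savitzky-Golay smoothing along the last axis, length preserved.

    Edges are handled by fitting the polynomial on the truncated terminal
    window (scipy's ``interp`` mode), so no padding values are invented.
    """
    series = np.asarray(series, dtype=float)
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and greater than the polynomial order")
    if series.shape[-1] < window:
        raise ValueError("series shorter than the smoothing window")
    return signal.savgol_filter(series, window_length=window, polyorder=order,
                                axis=-1, mode="interp")


# ---------------------------------------------------------------------------
# Shapley value regression
# ---------------------------------------------------------------------------


def _r2(y: np.ndarray, x: np.ndarray, cols: tuple[int, ...]) -> float:
    n = len(y)
    design = np.column_stack([np.ones(n)] + [x[:, c] for c in cols])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 0.0
    return 1.0 - float((resid**2).sum()) / tss


def shapley_r2(y: np.ndarray, x: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Shapley decomposition of the regression R² among regressors.

    Each regressor's attribution is its average incremental R² over all
    subsets (equivalently all orderings); attributions sum to the full-model
    R². Exact enumeration over 2^p subsets, hence p <= 12.
    """
    names = list(x.columns) if isinstance(x, pd.DataFrame) else None
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if p > 12:
        raise EEGSurpriseError(f"exact Shapley enumeration infeasible for p={p} > 12")
    if n <= p + 1:
        raise EEGSurpriseError("need n > p + 1 observations")
    r2_cache: dict[tuple[int, ...], float] = {(): 0.0}
    for size in range(1, p + 1):
        for cols in itertools.combinations(range(p), size):
            r2_cache[cols] = _r2(y, x, cols)
    phi = np.zeros(p)
    for j in range(p):
        others = [c for c in range(p) if c != j]
        for size in range(0, p):
            w = factorial(size) * factorial(p - size - 1) / factorial(p)
            for s in itertools.combinations(others, size):
                with_j = tuple(sorted(s + (j,)))
                phi[j] += w * (r2_cache[with_j] - r2_cache[s])
    if names:
        return pd.Series(phi, index=names).to_numpy()
    return phi


# ---------------------------------------------------------------------------
# Cluster-based permutation inference
# ---------------------------------------------------------------------------


def _clusters_1d(t: np.ndarray, thr: float) -> list[tuple[int, int, int, float, float]]:
    """Maximal suprathreshold runs: (i_start, i_end, sign, mass, t_extreme)."""
    out = []
    for sign in (1, -1):
        mask = t * sign > thr
        if not mask.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False]))))
        for a, b in zip(edges[::2], edges[1::2]):
            seg = t[a:b]
            ext = seg.max() if sign > 0 else seg.min()
            out.append((int(a), int(b - 1), sign, float(seg.sum()), float(ext)))
    out.sort(key=lambda c: c[0])
    return out


def _max_cluster_mass_rows(tmat: np.ndarray, thr: float) -> np.ndarray:
    """Per row, the maximum absolute cluster mass over both signs (0 if none)."""
    n_rows = tmat.shape[0]
    out = np.zeros(n_rows)
    for r in range(n_rows):
        masses = [abs(m) for *_, m, _ in _clusters_1d(tmat[r], thr)]
        if masses:
            out[r] = max(masses)
    return out


def _tvalues(data: np.ndarray) -> np.ndarray:
    n = data.shape[0]
    m = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    zero = sd == 0
    if np.any(zero & (m != 0)):
        raise InferenceError("degenerate variance: identical nonzero values across participants")
    sd = np.where(zero, 1.0, sd)  # 0/0 timepoints carry no evidence -> t = 0
    return m / (sd / np.sqrt(n))


def cluster_permutation_onesample(
    data: np.ndarray,
    n_perm: int = N_PERMUTATIONS,
    alpha_form: float = CLUSTER_FORMING_ALPHA,
    seed: int = 0,
    times: np.ndarray | None = None,
    _chunk: int = 2_000,
) -> ClusterResult:
    """One-sample cluster-based permutation test against zero over timepoints.

    Per timepoint a one-sample t is computed; contiguous runs beyond the
    two-tailed ``alpha_form`` t-threshold form clusters scored by their summed
    t (mass). The null distribution of the maximum |mass| (over both signs,
    one family) is built from ``n_perm`` random per-participant sign flips;
    p_cluster = (1 + #{null >= observed}) / (1 + n_perm).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise InferenceError("need a (participants >= 2, timepoints) array")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n, t_len = data.shape
    if times is None:
        times = np.arange(t_len, dtype=float)
    thr = float(stats.t.ppf(1 - alpha_form / 2, df=n - 1))
    t_obs = _tvalues(data)
    raw = _clusters_1d(t_obs, thr)

    rng = child_rng(seed, 7)
    sumsq = (data**2).sum(axis=0)
    null_max = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(_chunk, n_perm - done)
        signs = rng.integers(0, 2, size=(k, n)) * 2.0 - 1.0
        means = signs @ data / n
        var = (sumsq / n - means**2) * (n / (n - 1))
        var = np.maximum(var, 1e-300)
        t_perm = means / np.sqrt(var / n)
        null_max[done : done + k] = _max_cluster_mass_rows(t_perm, thr)
        done += k

    clusters = []
    for a, b, sign, mass, ext in raw:
        p = (1.0 + float((null_max >= abs(mass)).sum())) / (1.0 + n_perm)
        clusters.append(
            Cluster(
                t_start=float(times[a]), t_end=float(times[b]), sign=sign,
                mass=mass, p_cluster=p, t_extreme=ext, i_start=a, i_end=b,
            )
        )
    i_ext = int(np.argmax(np.abs(t_obs)))
    return ClusterResult(
        clusters=clusters, t_max=float(t_obs[i_ext]), n_permutations=n_perm,
        threshold=thr, times=np.asarray(times, dtype=float), t_obs=t_obs,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _per_participant_rdms(rdms, participants):
    """Pair each participant's epochs with their RDM dict.

    ``rdms`` may be one dict shared by the cohort or a sequence of dicts (one
    per participant, e.g. when every participant saw a unique stimulus set).
    """
    if isinstance(rdms, dict):
        for e in participants:
            yield e, rdms
    else:
        yield from zip(participants, rdms, strict=True)


def run_erp_scaling(
    participants,
    rdms,
    roi=PARIETO_OCCIPITAL_ROI,
    model_order: tuple[str, ...] = MODEL_ORDER,
    n_perm: int = N_PERMUTATIONS,
    alpha_form: float = CLUSTER_FORMING_ALPHA,
    smooth: tuple[int, int] = (SAVGOL_ORDER, SAVGOL_WINDOW),
    seed: int = 0,
) -> tuple[BetaTimecourse, dict[str, ClusterResult], dict]:
    """Full ERP scaling analysis across a cohort.

    ``participants`` is an iterable of :class:`Epochs` (consumed lazily, so a
    generator keeps memory flat); ``rdms`` is a model-name → :class:`RDM` dict
    shared by the cohort or a per-participant sequence of such dicts. Per
    participant: the surprise design is built from the trial table
    (unexpected, correct, go trials), the ROI average is regressed per
    timepoint onto the standardized regressors, and the betas are
    Savitzky-Golay smoothed. Group inference runs one cluster permutation
    test per model. Returns (betas, cluster results, provenance).
    """
    order, window = smooth
    betas = []
    times = None
    for e, e_rdms in _per_participant_rdms(rdms, participants):
        if times is None:
            times = e.times
        elif len(times) != len(e.times) or not np.allclose(times, e.times):
            raise EEGSurpriseError("participants must share a common time axis")
        x = build_surprise_design(e.trials, e_rdms, model_order=model_order)
        y = roi_average(e, roi)[x.index.to_numpy()]
        b = fit_surprise_regression(y, x)
        betas.append(savgol_smooth(b, order=order, window=window))
    if not betas:
        raise EEGSurpriseError("empty participant iterable")
    bt = BetaTimecourse(
        betas=np.stack(betas), times=times, model_names=tuple(model_order), smoothed=True
    )
    results = {
        m: cluster_permutation_onesample(
            bt.for_model(m), n_perm=n_perm, alpha_form=alpha_form,
            seed=seed + 1000 + i, times=times,
        )
        for i, m in enumerate(model_order)
    }
    provenance = {
        "n_participants": bt.betas.shape[0],
        "model_order": list(model_order),
        "roi": list(roi),
        "n_perm": n_perm,
        "alpha_form": alpha_form,
        "savgol": {"order": order, "window": window},
        "seed": seed,
        "standardized_regressors": True,
    }
    return bt, results, provenance
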