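"""Synthetic cohorts with planted effects for every pipeline stage.

The generator emulates the study design end to end: feature banks whose RDMs
have a controlled cross-layer correlation, word embeddings with a cluster
structure, cue→image trial sequences, behavioral responses with condition-wise
RT/accuracy, and EEG epochs combining

* a shared evoked template (P1/N1/P2-like bumps),
* stimulus-specific topographies whose pattern geometry follows a weighted
  mixture of model RDMs (exact-correlation construction with PSD repair),
* an ROI-projected amplitude increment on unexpected trials proportional to
  the planted per-model surprise coefficients inside their planted windows,
* AR(1) + white Gaussian noise.

All randomness derives from a single seed through named streams, so identical
specs yield bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from eegsurprise._utils import (
    child_rng,
    lower_tri,
    nearest_psd_correlation,
    patterns_from_similarity,
    squareform_from_lower,
)
from eegsurprise.design import (
    StimulusSet,
    build_transition_matrix,
    generate_session,
    label_response_congruency,
)
from eegsurprise.eeg_preprocess import Epochs, PARIETO_OCCIPITAL_ROI
from eegsurprise.encoding import standardize_design
from eegsurprise.exceptions import GeneratorError
from eegsurprise.feature_models import (
    MODEL_ORDER,
    RDM,
    WordCluster,
    animacy_rdm,
    build_surprise_design,
    compute_rdm,
    semantic_rdm,
)

_FILLER_PREFIX = "CH"


def default_channels(n_channels: int) -> list[str]:
    """ROI electrodes first, then EOG, then generic filler channels."""
    base = list(PARIETO_OCCIPITAL_ROI) + ["VEOG", "HEOG"]
    if n_channels < len(base):
        raise ValueError(f"need at least {len(base)} channels")
    return base + [f"{_FILLER_PREFIX}{i:02d}" for i in range(n_channels - len(base))]


@dataclass
class GeneratorSpec:
    """Study-scale defaults for the synthetic cohort.

    The defaults mirror the study design: 38 participants, 8 EEG blocks of 128
    trials, 64 channels at 256 Hz, epochs −0.8–1.0 s around image onset, a
    planted high-level-surprise amplitude modulation in the 188–262 ms window,
    and condition-wise RT/accuracy targets of 511/516/526 ms and
    96.4/96.1/95.1%.
    """

    n_participants: int = 38
    n_blocks: int = 8
    n_channels: int = 64
    sfreq: float = 256.0
    epoch_window: tuple[float, float] = (-0.8, 1.0)
    n_items: int = 8
    n_pairs_ratio_nogo: tuple[int, int, int] = (8, 7, 16)
    feature_dims: dict = field(
        default_factory=lambda: {"lowlevel": 200, "highlevel": 120, "untrained": 120}
    )
    target_cross_rdm_corr: float = 0.0
    planted_beta: dict = field(
        default_factory=lambda: {"highlevel": (0.5, (0.188, 0.262))}
    )
    geometry_mixture: dict = field(
        default_factory=lambda: {"lowlevel": 0.5, "highlevel": 0.5}
    )
    geometry_window: tuple[float, float] = (0.10, 0.40)
    pattern_amp_uv: float = 3.0
    noise: tuple[float, float] = (0.3, 5.0)  # (AR(1) coefficient, stationary SD µV)
    rt_model: dict = field(
        default_factory=lambda: {
            "expected": (511.0, 120.0),
            "unexpected_same_response": (516.0, 120.0),
            "unexpected_different_response": (526.0, 120.0),
        }
    )
    accuracy: dict = field(
        default_factory=lambda: {
            "expected": 0.964,
            "unexpected_same_response": 0.961,
            "unexpected_different_response": 0.951,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        t0, t1 = self.epoch_window
        for name, (_, (w0, w1)) in self.planted_beta.items():
            if not (t0 <= w0 < w1 <= t1):
                raise ValueError(f"planted window for {name!r} outside the epoch")
        if any(w < 0 for w in self.geometry_mixture.values()):
            raise ValueError("geometry mixture weights must be >= 0")
        if self.noise[1] <= 0:
            raise ValueError("noise SD must be > 0")

    def fast(self, **overrides) -> "GeneratorSpec":
        """Reduced-scale profile for quick runs: 8 participants, 2 blocks."""
        base = dict(n_participants=8, n_blocks=2)
        base.update(overrides)
        return replace(self, **base)

    @property
    def times(self) -> np.ndarray:
        t0, t1 = self.epoch_window
        n = int(round((t1 - t0) * self.sfreq)) + 1
        return t0 + np.arange(n) / self.sfreq


# ---------------------------------------------------------------------------
# Feature banks and embeddings
# ---------------------------------------------------------------------------


def synth_feature_bank(
    n_items: int = 8,
    dims: dict | None = None,
    target_cross_rdm_corr: float = 0.0,
    seed: int = 0,
    tol: float = 0.1,
    max_iter: int = 50,
) -> StimulusSet:
    """Two feature layers with a controlled cross-layer RDM correlation.

    The low-level RDM comes from random features. The high-level RDM's lower
    triangle is constructed as an exact linear blend of the (standardized)
    low-level triangle and an orthogonalized random component, mapped back to
    distances in (0, 2); features realizing it exactly are drawn via a
    Cholesky construction on the implied similarity matrix (PSD-repaired if
    needed, with the achieved correlation re-checked against ``tol``). A
    random-feature untrained control layer is always included.
    """
    if n_items < 3:
        raise GeneratorError("need at least 3 items")
    if not -1.0 <= target_cross_rdm_corr <= 1.0:
        raise GeneratorError("target correlation must be in [-1, 1]")
    dims = dims or {"lowlevel": 200, "highlevel": 120, "untrained": 120}
    rng = child_rng(seed, 10)
    ids = [f"img{i + 1:02d}" for i in range(n_items)]
    animacy = np.array([1] * (n_items // 2) + [0] * (n_items - n_items // 2))

    low = rng.standard_normal((n_items, dims["lowlevel"]))
    d_low = compute_rdm(low, items=ids).d
    v_low = lower_tri(d_low)

    z1 = (v_low - v_low.mean()) / v_low.std()
    for attempt in range(max_iter):
        noise = rng.standard_normal(v_low.size)
        noise -= noise.mean()
        noise -= (noise @ z1) / (z1 @ z1) * z1  # orthogonalize exactly
        z2 = noise / noise.std()
        t = target_cross_rdm_corr
        v_high_std = t * z1 + np.sqrt(max(0.0, 1.0 - t**2)) * z2
        v_high = 1.0 + 0.3 * v_high_std  # distances centered at 1, spread 0.3
        v_high = np.clip(v_high, 0.02, 1.98)
        s_high = nearest_psd_correlation(1.0 - squareform_from_lower(v_high, n_items))
        high, _ = patterns_from_similarity(s_high, dims["highlevel"], rng)
        achieved = float(np.corrcoef(lower_tri(compute_rdm(high, items=ids).d), v_low)[0, 1])
        if abs(achieved - target_cross_rdm_corr) <= tol:
            break
    else:
        raise GeneratorError(
            f"cross-RDM correlation target {target_cross_rdm_corr} not met within "
            f"±{tol} after {max_iter} attempts (last achieved {achieved:.3f})"
        )
    untrained = rng.standard_normal((n_items, dims["untrained"]))
    return StimulusSet(
        ids=ids,
        animacy=animacy,
        feature_bank={"lowlevel": low, "highlevel": high, "untrained": untrained},
    )


def synth_embeddings(
    labels: list[str],
    words_per_cluster: int = 5,
    dim: int = 50,
    within_spread: float = 0.1,
    between_spread: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[WordCluster]]:
    """Cluster-structured word embeddings as a stand-in vocabulary.

    Cluster centroids are unit vectors scaled by ``between_spread`` (nearly
    orthogonal in high dimension); members jitter around their centroid with
    isotropic noise of scale ``within_spread``. Returns the embedding table
    (word-indexed) and the corresponding clusters.
    """
    if within_spread <= 0 or between_spread <= 0:
        raise GeneratorError("spreads must be > 0")
    rng = child_rng(seed, 11)
    rows, index, clusters = [], [], []
    for label in labels:
        c = rng.standard_normal(dim)
        c = c / np.linalg.norm(c) * between_spread
        members = [label] + [f"{label}_rel{k}" for k in range(1, words_per_cluster)]
        for w in members:
            v = c + within_spread * rng.standard_normal(dim)
            rows.append(v)
            index.append(w)
        clusters.append(WordCluster(label=label, members=members))
    return pd.DataFrame(np.array(rows), index=index), clusters


def build_model_rdms(
    stimuli: StimulusSet,
    embeddings: pd.DataFrame | None = None,
    clusters: list[WordCluster] | None = None,
    seed: int = 0,
) -> dict[str, RDM]:
    """The five model RDMs for a stimulus set (semantic from embeddings)."""
    if embeddings is None or clusters is None:
        embeddings, clusters = synth_embeddings(list(stimuli.ids), seed=seed)
    sem = semantic_rdm(clusters, embeddings)
    sem = RDM(items=list(stimuli.ids), d=sem.d, metric_tag=sem.metric_tag,
              self_distance=True)
    return {
        "lowlevel": compute_rdm(stimuli.feature_bank["lowlevel"], items=stimuli.ids),
        "highlevel": compute_rdm(stimuli.feature_bank["highlevel"], items=stimuli.ids),
        "semantic": sem,
        "task": animacy_rdm(stimuli.animacy, list(stimuli.ids)),
        "untrained": compute_rdm(stimuli.feature_bank["untrained"], items=stimuli.ids),
    }


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def synth_behavior(
    spec: GeneratorSpec, trials: pd.DataFrame, animacy: dict[str, int], seed: int = 0
) -> pd.DataFrame:
    """Fill responses, correctness and RTs into a labeled trial table.

    RTs are lognormal with the condition's target mean/SD; correctness is
    Bernoulli with the condition's target accuracy. No-go trials get response
    "none" (correct withhold). Incorrect go responses get the wrong animacy
    button and no RT exclusion handling here (that is the analysis's job).
    """
    rng = child_rng(spec.seed, 20, seed)
    out = label_response_congruency(trials, animacy)
    n = len(out)
    responses, corrects, rts = [], [], []
    for _, row in out.iterrows():
        if row["nogo"]:
            responses.append("none")
            corrects.append(True)
            rts.append(np.nan)
            continue
        cond = row["expectedness"]
        acc = spec.accuracy.get(cond, 0.95)
        mean, sd = spec.rt_model.get(cond, (520.0, 120.0))
        mu, sigma = _lognormal_params(mean, sd)
        correct = bool(rng.random() < acc)
        truth = "animate" if animacy[row["image"]] == 1 else "inanimate"
        wrong = "inanimate" if truth == "animate" else "animate"
        responses.append(truth if correct else wrong)
        corrects.append(correct)
        rts.append(float(rng.lognormal(mu, sigma)))
    out["response"] = responses
    out["correct"] = pd.array(corrects, dtype="boolean")
    out["rt_ms"] = rts
    return out


# ---------------------------------------------------------------------------
# EEG epochs
# ---------------------------------------------------------------------------


def _evoked_template(times: np.ndarray) -> np.ndarray:
    """Shared evoked timecourse: P1/N1/P2-like Gaussian bumps (µV)."""
    bumps = ((2.0, 0.100, 0.015), (-2.5, 0.160, 0.020), (3.0, 0.220, 0.030))
    out = np.zeros_like(times)
    for amp, mu, sigma in bumps:
        out += amp * np.exp(-0.5 * ((times - mu) / sigma) ** 2)
    return out


def _band_limited_boxcar(
    times: np.ndarray, window: tuple[float, float], sfreq: float
) -> np.ndarray:
    """Unit boxcar over ``window`` restricted to the 1-60 Hz analysis band.

    Recorded scalp EEG carries no energy below the acquisition high-pass, so
    planted modulations are emitted band-limited; this keeps the planted
    effect invariant under the pipeline's own band-pass step.
    """
    from scipy.signal import filtfilt

    from eegsurprise.eeg_preprocess import _fir_kernel

    kernel = _fir_kernel(1.0, min(60.0, sfreq / 2 * 0.9), sfreq)
    margin = len(kernel)
    n = len(times)
    ext_times = times[0] + (np.arange(n + 2 * margin) - margin) / sfreq
    box = ((ext_times >= window[0]) & (ext_times <= window[1])).astype(float)
    filtered = filtfilt(kernel, [1.0], box, padlen=0)
    return filtered[margin : margin + n]


def effect_window_gain(spec: GeneratorSpec, model: str) -> float:
    """Mean of the realized (band-limited) effect profile inside its window.

    The scale bookkeeping needed to compare window-averaged recovered betas
    with the planted coefficient.
    """
    _, window = spec.planted_beta[model]
    times = spec.times
    prof = _band_limited_boxcar(times, window, spec.sfreq)
    mask = (times >= window[0]) & (times <= window[1])
    return float(prof[mask].mean())


def _roi_contrast_topography(channels: list[str]) -> np.ndarray:
    """Zero-mean topography: +1 on ROI electrodes, compensated elsewhere.

    Zero channel-mean makes planted effects invariant under average
    referencing; the ROI average of this topography is exactly 1 (EOG
    channels carry no signal).
    """
    topo = np.zeros(len(channels))
    roi = [i for i, c in enumerate(channels) if c in PARIETO_OCCIPITAL_ROI]
    rest = [
        i for i, c in enumerate(channels)
        if c not in PARIETO_OCCIPITAL_ROI and "EOG" not in c
    ]
    topo[roi] = 1.0
    if rest:
        topo[rest] = -len(roi) / len(rest)
    return topo


def _ar1_noise(
    rng: np.random.Generator, shape: tuple[int, ...], coef: float, sd: float
) -> np.ndarray:
    innov_sd = sd * np.sqrt(1.0 - coef**2) if abs(coef) < 1 else sd
    white = rng.standard_normal(shape) * innov_sd
    return sps.lfilter([1.0], [1.0, -coef], white, axis=-1)


def synth_participant_epochs(
    spec: GeneratorSpec,
    trials: pd.DataFrame,
    rdms: dict[str, RDM],
    participant: int,
) -> Epochs:
    """Epochs for one participant with planted geometry and surprise scaling."""
    rng = child_rng(spec.seed, 30, participant)
    times = spec.times
    channels = default_channels(spec.n_channels)
    n_ch, n_t, n_trials = len(channels), len(times), len(trials)
    items = rdms[MODEL_ORDER[0]].items

    data = np.zeros((n_trials, n_ch, n_t))

    # shared evoked template on a zero-mean scalp topography
    evoked_topo = _roi_contrast_topography(channels)
    data += _evoked_template(times)[None, None, :] * evoked_topo[None, :, None]

    # stimulus-specific geometry: patterns over non-EOG channels with pairwise
    # correlations following the RDM mixture
    weights = {m: w for m, w in spec.geometry_mixture.items() if w > 0}
    if weights:
        total = sum(weights.values())
        d_mix = sum(w * rdms[m].d for m, w in weights.items()) / total
        np.fill_diagonal(d_mix, 0.0)
        sim = 1.0 - d_mix
        scalp = np.array([i for i, c in enumerate(channels) if "EOG" not in c])
        pats, _ = patterns_from_similarity(sim, len(scalp), rng)
        pats *= spec.pattern_amp_uv * np.sqrt(len(scalp))  # unit-norm rows → per-channel scale
        g0, g1 = spec.geometry_window
        env = np.clip(np.sin(np.pi * (times - g0) / max(g1 - g0, 1e-9)), 0.0, None)
        env *= (times >= g0) & (times <= g1)
        item_ix = {item: i for i, item in enumerate(items)}
        rows = np.array([item_ix[i] for i in trials["image"]])
        data[:, scalp, :] += pats[rows][:, :, None] * env[None, None, :]

    # planted surprise scaling on unexpected correct go trials
    if spec.planted_beta:
        x = build_surprise_design(trials, rdms)
        xz, _, _ = standardize_design(x.to_numpy())
        topo = _roi_contrast_topography(channels)
        for mi, m in enumerate(MODEL_ORDER):
            if m not in spec.planted_beta:
                continue
            beta, window = spec.planted_beta[m]
            prof = _band_limited_boxcar(times, window, spec.sfreq)
            amp = beta * xz[:, list(x.columns).index(m)]
            data[x.index.to_numpy()] += (
                amp[:, None, None] * topo[None, :, None] * prof[None, None, :]
            )

    coef, sd = spec.noise
    data += _ar1_noise(rng, (n_trials, n_ch, n_t), coef, sd)
    return Epochs(data=data, times=times, sfreq=spec.sfreq, channels=channels,
                  trials=trials.reset_index(drop=True))


def synth_epochs(spec: GeneratorSpec, trials_per_participant, rdms):
    """Yield per-participant epochs for given trial tables and RDMs.

    ``rdms`` is one model-name → RDM dict shared by everyone or a sequence of
    such dicts aligned with the trial tables.
    """
    for p, trials in enumerate(trials_per_participant):
        e_rdms = rdms if isinstance(rdms, dict) else rdms[p]
        yield synth_participant_epochs(spec, trials, e_rdms, p)


def synth_cohort(spec: GeneratorSpec, lazy: bool = True):
    """Generate the full synthetic study.

    Returns ``(stimuli, rdms, trials_per_participant, epochs)``; the first
    three are per-participant lists and ``epochs`` is a generator over
    participants when ``lazy`` (keeps memory flat at study scale) or a list
    otherwise. As in the emulated design, every participant gets a unique
    stimulus set (hence unique RDMs): chance correlations between model RDMs
    then vary across participants instead of biasing the whole group.
    """
    stimuli_all, rdms_all, trials_all = [], [], []
    n_pairs, ratio, nogo = spec.n_pairs_ratio_nogo
    for p in range(spec.n_participants):
        stimuli = synth_feature_bank(
            n_items=spec.n_items, dims=spec.feature_dims,
            target_cross_rdm_corr=spec.target_cross_rdm_corr,
            seed=spec.seed * 10_000 + p,
        )
        rdms = build_model_rdms(stimuli, seed=spec.seed * 10_000 + p)
        animacy = dict(zip(stimuli.ids, stimuli.animacy.tolist()))
        tm = build_transition_matrix(n_pairs, ratio, nogo,
                                     images=list(stimuli.ids),
                                     seed=spec.seed * 10_000 + p)
        t = generate_session(tm, n_blocks=spec.n_blocks, seed=spec.seed * 1_000 + p)
        t = synth_behavior(spec, t, animacy, seed=p)
        t["participant"] = p
        stimuli_all.append(stimuli)
        rdms_all.append(rdms)
        trials_all.append(t)

    def epoch_iter():
        for p in range(spec.n_participants):
            yield synth_participant_epochs(spec, trials_all[p], rdms_all[p], p)

    epochs = epoch_iter() if lazy else list(epoch_iter())
    return stimuli_all, rdms_all, trials_all, epochs
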