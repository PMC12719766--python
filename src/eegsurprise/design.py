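"""Experimental design: stimulus-set selection and cue→image trial sequences.

The paradigm pairs one-letter cues with object images. Each cue predicts its
associated image with 7:1 odds against any specific other image, so images are
*expected* when preceded by their own cue and *unexpected* otherwise. Vowel
cues mark no-go trials. One block realizes the transition-count matrix exactly:
with 8 cue-image pairs and ratio 7, a block holds 56 expected + 56 unexpected
go trials plus 16 no-go trials (128 total).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from eegsurprise._utils import child_rng, lower_tri
from eegsurprise.exceptions import (
    DegenerateInputError,
    DesignInfeasibleError,
    SequencingError,
)

VOWELS = ("a", "e", "i", "o", "u")
CONSONANTS = tuple(c for c in "bcdfghjklmnpqrstvwxz")

#: fixed column order for serialized trial tables
TRIAL_COLUMNS = (
    "block",
    "trial",
    "cue",
    "image",
    "expected_image",
    "expectedness",
    "nogo",
    "response",
    "correct",
    "rt_ms",
)


@dataclass
class StimulusSet:
    """A set of stimulus items with animacy labels and per-model feature matrices.

    ``feature_bank`` maps a model name (e.g. ``"lowlevel"``) to an
    (n_items, n_dims) activation matrix whose rows follow ``ids``.
    """

    ids: list[str]
    animacy: np.ndarray  # per-item binary label, animate = 1
    feature_bank: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.animacy = np.asarray(self.animacy, dtype=int)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("stimulus ids must be unique")
        if len(self.animacy) != len(self.ids):
            raise ValueError("animacy labels must match ids")
        for name, mat in self.feature_bank.items():
            if np.asarray(mat).shape[0] != len(self.ids):
                raise ValueError(f"feature matrix {name!r} row count != n items")

    @property
    def n_items(self) -> int:
        return len(self.ids)

    def subset(self, indices: list[int]) -> "StimulusSet":
        idx = list(indices)
        return StimulusSet(
            ids=[self.ids[i] for i in idx],
            animacy=self.animacy[idx],
            feature_bank={k: np.asarray(v)[idx] for k, v in self.feature_bank.items()},
        )


@dataclass
class TransitionMatrix:
    """Per-block cue × image trial counts plus the cue→expected-image map."""

    counts: np.ndarray  # (n_cues, n_images) integer counts per block
    nogo_count: int
    cues: list[str]
    images: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)

    @property
    def cue_image_map(self) -> dict[str, str]:
        """Bijection cue → associated (expected) image: the diagonal."""
        return {c: self.images[i] for i, c in enumerate(self.cues)}

    @property
    def n_go_trials(self) -> int:
        return int(self.counts.sum())

    @property
    def n_trials(self) -> int:
        return self.n_go_trials + self.nogo_count


def build_transition_matrix(
    n_pairs: int = 8,
    ratio: int = 7,
    nogo_count: int = 16,
    images: list[str] | None = None,
    cues: list[str] | None = None,
    seed: int = 0,
) -> TransitionMatrix:
    """Build the per-block transition-count matrix.

    The diagonal (expected pairings) holds ``ratio`` trials per block, every
    off-diagonal (unexpected) cell holds one, so each image is ``ratio`` times
    more likely to follow its associated cue than any other image. Go cues are
    ``n_pairs`` seeded-random consonants unless given explicitly.
    """
    if n_pairs < 2:
        raise ValueError("need at least two cue-image pairs")
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if nogo_count < 0:
        raise ValueError("nogo_count must be >= 0")
    if images is None:
        images = [f"img{i + 1:02d}" for i in range(n_pairs)]
    if cues is None:
        rng = child_rng(seed, 1)
        cues = list(rng.choice(CONSONANTS, size=n_pairs, replace=False))
    if len(cues) != n_pairs or len(images) != n_pairs:
        raise ValueError("cues and images must both have length n_pairs")
    counts = np.ones((n_pairs, n_pairs), dtype=int)
    np.fill_diagonal(counts, ratio)
    return TransitionMatrix(counts=counts, nogo_count=nogo_count, cues=cues, images=images)


def _trial_pool(tm: TransitionMatrix, rng: np.random.Generator) -> list[tuple]:
    """Expand counts into (cue, image, expected_image, expectedness, nogo) tuples."""
    pool = []
    for i, cue in enumerate(tm.cues):
        expected = tm.images[i]
        for j, image in enumerate(tm.images):
            for _ in range(int(tm.counts[i, j])):
                kind = "expected" if i == j else "unexpected"
                pool.append((cue, image, expected, kind, False))
    # No-go trials: vowel cues carry no image prediction. Images cycle so each
    # appears (nearly) equally often; vowels are drawn at random.
    order = rng.permutation(len(tm.images))
    for k in range(tm.nogo_count):
        cue = str(rng.choice(VOWELS))
        image = tm.images[order[k % len(tm.images)]]
        pool.append((cue, image, "", "nogo", True))
    return pool


def generate_block_sequence(
    tm: TransitionMatrix,
    seed: int = 0,
    block: int = 0,
    max_retries: int = 10_000,
) -> pd.DataFrame:
    """Randomize one block realizing ``tm`` exactly, no consecutive (cue, image) repeat.

    Rejection sampling: shuffle the full trial pool and accept the first
    permutation in which no two adjacent trials (of any type, no-go included)
    share the same (cue, image) pair.
    """
    rng = child_rng(seed, 2, block)
    pool = _trial_pool(tm, rng)
    n = len(pool)
    for attempt in range(max_retries):
        order = list(rng.permutation(n))
        pairs = [(pool[k][0], pool[k][1]) for k in order]
        # repair adjacent duplicates by swapping into a conflict-free slot;
        # pure rejection is hopeless for heavy diagonals (behavioral blocks)
        for _ in range(10 * n):
            dup = next((k for k in range(n - 1) if pairs[k] == pairs[k + 1]), None)
            if dup is None:
                break
            for j in rng.permutation(n):
                if abs(j - dup) <= 1:
                    continue
                ok_here = pairs[j] != pairs[dup - 1] if dup > 0 else True
                ok_here &= pairs[j] != pairs[dup + 1]
                ok_there = pairs[dup] != pairs[j - 1] if j > 0 else True
                if j + 1 < n:
                    ok_there &= pairs[dup] != pairs[j + 1]
                if ok_here and ok_there:
                    order[dup], order[j] = order[j], order[dup]
                    pairs[dup], pairs[j] = pairs[j], pairs[dup]
                    break
            else:
                break  # no repair slot found; reshuffle
        if all(pairs[k] != pairs[k + 1] for k in range(n - 1)):
            rows = [pool[k] for k in order]
            df = pd.DataFrame(
                rows, columns=["cue", "image", "expected_image", "expectedness", "nogo"]
            )
            df.insert(0, "trial", np.arange(n))
            df.insert(0, "block", block)
            df["response"] = ""
            df["correct"] = pd.array([pd.NA] * n, dtype="boolean")
            df["rt_ms"] = np.nan
            return df[list(TRIAL_COLUMNS)]
    raise SequencingError(
        f"no-consecutive-repeat constraint unsatisfied after {max_retries} shuffles"
    )


def generate_session(
    tm: TransitionMatrix, n_blocks: int = 8, seed: int = 0
) -> pd.DataFrame:
    """Concatenate ``n_blocks`` independently randomized blocks."""
    blocks = [generate_block_sequence(tm, seed=seed, block=b) for b in range(n_blocks)]
    return pd.concat(blocks, ignore_index=True)


def label_response_congruency(
    trials: pd.DataFrame, animacy: dict[str, int]
) -> pd.DataFrame:
    """Split unexpected trials by response congruency with the expected image.

    An unexpected image whose animacy (hence required button) matches the
    expected image's animacy becomes ``unexpected_same_response``, otherwise
    ``unexpected_different_response``. Expected and no-go trials pass through.
    """
    out = trials.copy()
    labels = []
    for _, row in out.iterrows():
        kind = row["expectedness"]
        if not str(kind).startswith("unexpected"):
            labels.append(kind)
            continue
        for key in (row["image"], row["expected_image"]):
            if key not in animacy:
                raise DesignInfeasibleError(f"missing animacy label for {key!r}")
        same = animacy[row["image"]] == animacy[row["expected_image"]]
        labels.append("unexpected_same_response" if same else "unexpected_different_response")
    out["expectedness"] = labels
    return out


# ---------------------------------------------------------------------------
# Stimulus-set selection
# ---------------------------------------------------------------------------


def _subset_objective_terms(
    candidates: StimulusSet, subset: tuple[int, ...], layer_names: tuple[str, str]
) -> tuple[float, float, float]:
    """Raw objective terms for one subset: (var_low, var_high, |corr|)."""
    # local import avoids a circular import at module load
    from eegsurprise.feature_models import compute_rdm

    rdms = []
    for layer in layer_names:
        feats = np.asarray(candidates.feature_bank[layer])[list(subset)]
        rdms.append(compute_rdm(feats, items=[candidates.ids[i] for i in subset]))
    v_low = float(np.var(lower_tri(rdms[0].d)))
    v_high = float(np.var(lower_tri(rdms[1].d)))
    a, b = lower_tri(rdms[0].d), lower_tri(rdms[1].d)
    if np.std(a) == 0 or np.std(b) == 0:
        raise DegenerateInputError("constant RDM in candidate subset; correlation undefined")
    corr = float(np.corrcoef(a, b)[0, 1])
    return v_low, v_high, abs(corr)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    return np.zeros_like(x) if sd == 0 else (x - np.mean(x)) / sd


def select_stimuli(
    candidates: StimulusSet,
    layer_names: tuple[str, str] = ("lowlevel", "highlevel"),
    n: int = 8,
    seed: int = 0,
    max_exhaustive: int = 10_000,
    n_random_starts: int = 200,
) -> StimulusSet:
    """Select ``n`` items (half animate, half inanimate) optimizing RDM structure.

    The composite objective is J = z(var RDM_low) + z(var RDM_high)
    - z(|corr(RDM_low, RDM_high)|), with variances over off-diagonal RDM
    entries, the correlation over vectorized lower triangles, and z-scores
    taken across all evaluated subsets. Subsets are enumerated exhaustively
    when there are at most ``max_exhaustive`` admissible ones, otherwise a
    seeded random search with single-swap hill climbing is used.
    """
    if n % 2:
        raise ValueError("n must be even (balanced animacy classes)")
    for layer in layer_names:
        if layer not in candidates.feature_bank:
            raise DesignInfeasibleError(f"candidates lack features for layer {layer!r}")
        feats = np.asarray(candidates.feature_bank[layer], dtype=float)
        if np.allclose(feats.std(axis=1), 0):
            raise DegenerateInputError(f"constant feature matrix for layer {layer!r}")
    animate = np.flatnonzero(candidates.animacy == 1)
    inanimate = np.flatnonzero(candidates.animacy == 0)
    half = n // 2
    if len(animate) < half or len(inanimate) < half:
        raise DesignInfeasibleError(
            f"need >= {half} candidates per animacy class, have "
            f"{len(animate)} animate / {len(inanimate)} inanimate"
        )

    from math import comb

    n_subsets = comb(len(animate), half) * comb(len(inanimate), half)
    if n_subsets <= max_exhaustive:
        subsets = [
            tuple(sorted(a + b))
            for a in itertools.combinations(animate.tolist(), half)
            for b in itertools.combinations(inanimate.tolist(), half)
        ]
    else:
        subsets = _hill_climb_pool(
            candidates, layer_names, animate, inanimate, half, seed, n_random_starts
        )

    if len(subsets) == 1:
        return candidates.subset(list(subsets[0]))

    terms = np.array(
        [_subset_objective_terms(candidates, s, layer_names) for s in subsets]
    )
    j = _zscore(terms[:, 0]) + _zscore(terms[:, 1]) - _zscore(terms[:, 2])
    best = subsets[int(np.argmax(j))]
    return candidates.subset(list(best))


def _hill_climb_pool(
    candidates: StimulusSet,
    layer_names: tuple[str, str],
    animate: np.ndarray,
    inanimate: np.ndarray,
    half: int,
    seed: int,
    n_random_starts: int,
) -> list[tuple[int, ...]]:
    """Random starts + single-item swap hill climbing on a pre-z-scoring proxy.

    Because z-scores are taken over evaluated subsets, hill climbing uses the
    raw terms standardized over an initial random sample; all subsets visited
    are returned so the final z-scored ranking covers them.
    """
    rng = child_rng(seed, 3)
    visited: dict[tuple[int, ...], tuple[float, float, float]] = {}

    def evaluate(s: tuple[int, ...]) -> tuple[float, float, float]:
        if s not in visited:
            visited[s] = _subset_objective_terms(candidates, s, layer_names)
        return visited[s]

    def sample() -> tuple[int, ...]:
        a = rng.choice(animate, size=half, replace=False)
        b = rng.choice(inanimate, size=half, replace=False)
        return tuple(sorted(a.tolist() + b.tolist()))

    pool = {sample() for _ in range(n_random_starts)}
    for s in list(pool):
        evaluate(s)
    terms = np.array(list(visited.values()))
    mu, sd = terms.mean(axis=0), terms.std(axis=0)
    sd[sd == 0] = 1.0

    def proxy(s: tuple[int, ...]) -> float:
        t = np.asarray(evaluate(s))
        z = (t - mu) / sd
        return float(z[0] + z[1] - z[2])

    best = max(pool, key=proxy)
    improved = True
    while improved:
        improved = False
        current = set(best)
        for i in best:
            cls = animate if candidates.animacy[i] == 1 else inanimate
            for j in cls:
                if int(j) in current:
                    continue
                trial = tuple(sorted((current - {i}) | {int(j)}))
                if proxy(trial) > proxy(best):
                    best, improved = trial, True
                    current = set(best)
                    break
            if improved:
                break
    return list(visited.keys())


# ---------------------------------------------------------------------------
# Trial-table serialization
# ---------------------------------------------------------------------------


def save_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as delimited text with the fixed column header."""
    trials[list(TRIAL_COLUMNS)].to_csv(path, index=False)


def load_trials(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"cue": str, "image": str, "expected_image": str, "response": str},
        keep_default_na=False, na_values=[""],
    )
    df["nogo"] = df["nogo"].astype(bool)
    df["correct"] = df["correct"].astype("boolean")
    df["expected_image"] = df["expected_image"].fillna("")
    df["response"] = df["response"].fillna("")
    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    return df[list(TRIAL_COLUMNS) + [c for c in df.columns if c not in TRIAL_COLUMNS]]
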