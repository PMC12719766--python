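"""Model RDMs and trial-wise surprise extraction.

Five model RDMs describe the stimulus set at different levels: low-level
visual (early DNN layer), high-level visual (late DNN layer), semantic
(word-embedding clusters), task (animacy category), and an untrained-network
control. The *surprise* of an unexpected trial under a model is the RDM
distance between the image the cue predicted and the image actually shown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from eegsurprise._utils import lower_tri
from eegsurprise.exceptions import (
    AlignmentError,
    DegenerateInputError,
    EEGSurpriseError,
    ItemLookupError,
)

#: canonical regressor order used by every downstream stage
MODEL_ORDER = ("lowlevel", "highlevel", "semantic", "task", "untrained")


@dataclass
class RDM:
    """Symmetric item × item dissimilarity matrix.

    ``self_distance`` flags matrices whose diagonal is a defined nonzero
    within-category distance (the semantic RDM) rather than identically zero.
    """

    items: list[str]
    d: np.ndarray
    metric_tag: str = ""
    self_distance: bool = False

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.items)
        if self.d.shape != (n, n):
            raise ValueError("RDM shape must match item count")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")

    @property
    def n_items(self) -> int:
        return len(self.items)

    def index(self, item: str) -> int:
        try:
            return self.items.index(item)
        except ValueError:
            raise ItemLookupError(f"item {item!r} not in RDM") from None

    def lookup(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    def lower_tri(self) -> np.ndarray:
        """Lower triangle excluding diagonal, row-major (package convention)."""
        return lower_tri(self.d)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.d, index=self.items, columns=self.items).to_csv(path)

    @classmethod
    def from_csv(cls, path, metric_tag: str = "") -> "RDM":
        df = pd.read_csv(path, index_col=0)
        return cls(items=[str(c) for c in df.columns], d=df.to_numpy(), metric_tag=metric_tag)


def compute_rdm(
    features: np.ndarray, items: list[str] | None = None, metric_tag: str = "pearson"
) -> RDM:
    """Pearson correlation-distance RDM: d[i, j] = 1 - r(row_i, row_j).

    Each item's feature row must have nonzero variance; the diagonal is
    exactly zero.
    """
    feats = np.asarray(features, dtype=float)
    if feats.ndim != 2 or feats.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two items")
    if items is None:
        items = [f"item{i}" for i in range(feats.shape[0])]
    sd = feats.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateInputError(
            f"zero-variance feature rows for items: {[items[i] for i in bad]}"
        )
    d = 1.0 - np.corrcoef(feats)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return RDM(items=list(items), d=d, metric_tag=metric_tag)


def average_rdms(rdms: list[RDM]) -> RDM:
    """Element-wise mean of RDMs sharing an identical item order.

    Used to average the RDMs of multiple trained network instances so results
    do not hinge on one random weight initialization.
    """
    if not rdms:
        raise ValueError("empty RDM list")
    items = rdms[0].items
    for r in rdms[1:]:
        if r.items != items:
            raise AlignmentError("RDM item orders differ; refusing to average")
    d = np.mean([r.d for r in rdms], axis=0)
    return RDM(items=list(items), d=d, metric_tag=rdms[0].metric_tag,
               self_distance=rdms[0].self_distance)


# ---------------------------------------------------------------------------
# Word-embedding semantics
# ---------------------------------------------------------------------------


@dataclass
class WordCluster:
    """A category label plus its k most related terms (label included)."""

    label: str
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("cluster members must be unique")
        if self.label not in self.members:
            raise ValueError("label must be a member of its own cluster")


def _embedding_matrix(embeddings: pd.DataFrame, words: list[str]) -> np.ndarray:
    missing = [w for w in words if w not in embeddings.index]
    if missing:
        raise ItemLookupError(f"words not in embedding vocabulary: {missing}")
    return embeddings.loc[words].to_numpy(dtype=float)


def _cosine_similarity(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise DegenerateInputError("cosine similarity undefined for zero vectors")
    return (a @ b.T) / np.outer(na, nb)


def build_word_cluster(
    label: str,
    embeddings: pd.DataFrame,
    excluded_labels: list[str] = (),
    k: int = 4,
    exclude_members: dict[str, list[str]] | None = None,
) -> WordCluster:
    """Form a cluster of the label plus its ``k`` nearest words by cosine similarity.

    Other category labels are never admitted. By default only the *labels*
    themselves are barred; pass ``exclude_members`` (label → already-chosen
    members) to additionally bar other categories' cluster members.
    """
    banned = {w for w in excluded_labels if w != label}
    if exclude_members:
        for lab, members in exclude_members.items():
            if lab != label:
                banned.update(members)
    vec = _embedding_matrix(embeddings, [label])
    vocab = [w for w in embeddings.index if w != label and w not in banned]
    if len(vocab) < k:
        raise ItemLookupError(f"vocabulary too small for k={k} related terms")
    sims = _cosine_similarity(vec, _embedding_matrix(embeddings, vocab))[0]
    order = np.argsort(-sims, kind="stable")[:k]
    return WordCluster(label=label, members=[label] + [vocab[i] for i in order])


def semantic_rdm(clusters: list[WordCluster], embeddings: pd.DataFrame) -> RDM:
    """Cluster-averaged cosine-distance RDM over category word clusters.

    Between-category entries average 1 - cosine over all cross-cluster word
    pairs; the diagonal averages over distinct within-cluster pairs, giving a
    defined nonzero self-distance instead of a trivial zero.
    """
    n = len(clusters)
    mats = [_embedding_matrix(embeddings, c.members) for c in clusters]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            sim = _cosine_similarity(mats[i], mats[j])
            dist = 1.0 - sim
            if i == j:
                m = len(clusters[i].members)
                if m < 2:
                    d[i, i] = 0.0
                else:
                    iu = np.triu_indices(m, k=1)
                    d[i, i] = float(dist[iu].mean())
            else:
                d[i, j] = d[j, i] = float(dist.mean())
    return RDM(
        items=[c.label for c in clusters], d=d, metric_tag="cluster-cosine",
        self_distance=True,
    )


def animacy_rdm(labels: dict[str, int] | np.ndarray, items: list[str]) -> RDM:
    """Binary task RDM: 0 within an animacy category, 1 between categories."""
    if isinstance(labels, dict):
        missing = [i for i in items if i not in labels]
        if missing:
            raise ItemLookupError(f"missing animacy labels: {missing}")
        vec = np.array([labels[i] for i in items], dtype=float)
    else:
        vec = np.asarray(labels, dtype=float)
        if len(vec) != len(items):
            raise ValueError("label vector length must match items")
    d = (vec[:, None] != vec[None, :]).astype(float)
    return RDM(items=list(items), d=d, metric_tag="animacy")


# ---------------------------------------------------------------------------
# Trial-wise surprise
# ---------------------------------------------------------------------------


def surprise_value(rdm: RDM, expected: str, seen: str) -> float:
    """Representational distance between the cue-predicted and the seen image."""
    return rdm.lookup(expected, seen)


def build_surprise_design(
    trials: pd.DataFrame, rdms: dict[str, RDM], model_order: tuple[str, ...] = MODEL_ORDER
) -> pd.DataFrame:
    """One 5-vector of surprise regressors per qualifying trial.

    Qualifying trials are unexpected, correct, go trials (hits); all others are
    absent from the design. Columns follow ``model_order``; the index holds the
    positional row numbers of the qualifying trials in ``trials``.
    """
    missing = [m for m in model_order if m not in rdms]
    if missing:
        raise ItemLookupError(f"missing model RDMs: {missing}")
    items = rdms[model_order[0]].items
    for m in model_order[1:]:
        if set(rdms[m].items) != set(items):
            raise AlignmentError(f"RDM {m!r} covers a different item set")
    is_unexpected = trials["expectedness"].astype(str).str.startswith("unexpected")
    correct = trials["correct"].fillna(False).astype(bool)
    mask = is_unexpected & correct & ~trials["nogo"].astype(bool)
    qualifying = trials.loc[mask.to_numpy()]
    if qualifying.empty:
        raise EEGSurpriseError("no qualifying (unexpected, correct, go) trials")
    rows = {
        m: [surprise_value(rdms[m], r["expected_image"], r["image"])
            for _, r in qualifying.iterrows()]
        for m in model_order
    }
    out = pd.DataFrame(rows, index=np.flatnonzero(mask.to_numpy()))
    if not np.all(np.isfinite(out.to_numpy())):
        raise DegenerateInputError("non-finite surprise value in design")
    return out
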