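"""Banded dynamic time warping over word sequences, and 1-NN segment labels.

The local cost between two words is the modified lexical distance (adjacent
symbols cost nothing); the alignment uses the standard three-move dynamic
programme (match / insert / delete, unweighted) restricted to a Sakoe-Chiba
band |i - j| <= r (default r = 5, total width 11).

A test activity segment is classified at every prefix length p = 1..m: its
first p words are compared with each training segment's prefix of length
min(p, |training segment|), and the nearest training segment's label wins
(K = 1; distance ties resolve to the earliest training segment).  Because a
DP cell D[i, j] depends only on the subsequences up to i and j, one banded
pass per training segment yields all equal-length prefix distances on the
diagonal, which keeps the prefix sweep cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .labeling import ActivitySegment

__all__ = [
    "DtwConfig",
    "PrefixResult",
    "dtw_distance",
    "prefix_distance_matrix",
    "classify_segment",
    "accuracy_by_wordcount",
]


@dataclass(frozen=True)
class DtwConfig:
    """Parameters of the DTW 1-NN segment classifier."""

    band: int = 5  # Sakoe-Chiba radius r (total width 2r + 1)
    k: int = 1  # neighbours in the K-NN vote
    max_prefix: int = 40
    length_normalize: bool = False  # divide by the compared prefix length
    full_train: bool = False  # compare test prefixes against full training segments

    def __post_init__(self) -> None:
        if self.band < 0:
            raise ValueError("band radius must be >= 0")
        if self.k < 1:
            raise ValueError("K must be >= 1")


def _local_cost(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Modified lexical distance between word arrays, broadcasting over rows."""
    d = np.abs(a.astype(np.int32) - b.astype(np.int32))
    return (d - (d > 0)).sum(axis=-1)


def dtw_distance(a: np.ndarray, b: np.ndarray, r: int = 5) -> float:
    """Banded DTW distance between two word sequences.

    Raises when the band leaves no admissible path (only possible when the
    lengths differ by more than r; equal-length sequences always admit the
    diagonal path).
    """
    a = np.atleast_2d(np.asarray(a, dtype=np.int16))
    b = np.atleast_2d(np.asarray(b, dtype=np.int16))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("sequences must be non-empty")
    la, lb = a.shape[0], b.shape[0]
    if abs(la - lb) > r:
        raise ValueError(
            f"band radius {r} admits no path for lengths {la} and {lb}"
        )
    inf = np.inf
    prev = np.full(lb + 1, inf)
    prev[0] = 0.0
    for i in range(1, la + 1):
        cur = np.full(lb + 1, inf)
        jlo, jhi = max(1, i - r), min(lb, i + r)
        cost = _local_cost(a[i - 1], b[jlo - 1 : jhi])
        for j in range(jlo, jhi + 1):
            best = min(prev[j], prev[j - 1], cur[j - 1])
            cur[j] = cost[j - jlo] + best
        prev = cur
    return float(prev[lb])


def prefix_distance_matrix(
    test_words: np.ndarray, train_words: Sequence[np.ndarray], r: int = 5
) -> np.ndarray:
    """(m, n_train) matrix of equal-length-prefix banded DTW distances.

    Entry (p-1, t) is the distance between the test prefix of length
    min(p, |train_t|) and the training segment's prefix of the same length;
    the diagonal of one banded DP per training segment supplies every p.
    """
    test = np.atleast_2d(np.asarray(test_words, dtype=np.int16))
    m = test.shape[0]
    n_tr = len(train_words)
    if n_tr == 0:
        raise ValueError("training set must be non-empty")
    lengths = np.asarray([len(t) for t in train_words])
    lmax = int(lengths.max())
    stacked = np.zeros((n_tr, lmax, 8), dtype=np.int16)
    for t, w in enumerate(train_words):
        stacked[t, : len(w)] = np.atleast_2d(np.asarray(w, dtype=np.int16))

    inf = np.inf
    prev = np.full((n_tr, lmax + 1), inf)
    prev[:, 0] = 0.0
    diag = np.full((m + 1, n_tr), inf)
    diag[0] = 0.0
    for i in range(1, m + 1):
        cur = np.full((n_tr, lmax + 1), inf)
        jlo, jhi = max(1, i - r), min(lmax, i + r)
        if jlo <= jhi:
            cost = _local_cost(test[i - 1][None, None, :], stacked[:, jlo - 1 : jhi, :]).astype(float)
            # columns beyond a training segment's length are unreachable
            cols = np.arange(jlo, jhi + 1)
            cost[cols[None, :] > lengths[:, None]] = inf
            for j in range(jlo, jhi + 1):
                best = np.minimum(np.minimum(prev[:, j], prev[:, j - 1]), cur[:, j - 1])
                cur[:, j] = cost[:, j - jlo] + best
        sel = lengths >= i
        if i <= lmax:
            diag[i, sel] = cur[sel, i]
        short = np.flatnonzero(~sel)
        diag[i, short] = diag[lengths[short], short]
        prev = cur
    return diag[1:]


@dataclass
class PrefixResult:
    """Predictions of one test segment at every prefix length."""

    predictions: list[str]  # length m
    nn_indices: np.ndarray  # (m,) index of the nearest training segment
    distances: np.ndarray  # (m,) its DTW distance

    def __len__(self) -> int:
        return len(self.predictions)


def classify_segment(
    test: "ActivitySegment | np.ndarray",
    training: Sequence[ActivitySegment],
    config: DtwConfig = DtwConfig(),
) -> PrefixResult:
    """1-NN (or K-NN) classification of a segment at every prefix length."""
    if len(training) == 0:
        raise ValueError("training segment list must be non-empty")
    test_words = test.words if isinstance(test, ActivitySegment) else np.asarray(test)
    if test_words is None:
        raise ValueError("test segment has no words; encode it first")
    m = min(len(test_words), config.max_prefix)
    test_words = np.atleast_2d(np.asarray(test_words, dtype=np.int16))[:m]
    train_words = []
    for seg in training:
        if seg.words is None:
            raise ValueError("training segments must be encoded (words set)")
        train_words.append(np.asarray(seg.words, dtype=np.int16)[: config.max_prefix])

    if config.full_train:
        dist = np.full((m, len(train_words)), np.inf)
        for t, tw in enumerate(train_words):
            for p in range(1, m + 1):
                if abs(p - len(tw)) <= config.band:
                    dist[p - 1, t] = dtw_distance(test_words[:p], tw, config.band)
    else:
        dist = prefix_distance_matrix(test_words, train_words, config.band).astype(float)

    if config.length_normalize:
        lengths = np.asarray([len(t) for t in train_words])
        comp_len = np.minimum(np.arange(1, m + 1)[:, None], lengths[None, :])
        dist = dist / comp_len

    labels = [seg.label for seg in training]
    preds: list[str] = []
    nn_idx = np.empty(m, dtype=int)
    nn_dist = np.empty(m)
    for p in range(m):
        order = np.argsort(dist[p], kind="stable")[: config.k]
        nn_idx[p] = order[0]
        nn_dist[p] = dist[p, order[0]]
        if config.k == 1:
            preds.append(labels[order[0]])
        else:
            votes: dict[str, int] = {}
            for t in order:
                votes[labels[t]] = votes.get(labels[t], 0) + 1
            top = max(votes.values())
            # majority; ties resolve to the nearest neighbour among the tied
            preds.append(next(labels[t] for t in order if votes[labels[t]] == top))
    return PrefixResult(predictions=preds, nn_indices=nn_idx, distances=nn_dist)


def accuracy_by_wordcount(
    results: Sequence[tuple[str, PrefixResult]]
) -> dict[int, float]:
    """Percent of test segments predicted correctly at each prefix length.

    At word count p only segments of length >= p participate.
    """
    if len(results) == 0:
        raise ValueError("no prefix results")
    max_p = max(len(r) for _, r in results)
    curve = {}
    for p in range(1, max_p + 1):
        eligible = [(t, r) for t, r in results if len(r) >= p]
        correct = sum(1 for t, r in eligible if r.predictions[p - 1] == t)
        curve[p] = 100.0 * correct / len(eligible)
    return curve
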