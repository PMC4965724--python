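"""Class-by-word affinity matrix streaming classifier.

Training counts how often each SAX word occurs in each class (matrix A),
row-normalises it so each class row sums to one (A-bar), then scales each
column to a unit vector (A-hat).  A test word's evidence row P_i is its
A-hat column; an unseen word borrows the columns of its nearest vocabulary
words under lexical distance d_l (summed and re-normalised, then cached).
The class decision at stream position i is the argmax of the windowed sum

    Pbar_i = sum_{j=max(1, i-w)}^{i} P_j

(the current row plus up to w predecessors; early positions use the
truncated sum).  w = 0 reduces to the per-instance argmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .protocol import CLASS_CODES
from .sax import lexical_distance, strings_to_words, words_to_strings

__all__ = [
    "AffinityModel",
    "AffinityTrace",
    "train",
    "lookup_row",
    "classify_stream",
    "sweep",
]


@dataclass
class AffinityModel:
    """Trained affinity matrices over a word vocabulary."""

    classes: list[str]
    vocab: np.ndarray  # (V, 8) unique words, lexicographic order
    counts: np.ndarray  # A: (C, V) raw co-occurrence counts
    row_normalized: np.ndarray  # A-bar: rows sum to 1
    unit_columns: np.ndarray  # A-hat: columns unit-norm
    norm: str = "l2"  # norm used for A-hat columns and imputed rows
    _word_index: dict = field(default_factory=dict, repr=False)
    _imputation_cache: dict = field(default_factory=dict, repr=False)

    @property
    def vocabulary_size(self) -> int:
        return self.vocab.shape[0]

    def column_of(self, word) -> Optional[np.ndarray]:
        """A-hat column of an in-vocabulary word, else None."""
        idx = self._word_index.get(np.asarray(word, dtype=np.int16).tobytes())
        return None if idx is None else self.unit_columns[:, idx]


def _normalize(v: np.ndarray, norm: str) -> np.ndarray:
    s = np.linalg.norm(v) if norm == "l2" else np.abs(v).sum()
    if s == 0:
        raise ValueError("cannot normalise a zero vector")
    return v / s


def train(
    words: np.ndarray,
    labels: Sequence[str],
    classes: Sequence[str] = CLASS_CODES,
    norm: str = "l2",
) -> AffinityModel:
    """Build the affinity model from labelled training words.

    Every class must occur at least once in training (a class with an empty
    row cannot be normalised, nor ever predicted).
    """
    if norm not in ("l2", "l1"):
        raise ValueError(f"norm must be 'l2' or 'l1', got {norm!r}")
    words = np.atleast_2d(np.asarray(words, dtype=np.int16))
    labels = np.asarray(labels)
    if words.shape[0] != labels.shape[0]:
        raise ValueError("words and labels must have equal length")
    classes = list(classes)
    missing = sorted(set(classes) - set(labels))
    if missing:
        raise ValueError(f"class(es) absent from training data: {', '.join(missing)}")

    vocab, inverse = np.unique(words, axis=0, return_inverse=True)
    class_idx = {c: i for i, c in enumerate(classes)}
    rows = np.asarray([class_idx[l] for l in labels])
    counts = np.zeros((len(classes), vocab.shape[0]))
    np.add.at(counts, (rows, inverse), 1.0)

    row_sums = counts.sum(axis=1, keepdims=True)
    abar = counts / row_sums
    col_norm = (
        np.linalg.norm(abar, axis=0) if norm == "l2" else np.abs(abar).sum(axis=0)
    )
    ahat = abar / col_norm
    index = {vocab[i].tobytes(): i for i in range(vocab.shape[0])}
    return AffinityModel(
        classes=classes, vocab=vocab, counts=counts,
        row_normalized=abar, unit_columns=ahat, norm=norm, _word_index=index,
    )


def lookup_row(word, model: AffinityModel) -> np.ndarray:
    """Evidence row P_i for one word (imputing unseen words).

    An unseen word receives the sum of the A-hat columns of all vocabulary
    words at minimal lexical distance, re-normalised; the imputed row is
    cached for the rest of the classification session.
    """
    if model.vocabulary_size == 0:
        raise ValueError("model has an empty vocabulary")
    word = np.asarray(word, dtype=np.int16).ravel()
    if word.shape != (8,):
        raise ValueError("words must have exactly 8 symbols")
    key = word.tobytes()
    idx = model._word_index.get(key)
    if idx is not None:
        return model.unit_columns[:, idx]
    cached = model._imputation_cache.get(key)
    if cached is not None:
        return cached
    d = np.abs(model.vocab - word[None, :]).sum(axis=1)
    nearest = np.flatnonzero(d == d.min())
    row = _normalize(model.unit_columns[:, nearest].sum(axis=1), model.norm)
    model._imputation_cache[key] = row
    return row


@dataclass
class AffinityTrace:
    """Per-instance evidence for a classified stream."""

    words: np.ndarray  # (m, 8)
    imputed: np.ndarray  # (m,) bool
    P: np.ndarray  # (m, C) evidence rows
    Pbar: np.ndarray  # (m, C) windowed sums
    predictions: list[str]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.Pbar, columns=[f"aff_{c}" for c in range(self.Pbar.shape[1])])
        df.insert(0, "word", words_to_strings(self.words))
        df.insert(1, "imputed", self.imputed)
        df["prediction"] = self.predictions
        return df


def classify_stream(
    words: np.ndarray, model: AffinityModel, w: int = 30
) -> tuple[list[str], AffinityTrace]:
    """Classify a word stream with an affinity summation window of w.

    Ties in the argmax resolve to the lowest class index (catalogue order).
    """
    if w < 0:
        raise ValueError("summation window w must be >= 0")
    words = np.atleast_2d(np.asarray(words, dtype=np.int16))
    if words.shape[0] == 0:
        raise ValueError("cannot classify an empty stream")
    m = words.shape[0]
    P = np.empty((m, len(model.classes)))
    imputed = np.empty(m, dtype=bool)
    for i in range(m):
        key = words[i].tobytes()
        imputed[i] = key not in model._word_index
        P[i] = lookup_row(words[i], model)
    cs = np.vstack([np.zeros((1, P.shape[1])), np.cumsum(P, axis=0)])
    lo = np.maximum(np.arange(m) - w, 0)
    Pbar = cs[np.arange(1, m + 1)] - cs[lo]
    preds = [model.classes[j] for j in np.argmax(Pbar, axis=1)]
    return preds, AffinityTrace(words=words, imputed=imputed, P=P, Pbar=Pbar, predictions=preds)


def sweep(folds, n_values=(5, 7, 9, 11, 15), w_values=(3, 5, 10, 15, 30)):
    """Fold-mean accuracy over an (alphabet size, window) grid.

    Convenience front for :func:`semgrip.evaluation.sweep_affinity`.
    """
    from .evaluation import sweep_affinity

    return sweep_affinity(folds, n_values=n_values, w_values=w_values)
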