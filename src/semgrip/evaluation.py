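"""Leave-one-repetition-out evaluation, metrics and parameter sweeps.

The protocol yields 12 repetitions of every action group; evaluation fold k
holds the k-th repetition's activity segments from all eight runs plus a
disjoint share of the run-start NR instances (each run's 60 retained NR
instances are split into twelve consecutive 5-word chunks, one per fold, so
folds stay disjoint while every fold sees rest data).  Each fold is withheld
once; the SAX codebook, the affinity matrices and the DTW training set are
rebuilt from the remaining eleven.

The affinity classifier is scored word-by-word: each test activity segment is
classified as its own stream (the summation window never crosses a segment
boundary).  The DTW classifier is scored segment-by-segment at a chosen
prefix length (default 20 words, where its accuracy curve flattens), and the
full accuracy-by-wordcount curve is reported alongside.

Reported accuracy is pooled over folds (trace of the summed confusion matrix
over the total count); the per-fold accuracies and their mean are kept too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import affinity as aff
from . import dtw as dtw_mod
from .baselines import BaselineResult, BaselineSpec, run_baseline
from .labeling import (
    NR_WINDOW,
    ActivitySegment,
    LabeledStream,
    label_run,
    segment_activities,
    subsample_nr,
)
from .preprocess import compute_mav, summarize_acc
from .protocol import CLASS_CODES, GROUPS, NR, make_schedule
from .sax import encode, fit_codebook
from .simulate import SubjectProfile, generate_dataset

__all__ = [
    "SubjectData",
    "RepetitionFolds",
    "EvalReport",
    "build_subject_data",
    "make_repetition_folds",
    "evaluate_affinity",
    "evaluate_dtw",
    "evaluate_baseline",
    "sweep_affinity",
    "sweep_dtw",
    "sweep_report",
]

REP_COUNT = 12
#: segment-level scoring prefix: where the accuracy-by-wordcount curve of the
#: default synthetic subjects flattens out
DEFAULT_SCORE_PREFIX = 15


@dataclass
class SubjectData:
    """Labelled, segmented dataset of one subject's eight runs."""

    segments: list[ActivitySegment]  # non-NR activity segments (<= 40 words)
    nr_segments: list[ActivitySegment]  # one run-start NR segment per run (60 words)
    streams: list[LabeledStream]  # full labelled streams, one per run


def build_subject_data(profile: SubjectProfile, seed: int) -> SubjectData:
    """Simulate, featurise and label all eight runs of one synthetic subject."""
    segments: list[ActivitySegment] = []
    nr_segments: list[ActivitySegment] = []
    streams: list[LabeledStream] = []
    for run in generate_dataset(profile, seed):
        bundle = run.as_bundle()
        mav = compute_mav(bundle)
        acc = summarize_acc(bundle)
        labeled = label_run(mav, acc, make_schedule(run.group_id))
        streams.append(labeled)
        segments.extend(
            seg for seg in segment_activities(labeled, include_nr=False)
        )
        keep = (
            (labeled.labels == NR)
            & (labeled.times >= NR_WINDOW[0])
            & (labeled.times < NR_WINDOW[1])
        )
        nr_segments.append(
            ActivitySegment(
                label=NR,
                times=labeled.times[keep],
                values=labeled.values[keep],
                rep_index=0,
                run_id=run.group_id,
            )
        )
    return SubjectData(segments=segments, nr_segments=nr_segments, streams=streams)


@dataclass
class RepetitionFolds:
    """Twelve disjoint train/test splits, one per protocol repetition."""

    folds: list[list[ActivitySegment]]  # fold k-1 = repetition k (+ NR share)

    def __len__(self) -> int:
        return len(self.folds)

    def split(self, k: int) -> tuple[list[ActivitySegment], list[ActivitySegment]]:
        """(train, test) segments with fold index k (0-based) withheld."""
        test = self.folds[k]
        train = [s for i, f in enumerate(self.folds) if i != k for s in f]
        return train, test


def make_repetition_folds(
    segments: Sequence[ActivitySegment],
    nr_segments: Sequence[ActivitySegment] = (),
    rep_count: int = REP_COUNT,
) -> RepetitionFolds:
    """Group activity segments by repetition index; share NR words out evenly.

    Every group must contribute every repetition 1..rep_count; each NR
    segment (one per run) is split into ``rep_count`` consecutive chunks so
    that the folds are pairwise disjoint.
    """
    folds: list[list[ActivitySegment]] = [[] for _ in range(rep_count)]
    seen: dict[tuple[str, int], bool] = {}
    for seg in segments:
        if not 1 <= seg.rep_index <= rep_count:
            raise ValueError(
                f"segment of {seg.label} has repetition index {seg.rep_index}, "
                f"expected 1..{rep_count}"
            )
        seen[(seg.run_id, seg.rep_index)] = True
        folds[seg.rep_index - 1].append(seg)
    groups = {seg.run_id for seg in segments}
    for g in sorted(groups, key=str):
        for rep in range(1, rep_count + 1):
            if (g, rep) not in seen:
                raise ValueError(f"group {g!r} is missing repetition {rep}")
    for nr_seg in nr_segments:
        chunk = len(nr_seg) // rep_count
        if chunk == 0:
            raise ValueError("NR segment too short to share across folds")
        for k in range(rep_count):
            lo, hi = k * chunk, (k + 1) * chunk if k < rep_count - 1 else len(nr_seg)
            folds[k].append(
                ActivitySegment(
                    label=NR,
                    times=nr_seg.times[lo:hi],
                    values=nr_seg.values[lo:hi],
                    rep_index=k + 1,
                    run_id=nr_seg.run_id,
                )
            )
    return RepetitionFolds(folds=folds)


@dataclass
class EvalReport:
    """Accuracy, per-class recall and the 25x25 confusion matrix."""

    accuracy: float  # percent, pooled over folds
    fold_accuracies: list[float]  # percent, one per fold
    confusion: pd.DataFrame  # rows = ground truth, columns = prediction
    n_total: int

    @property
    def fold_mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def tpr(self) -> dict:
        cm = self.confusion.to_numpy()
        rows = cm.sum(axis=1)
        return {
            c: (100.0 * cm[i, i] / rows[i] if rows[i] else float("nan"))
            for i, c in enumerate(self.confusion.index)
        }

    @classmethod
    def from_counts(
        cls, confusion: np.ndarray, fold_accuracies: list[float], classes: Sequence[str]
    ) -> "EvalReport":
        cm = pd.DataFrame(confusion, index=list(classes), columns=list(classes))
        total = int(confusion.sum())
        acc = 100.0 * float(np.trace(confusion)) / total if total else float("nan")
        return cls(accuracy=acc, fold_accuracies=fold_accuracies, confusion=cm, n_total=total)


def _fold_words(
    train: Sequence[ActivitySegment], test: Sequence[ActivitySegment], n: int
):
    """Fit the fold codebook on training MAVs; encode both sides."""
    train_values = np.concatenate([s.values for s in train], axis=0)
    codebook = fit_codebook(train_values, n)
    train_words = [encode(s.values, codebook) for s in train]
    test_words = [encode(s.values, codebook) for s in test]
    return codebook, train_words, test_words


def evaluate_affinity(
    folds: RepetitionFolds,
    n: int = 11,
    w: "int | Sequence[int]" = 30,
    classes: Sequence[str] = CLASS_CODES,
) -> "EvalReport | dict[int, EvalReport]":
    """Word-level leave-one-repetition-out evaluation of the affinity model.

    Pass a sequence of window sizes ``w`` to score several windows while
    computing the evidence rows only once per fold.
    """
    ws = [w] if np.isscalar(w) else list(w)
    cidx = {c: i for i, c in enumerate(classes)}
    conf = {wv: np.zeros((len(classes), len(classes))) for wv in ws}
    fold_acc = {wv: [] for wv in ws}
    for k in range(len(folds)):
        train, test = folds.split(k)
        _, train_words, test_words = _fold_words(train, test, n)
        model = aff.train(
            np.concatenate(train_words, axis=0),
            np.concatenate([[s.label] * len(s) for s in train]),
            classes=classes,
        )
        correct = {wv: 0 for wv in ws}
        total = 0
        for seg, words in zip(test, test_words):
            P = np.stack([aff.lookup_row(wd, model) for wd in words])
            cs = np.vstack([np.zeros((1, P.shape[1])), np.cumsum(P, axis=0)])
            m = len(words)
            total += m
            for wv in ws:
                lo = np.maximum(np.arange(m) - wv, 0)
                pbar = cs[np.arange(1, m + 1)] - cs[lo]
                pred_idx = np.argmax(pbar, axis=1)
                ti = cidx[seg.label]
                for pi in pred_idx:
                    conf[wv][ti, pi] += 1
                correct[wv] += int(np.sum(pred_idx == ti))
        for wv in ws:
            fold_acc[wv].append(100.0 * correct[wv] / total)
    reports = {
        wv: EvalReport.from_counts(conf[wv], fold_acc[wv], classes) for wv in ws
    }
    return reports[ws[0]] if np.isscalar(w) else reports


def _merge_consecutive_nr(
    segments: Sequence[ActivitySegment], max_len: int = 40, step: float = 0.05
) -> list[ActivitySegment]:
    """Re-join time-adjacent NR chunks of one run into full rest sequences.

    Fold construction splits each run's retained NR words into per-fold
    chunks; for DTW *training* the surviving chunks of each run are merged
    back into one rest sequence (rest is quasi-stationary, and the
    run-start instances are consecutive up to the withheld fold's hole) so
    rest is represented by realistic-length sequences rather than 5-word
    stubs whose prefix distance stops accumulating and undercuts every long
    segment.
    """
    out = [s for s in segments if s.label != NR]
    by_run: dict = {}
    for seg in segments:
        if seg.label == NR:
            by_run.setdefault(seg.run_id, []).append(seg)
    for run_id in sorted(by_run, key=str):
        chunks = sorted(by_run[run_id], key=lambda s: s.times[0])
        out.append(
            ActivitySegment(
                label=NR,
                times=np.concatenate([s.times for s in chunks]),
                values=np.concatenate([s.values for s in chunks]),
                rep_index=chunks[0].rep_index,
                run_id=run_id,
            )
        )
    return [
        ActivitySegment(
            label=s.label, times=s.times[:max_len], values=s.values[:max_len],
            rep_index=s.rep_index, run_id=s.run_id,
        )
        if len(s) > max_len
        else s
        for s in out
    ]


def evaluate_dtw(
    folds: RepetitionFolds,
    config: dtw_mod.DtwConfig = dtw_mod.DtwConfig(),
    n: int = 15,
    score_prefix: int = DEFAULT_SCORE_PREFIX,
    classes: Sequence[str] = CLASS_CODES,
) -> tuple[EvalReport, dict[int, float]]:
    """Segment-level leave-one-repetition-out evaluation of the DTW 1-NN.

    Returns the report scored at ``min(score_prefix, segment length)`` words
    plus the pooled accuracy-by-wordcount curve.
    """
    cidx = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)))
    fold_acc: list[float] = []
    all_results: list[tuple[str, dtw_mod.PrefixResult]] = []
    for k in range(len(folds)):
        train, test = folds.split(k)
        train = _merge_consecutive_nr(train, max_len=config.max_prefix)
        _, train_words, test_words = _fold_words(train, test, n)
        train_enc = [
            ActivitySegment(
                label=s.label, times=s.times, values=s.values,
                rep_index=s.rep_index, run_id=s.run_id, words=wd,
            )
            for s, wd in zip(train, train_words)
        ]
        correct = total = 0
        for seg, words in zip(test, test_words):
            res = dtw_mod.classify_segment(words, train_enc, config)
            all_results.append((seg.label, res))
            p = min(score_prefix, len(res)) - 1
            pred = res.predictions[p]
            conf[cidx[seg.label], cidx[pred]] += 1
            total += 1
            correct += pred == seg.label
        fold_acc.append(100.0 * correct / total)
    report = EvalReport.from_counts(conf, fold_acc, classes)
    return report, dtw_mod.accuracy_by_wordcount(all_results)


def pooled_instances(folds: RepetitionFolds) -> tuple[np.ndarray, np.ndarray]:
    """All MAV instances and labels across folds (for instance baselines)."""
    values = np.concatenate([s.values for f in folds.folds for s in f], axis=0)
    labels = np.concatenate([[s.label] * len(s) for f in folds.folds for s in f])
    return values, labels


def evaluate_baseline(
    folds: RepetitionFolds,
    spec: BaselineSpec = BaselineSpec(),
    cv_folds: int = 10,
    seed: int = 0,
) -> BaselineResult:
    """Stratified CV of an instance-level classifier on the pooled dataset."""
    values, labels = pooled_instances(folds)
    return run_baseline(values, labels, spec, folds=cv_folds, seed=seed)


def sweep_affinity(
    folds: RepetitionFolds,
    n_values: Sequence[int] = (5, 7, 9, 11, 15),
    w_values: Sequence[int] = (3, 5, 10, 15, 30),
) -> pd.DataFrame:
    """Fold-mean affinity accuracy (%) for every (symbols, window) cell."""
    table = pd.DataFrame(index=list(n_values), columns=list(w_values), dtype=float)
    table.index.name = "symbols"
    table.columns.name = "w"
    for n in n_values:
        reports = evaluate_affinity(folds, n=n, w=list(w_values))
        for w, rep in reports.items():
            table.loc[n, w] = rep.fold_mean_accuracy
    return table


def sweep_dtw(
    folds: RepetitionFolds,
    n_values: Sequence[int] = (5, 7, 9, 11, 15),
    config: dtw_mod.DtwConfig = dtw_mod.DtwConfig(),
    word_counts: Sequence[int] = (3, 7, 11, 15, 20),
) -> pd.DataFrame:
    """Accuracy-by-wordcount (%) per alphabet size for the DTW classifier."""
    table = pd.DataFrame(index=list(n_values), columns=list(word_counts), dtype=float)
    table.index.name = "symbols"
    table.columns.name = "words"
    for n in n_values:
        _, curve = evaluate_dtw(folds, config=config, n=n)
        for p in word_counts:
            table.loc[n, p] = curve.get(p, float("nan"))
    return table


def sweep_report(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Combine per-subject sweep tables into [low, high] range cells."""
    if len(tables) == 0:
        raise ValueError("no sweep tables given")
    stacked = np.stack([t.to_numpy(dtype=float) for t in tables])
    lows, highs = stacked.min(axis=0), stacked.max(axis=0)
    out = tables[0].copy().astype(object)
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            out.iloc[i, j] = (round(float(lows[i, j]), 1), round(float(highs[i, j]), 1))
    return out
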