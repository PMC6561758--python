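"""Stratified k-fold cross-validation with pooled (macro) aggregation.

Stratification is per taxon: within each taxon the sequence IDs are
shuffled by a seeded generator and dealt round-robin to folds, so per-fold
counts for a taxon differ by at most one.  The starting fold rotates with
the taxon index so small taxa do not all crowd fold 0.  Singleton taxa land
in exactly one fold — and are therefore absent from training when that fold
is tested — but they are never discarded: an unclassifiable singleton is
part of the honest error.

Aggregation follows the macro-average rule for imbalanced data: all
per-sequence TDs are pooled across folds first, and per-taxon ATDs and the
overall metrics are computed once on the pooled table.  Computing per-fold
metrics and averaging them gives a different (and misleading) number as
soon as a taxon's sequences are split unevenly across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Protocol, Sequence

import numpy as np

from .metrics import EvaluationReport, PredictionRecord, evaluate
from .taxonomy import ROOT, RankedLabel

__all__ = ["FoldAssignment", "Classifier", "stratified_folds", "run_cv", "macro_aggregate"]


class Classifier(Protocol):
    """Contract for classifiers pluggable into :func:`run_cv`.

    ``train`` receives labeled sequences; ``predict`` receives sequences and
    returns one label per sequence.  Ordinary classifiers read only the
    residues of a query; oracle classifiers (e.g. the Plateau reference) may
    read the query's label.
    """

    def train(self, sequences: Sequence) -> None: ...

    def predict(self, sequences: Sequence) -> List[RankedLabel]: ...


@dataclass
class FoldAssignment:
    """A mapping from sequence ID to fold index in ``0..k-1``."""

    assignment: Dict[str, int]
    k: int
    seed: int

    def fold_of(self, sequence_id: str) -> int:
        return self.assignment[sequence_id]

    def members(self, fold: int) -> List[str]:
        return [sid for sid, f in self.assignment.items() if f == fold]

    def __len__(self) -> int:
        return len(self.assignment)


def stratified_folds(dataset: Sequence, k: int, seed: int) -> FoldAssignment:
    """Deal each taxon's sequences round-robin into `k` folds.

    Deterministic for a given seed.  A taxon with n sequences occupies
    ``min(n, k)`` folds with per-fold counts differing by at most one.

    Raises
    ------
    ValueError
        If ``k < 2`` or the dataset is empty.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    dataset = list(dataset)
    if not dataset:
        raise ValueError("cannot assign folds on an empty dataset")
    by_taxon: Dict[RankedLabel, List[str]] = {}
    for seq in dataset:
        by_taxon.setdefault(seq.label, []).append(seq.id)

    rng = np.random.default_rng(seed)
    assignment: Dict[str, int] = {}
    for ti, taxon in enumerate(sorted(by_taxon, key=lambda t: t.ranks)):
        ids = sorted(by_taxon[taxon])
        order = rng.permutation(len(ids))
        offset = ti % k
        for j, idx in enumerate(order):
            assignment[ids[idx]] = (offset + j) % k
    return FoldAssignment(assignment=assignment, k=k, seed=seed)


def run_cv(
    dataset: Sequence, classifier: Classifier, folds: FoldAssignment
) -> List[PredictionRecord]:
    """Train on each fold's complement and predict the fold's sequences.

    A classifier exception while predicting a single sequence is downgraded
    to a depth-0 (fully unclassified) prediction with a warning, so no
    sequence is ever dropped from the table; an exception during training is
    propagated, annotated with the fold index.
    """
    dataset = list(dataset)
    by_fold: Dict[int, List] = {f: [] for f in range(folds.k)}
    for seq in dataset:
        by_fold[folds.fold_of(seq.id)].append(seq)

    predictions: Dict[str, RankedLabel] = {}
    for f in range(folds.k):
        test = by_fold[f]
        if not test:
            continue
        train = [s for g in range(folds.k) if g != f for s in by_fold[g]]
        if not train:
            raise ValueError("fold %d contains the whole dataset; training is empty" % f)
        try:
            classifier.train(train)
        except Exception as exc:
            exc.add_note("while training on the complement of fold %d" % f)
            raise
        for seq in test:
            try:
                predictions[seq.id] = classifier.predict([seq])[0]
            except Exception as exc:
                warnings.warn(
                    "classifier failed on sequence %r in fold %d (%s); "
                    "recording a depth-0 prediction" % (seq.id, f, exc)
                )
                predictions[seq.id] = ROOT

    return [
        PredictionRecord(s.id, s.label, predictions[s.id], fold=folds.fold_of(s.id))
        for s in dataset
    ]


def macro_aggregate(records: Sequence[PredictionRecord]) -> EvaluationReport:
    """Pool per-sequence TDs across folds, then compute per-taxon ATDs.

    This is the macro-average rule: identical to :func:`taxodist.metrics.evaluate`
    on the concatenated table, and deliberately NOT an average of per-fold
    metrics.  Duplicate sequence IDs across folds are an error.
    """
    return evaluate(list(records))
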