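"""Synthetic taxonomies, imbalanced datasets and controlled predictions.

Everything the toolkit needs for testing and demonstration is generated
here, without external databases:

* the six-label worked example (a four-rank toy tree whose 15 pairwise
  TDs are frozen and re-verified at load time);
* random ranked taxonomies with ragged depths and globally unique node
  names (so no rank name recurs at a position under two parents);
* heavily imbalanced per-taxon sequence counts via a power-law allocation
  (exponent 0 = balanced), mirroring the far-above-the-diagonal cumulative
  curves of real 16S/18S databases, with optional motif-bearing DNA so the
  built-in nearest-neighbor classifier has something to learn;
* classifier predictions with a controlled, per-rank corruption structure,
  whose metric expectations are known in closed form (corrupting only the
  lowest of d ranks with probability p gives an expected per-sequence TD
  of p/d).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .metrics import PredictionRecord, taxonomy_distance
from .taxonomy import RankedLabel, TaxonomyTree, build_tree, parse_label
from .io import LabeledSequence

__all__ = [
    "Fig2Fixture",
    "fig2_fixture",
    "random_taxonomy",
    "allocate_counts",
    "imbalanced_dataset",
    "simulate_predictions",
    "estimate_corruption_rates",
]


# ------------------------------------------------------------ worked example

#: The 15 pairwise TDs of the six worked-example labels, as exact rationals.
_EXPECTED_TDS: Dict[Tuple[str, str], Fraction] = {
    ("T1", "T2"): Fraction(1, 3),
    ("T1", "T3"): Fraction(2, 3),
    ("T1", "T4"): Fraction(1, 3),
    ("T1", "T5"): Fraction(2, 3),
    ("T1", "T6"): Fraction(3, 4),
    ("T2", "T3"): Fraction(2, 3),
    ("T2", "T4"): Fraction(1, 3),
    ("T2", "T5"): Fraction(2, 3),
    ("T2", "T6"): Fraction(3, 4),
    ("T3", "T4"): Fraction(2, 3),
    ("T3", "T5"): Fraction(1, 3),
    ("T3", "T6"): Fraction(1, 4),
    ("T4", "T5"): Fraction(1, 2),
    ("T4", "T6"): Fraction(3, 4),
    ("T5", "T6"): Fraction(2, 4),
}


@dataclass(frozen=True)
class Fig2Fixture:
    """Six worked-example labels T1..T6 and the tree they span."""

    labels: Dict[str, RankedLabel]
    tree: TaxonomyTree
    expected_tds: Dict[Tuple[str, str], Fraction]


def fig2_fixture() -> Fig2Fixture:
    """The six-label toy taxonomy with its frozen pairwise TD table.

    T1..T3 are three genus-depth labels under order ``orderA``; T4 and T5
    are the two family-depth internal labels and T6 a species-depth label
    under family ``familyC``.  (The species rank name is not constrained by
    the TD table — any name yields the same distances — so ``speciesG`` is
    used.)  The constructor re-derives all 15 pairwise TDs and raises if
    any disagrees with the frozen table.
    """
    labels = {
        "T1": parse_label("orderA;familyB;generaD"),
        "T2": parse_label("orderA;familyB;generaE"),
        "T3": parse_label("orderA;familyC;generaF"),
        "T4": parse_label("orderA;familyB"),
        "T5": parse_label("orderA;familyC"),
        "T6": parse_label("orderA;familyC;generaF;speciesG"),
    }
    for (na, nb), expected in _EXPECTED_TDS.items():
        got = taxonomy_distance(labels[na], labels[nb])
        if got != expected:
            raise AssertionError(
                "fixture self-check failed: TD(%s, %s) = %s, expected %s"
                % (na, nb, got, expected)
            )
    tree = build_tree(labels.values())
    return Fig2Fixture(labels=labels, tree=tree, expected_tds=dict(_EXPECTED_TDS))


# --------------------------------------------------------- random taxonomies

def random_taxonomy(
    n_taxa: int,
    max_depth: int = 6,
    branching: float = 1.5,
    seed: int = 0,
    min_depth: Optional[int] = None,
) -> List[RankedLabel]:
    """Random ranked lineages forming the leaves of a random tree.

    Lineages are grown root-down; at each level an existing (non-leaf)
    child is reused or — with probability proportional to `branching` — a
    new child with a globally unique name is created.  The final rank of
    every lineage is always a fresh node, so the returned labels are
    distinct and none is a strict prefix of another.  Depths are ragged,
    drawn uniformly from ``min_depth..max_depth`` (default
    ``max(1, max_depth - 2)``).  Deterministic under `seed`.

    Raises
    ------
    ValueError
        On infeasible parameters (``n_taxa < 1``, ``max_depth < 1``,
        ``branching <= 0`` or ``min_depth > max_depth``).
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if branching <= 0:
        raise ValueError("branching must be positive")
    if min_depth is None:
        min_depth = max(1, max_depth - 2)
    if not 1 <= min_depth <= max_depth:
        raise ValueError("min_depth must be in 1..max_depth")

    rng = np.random.default_rng(seed)
    children: Dict[Tuple[str, ...], List[str]] = {(): []}
    leaves: Set[Tuple[str, ...]] = set()
    counter = itertools.count()

    def new_name(level: int) -> str:
        return "r%d_%04d" % (level, next(counter))

    labels: List[RankedLabel] = []
    for _ in range(n_taxa):
        depth = int(rng.integers(min_depth, max_depth + 1))
        node: Tuple[str, ...] = ()
        for level in range(depth):
            last = level == depth - 1
            internal = [
                c for c in children.get(node, []) if node + (c,) not in leaves
            ]
            if last or not internal or rng.random() < branching / (
                branching + len(internal)
            ):
                name = new_name(level)
                children.setdefault(node, []).append(name)
                children[node + (name,)] = []
            else:
                name = internal[int(rng.integers(len(internal)))]
            node = node + (name,)
        leaves.add(node)
        labels.append(RankedLabel(node))
    return labels


# ------------------------------------------------------- imbalanced datasets

def allocate_counts(total: int, n_taxa: int, exponent: float) -> List[int]:
    """Deterministic power-law allocation of `total` sequences to taxa.

    Taxon i (0-based, most abundant first) gets a share proportional to
    ``(i + 1) ** -exponent`` of the sequences remaining after every taxon is
    given one; the integerization uses the largest-remainder rule.
    ``exponent = 0`` yields counts differing by at most one; large exponents
    concentrate most sequences in the first few taxa.

    Raises
    ------
    ValueError
        If ``total < n_taxa`` or ``exponent < 0``.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if total < n_taxa:
        raise ValueError("need at least one sequence per taxon (total < n_taxa)")
    if exponent < 0:
        raise ValueError("imbalance exponent must be >= 0")
    weights = np.arange(1, n_taxa + 1, dtype=float) ** -exponent
    weights /= weights.sum()
    remaining = total - n_taxa
    ideal = remaining * weights
    counts = np.floor(ideal).astype(int)
    shortfall = remaining - int(counts.sum())
    if shortfall:
        order = np.argsort(-(ideal - counts), kind="stable")
        counts[order[:shortfall]] += 1
    return list(1 + counts)


_BASES = np.array(list("ACGT"))


def imbalanced_dataset(
    labels: Sequence[RankedLabel],
    total_sequences: int,
    imbalance_exponent: float = 1.5,
    seed: int = 0,
    with_sequences: bool = True,
    sequence_length: int = 150,
    motif_length: int = 12,
) -> List[LabeledSequence]:
    """Labeled sequences with power-law per-taxon counts.

    Which taxon gets which abundance rank is shuffled by the seeded
    generator.  When `with_sequences` is true, each taxon carries a private
    random DNA motif implanted at a random position in otherwise random
    background of `sequence_length` bases, making taxa separable for the
    built-in nearest-neighbor classifier; otherwise residues are ``None``.

    Raises
    ------
    ValueError
        If ``total_sequences < len(labels)`` (every taxon gets at least one
        sequence) or labels are not distinct.
    """
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise ValueError("taxon labels must be distinct")
    rng = np.random.default_rng(seed)
    counts = allocate_counts(total_sequences, len(labels), imbalance_exponent)
    order = rng.permutation(len(labels))

    dataset: List[LabeledSequence] = []
    serial = itertools.count(1)
    for pos, li in enumerate(order):
        label = labels[li]
        n = counts[pos]
        motif = "".join(rng.choice(_BASES, size=motif_length)) if with_sequences else ""
        for _ in range(n):
            residues: Optional[str] = None
            if with_sequences:
                bg = rng.choice(_BASES, size=sequence_length)
                start = int(rng.integers(0, sequence_length - motif_length + 1))
                bg[start : start + motif_length] = list(motif)
                residues = "".join(bg)
            dataset.append(
                LabeledSequence(id="seq%06d" % next(serial), label=label, residues=residues)
            )
    return dataset


# ------------------------------------------------------ simulated predictions

Rates = Union[Sequence[float], Mapping[int, float]]


def _rate_fn(rates: Rates):
    if isinstance(rates, Mapping):
        table = dict(rates)
    else:
        table = dict(enumerate(rates))
    for r, p in table.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError("corruption rate %r at rank %d outside [0, 1]" % (p, r))
    return lambda r: table.get(r, 0.0)


def simulate_predictions(
    dataset: Sequence[LabeledSequence],
    rates: Rates,
    seed: int = 0,
) -> List[PredictionRecord]:
    """Predictions equal to the truth except for controlled per-rank noise.

    Rank position r of each sequence's label is independently replaced with
    probability ``rates[r]`` (positions beyond the given rates are left
    intact) by a *sibling* name — another name occurring at that position
    under the same parent prefix in the dataset's taxonomy — or by a novel
    name when the taxon has no sibling there.  A replaced rank always
    differs from the true one, so with a uniform label depth d and only the
    lowest rank corrupted at rate p, the expected per-sequence TD is p/d.

    Raises
    ------
    ValueError
        If any rate is outside [0, 1].
    """
    rate = _rate_fn(rates)
    rng = np.random.default_rng(seed)

    siblings: Dict[Tuple[str, ...], Set[str]] = {}
    for seq in dataset:
        ranks = seq.label.ranks
        for r in range(len(ranks)):
            siblings.setdefault(ranks[:r], set()).add(ranks[r])

    novel = itertools.count(1)
    records: List[PredictionRecord] = []
    for seq in dataset:
        truth = seq.label
        pred = list(truth.ranks)
        for r in range(truth.depth):
            if rng.random() < rate(r):
                options = sorted(siblings.get(truth.ranks[:r], set()) - {truth.ranks[r]})
                if options:
                    pred[r] = options[int(rng.integers(len(options)))]
                else:
                    pred[r] = "novel_%d_%04d" % (r, next(novel))
        records.append(
            PredictionRecord(seq.id, truth, RankedLabel(tuple(pred)), fold=-1)
        )
    return records


def estimate_corruption_rates(
    records: Sequence[PredictionRecord], n_ranks: int
) -> List[float]:
    """Observed per-rank mismatch frequencies of a prediction table.

    For each rank position r, the fraction of records (among those whose
    truth annotates rank r) whose prediction misses or differs at r.  On a
    table from :func:`simulate_predictions` this recovers the corruption
    rates up to sampling error.
    """
    freqs: List[float] = []
    for r in range(n_ranks):
        eligible = [rec for rec in records if rec.truth.depth > r]
        if not eligible:
            freqs.append(float("nan"))
            continue
        mismatched = sum(
            1
            for rec in eligible
            if rec.prediction.depth <= r
            or rec.prediction.ranks[r] != rec.truth.ranks[r]
        )
        freqs.append(mismatched / len(eligible))
    return freqs
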