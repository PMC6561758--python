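"""Taxonomy-based performance metrics for taxonomic assignment.

The per-prediction unit is the Taxonomy Distance (TD) between a true and a
predicted ranked lineage:

    TD = (number of ranks in difference) / (number of unique ranks in the two labels)

where the denominator is the deeper of the two depths and a rank position
counts as "in difference" when the names differ or only one label annotates
it.  TD is 0 for identical labels and 1 for labels disjoint at every rank;
it is kept as an exact rational (`fractions.Fraction`) and rendered as a
float only at report boundaries.

Per-taxon, the Average Taxonomy Distance (ATD) of a taxon with N truly
assigned sequences s_1..s_N and predictions P(s_i) is

    ATD = (1/N) * sum_i TD(s_i, P(s_i))

and the overall, taxon-count-based score is ATD_by_Taxa, the unweighted mean
of the M per-taxon ATDs.  Sequence-count-based counterparts (ATD_by_seq,
Err_by_seq) and the taxon-count binary metric (Err_by_taxa) are computed on
the same prediction table so the four viewpoints are directly comparable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, NamedTuple, Sequence, Tuple

import numpy as np

from .taxonomy import RankedLabel, TaxonomyTree, common_prefix_length

__all__ = [
    "PredictionRecord",
    "TaxonReport",
    "EvaluationReport",
    "DatasetSummary",
    "taxonomy_distance",
    "binary_error",
    "edge_distance",
    "atd",
    "evaluate",
    "dataset_summary",
]


@dataclass(frozen=True)
class PredictionRecord:
    """One classified sequence: its true and predicted lineage.

    ``fold`` is the cross-validation fold index the sequence was tested in,
    or -1 when no cross-validation was performed.
    """

    sequence_id: str
    truth: RankedLabel
    prediction: RankedLabel
    fold: int = -1


def taxonomy_distance(a: RankedLabel, b: RankedLabel) -> Fraction:
    """Taxonomy Distance between two ranked lineages, as an exact rational.

    Counts the rank positions (over ``0..max(depth)-1``) where the names
    differ or only one label has a rank, divided by the deeper depth.  Two
    depth-0 labels are at distance 0.  Matching is positional: a position is
    compared independently of whether an earlier position matched.
    """
    d = max(a.depth, b.depth)
    if d == 0:
        return Fraction(0)
    mismatches = 0
    for i in range(d):
        if i >= a.depth or i >= b.depth or a.ranks[i] != b.ranks[i]:
            mismatches += 1
    return Fraction(mismatches, d)


def binary_error(a: RankedLabel, b: RankedLabel) -> int:
    """0 iff the two full normalized lineages are equal, else 1.

    Always an upper bound on :func:`taxonomy_distance` for the same pair.
    """
    return 0 if a == b else 1


def edge_distance(tree: TaxonomyTree, a: RankedLabel, b: RankedLabel) -> int:
    """Number of edges on the path between two labels' nodes in `tree`.

    This is the unit-branch-length, pair-based comparator (the UniFrac-style
    minimum tree distance): ``depth(a) + depth(b) - 2 * shared prefix``.
    Unlike TD it grows with over-specialization depth rather than with the
    fraction of ranks in error.

    Raises
    ------
    KeyError
        If either label is not a node of `tree`.
    """
    tree.node(a)
    tree.node(b)
    return a.depth + b.depth - 2 * common_prefix_length(a, b)


def atd(records: Sequence[PredictionRecord]) -> Fraction:
    """Average Taxonomy Distance of predictions sharing one true taxon.

    Raises
    ------
    ValueError
        If `records` is empty or the records disagree on the true label.
    """
    if not records:
        raise ValueError("ATD of an empty record set is undefined")
    truth = records[0].truth
    if any(r.truth != truth for r in records):
        raise ValueError("records do not share a single true taxon")
    return sum(
        (taxonomy_distance(r.truth, r.prediction) for r in records), Fraction(0)
    ) / len(records)


@dataclass(frozen=True)
class TaxonReport:
    """Per-taxon aggregation over the sequences truly in that taxon."""

    taxon: RankedLabel
    n_sequences: int
    atd: Fraction
    binary_error_rate: Fraction


@dataclass(frozen=True)
class EvaluationReport:
    """All per-taxon reports plus the four overall metrics and dispersions.

    ``atd_by_taxa``/``err_by_taxa`` weight each of the M taxa equally;
    ``atd_by_seq``/``err_by_seq`` weight each sequence equally.  Dispersions
    are population standard deviations: ``sd_by_seq`` over per-record TDs,
    ``sd_by_taxa`` over per-taxon ATDs, ``sd_err_by_taxa`` over per-taxon
    binary error rates.
    """

    taxon_reports: Tuple[TaxonReport, ...]
    atd_by_taxa: Fraction
    atd_by_seq: Fraction
    err_by_taxa: Fraction
    err_by_seq: Fraction
    sd_by_taxa: float
    sd_by_seq: float
    sd_err_by_taxa: float

    @property
    def n_taxa(self) -> int:
        """M, the number of distinct true taxa."""
        return len(self.taxon_reports)

    @property
    def n_sequences(self) -> int:
        return sum(t.n_sequences for t in self.taxon_reports)

    def taxon_atds(self) -> Dict[RankedLabel, Fraction]:
        return {t.taxon: t.atd for t in self.taxon_reports}


def evaluate(records: Sequence[PredictionRecord]) -> EvaluationReport:
    """Evaluate a full prediction table, grouping by the TRUE label.

    Raises
    ------
    ValueError
        On an empty table or duplicated sequence IDs.
    """
    if not records:
        raise ValueError("cannot evaluate an empty prediction table")
    seen = Counter(r.sequence_id for r in records)
    dups = [sid for sid, n in seen.items() if n > 1]
    if dups:
        raise ValueError("duplicate sequence IDs in prediction table: %s" % dups[:10])

    by_taxon: Dict[RankedLabel, List[PredictionRecord]] = {}
    for r in records:
        by_taxon.setdefault(r.truth, []).append(r)

    tds = [taxonomy_distance(r.truth, r.prediction) for r in records]
    errs = [binary_error(r.truth, r.prediction) for r in records]

    reports: List[TaxonReport] = []
    for taxon in sorted(by_taxon, key=lambda t: t.ranks):
        recs = by_taxon[taxon]
        n = len(recs)
        taxon_atd = sum(
            (taxonomy_distance(r.truth, r.prediction) for r in recs), Fraction(0)
        ) / n
        err_rate = Fraction(
            sum(binary_error(r.truth, r.prediction) for r in recs), n
        )
        reports.append(TaxonReport(taxon, n, taxon_atd, err_rate))

    m = len(reports)
    atd_by_taxa = sum((t.atd for t in reports), Fraction(0)) / m
    err_by_taxa = sum((t.binary_error_rate for t in reports), Fraction(0)) / m
    atd_by_seq = sum(tds, Fraction(0)) / len(records)
    err_by_seq = Fraction(sum(errs), len(records))

    return EvaluationReport(
        taxon_reports=tuple(reports),
        atd_by_taxa=atd_by_taxa,
        atd_by_seq=atd_by_seq,
        err_by_taxa=err_by_taxa,
        err_by_seq=err_by_seq,
        sd_by_taxa=float(np.std([float(t.atd) for t in reports])),
        sd_by_seq=float(np.std([float(td) for td in tds])),
        sd_err_by_taxa=float(
            np.std([float(t.binary_error_rate) for t in reports])
        ),
    )


class DatasetSummary(NamedTuple):
    n_sequences: int
    n_taxa: int
    n_singletons: int


def dataset_summary(dataset: Iterable) -> DatasetSummary:
    """Sequence/taxon/singleton counts of a labeled dataset.

    Accepts an iterable of :class:`~taxodist.taxonomy.RankedLabel` or of any
    objects with a ``label`` attribute (e.g. labeled sequences).  A taxon is
    a distinct full lineage; a singleton is a taxon with exactly one
    sequence.
    """
    counts: Counter = Counter()
    for item in dataset:
        label = item if isinstance(item, RankedLabel) else item.label
        counts[label] += 1
    n_seq = sum(counts.values())
    n_singletons = sum(1 for n in counts.values() if n == 1)
    return DatasetSummary(n_seq, len(counts), n_singletons)
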