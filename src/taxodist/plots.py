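"""ATD plots and the cumulative taxon-imbalance plot.

The ATD plot draws per-taxon ATDs sorted in ascending order against the
fraction of taxa, so "the method is perfectly correct on half of the taxa"
reads off as the series staying at 0 until x = 0.5, and one-rank errors on
depth-6 lineages show up as a plateau near TD 1/6.  Merged ATD plots
overlay several methods (the Plateau oracle drawn distinctly) on the same
axes; a paired per-taxon difference series shows how far each method sits
from another.  The cumulative-fraction plot sorts taxa by descending
sequence count and accumulates sequence fractions: balanced data lies on
the 45-degree diagonal, imbalanced data bows above it.

Every series is also available as plain data (and exportable as TSV) so
figures can be restyled downstream.
"""

from __future__ import annotations

import csv
from collections import Counter
from pathlib import Path
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import matplotlib.pyplot as plt

from .metrics import EvaluationReport
from .taxonomy import RankedLabel

__all__ = [
    "atd_plot_series",
    "atd_difference_series",
    "cumulative_fraction_series",
    "atd_plot",
    "merged_atd_plot",
    "cumulative_fraction_plot",
    "write_series_tsv",
]

Series = List[Tuple[float, float]]


def atd_plot_series(report: EvaluationReport, normalized: bool = True) -> Series:
    """Per-taxon ATDs sorted ascending, against taxon fraction.

    x is ``(rank index)/M`` in (0, 1] when `normalized` (so plots from
    datasets of different sizes overlay), or the 1-based raw index
    otherwise.  Ties in ATD are ordered by taxon label for determinism; the
    y series is therefore non-decreasing.

    Raises
    ------
    ValueError
        On a report with no taxa.
    """
    if not report.taxon_reports:
        raise ValueError("cannot plot an empty report")
    items = sorted(
        report.taxon_reports, key=lambda t: (t.atd, t.taxon.ranks)
    )
    m = len(items)
    return [
        ((i + 1) / m if normalized else float(i + 1), float(t.atd))
        for i, t in enumerate(items)
    ]


def atd_difference_series(
    a: EvaluationReport, b: EvaluationReport, normalized: bool = True
) -> Series:
    """Per-taxon ATD differences (a - b), paired by taxon, sorted ascending.

    Raises
    ------
    ValueError
        If the two reports do not cover the same taxon set.
    """
    atds_a = a.taxon_atds()
    atds_b = b.taxon_atds()
    if set(atds_a) != set(atds_b):
        raise ValueError("reports cover different taxon sets; cannot pair by taxon")
    diffs = sorted(
        ((float(atds_a[t] - atds_b[t]), t.ranks) for t in atds_a),
    )
    m = len(diffs)
    return [
        ((i + 1) / m if normalized else float(i + 1), d)
        for i, (d, _) in enumerate(diffs)
    ]


def cumulative_fraction_series(dataset: Iterable, normalized: bool = True) -> Series:
    """Cumulative sequence fraction over taxa sorted by descending count.

    Accepts labels or labeled sequences.  A perfectly balanced dataset
    yields points on the 45-degree diagonal; heavy imbalance bows the curve
    far above it.  The series is non-decreasing and ends at (1, 1).

    Raises
    ------
    ValueError
        On an empty dataset.
    """
    counts: Counter = Counter()
    for item in dataset:
        label = item if isinstance(item, RankedLabel) else item.label
        counts[label] += 1
    if not counts:
        raise ValueError("cannot summarize an empty dataset")
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0].ranks))
    total = sum(counts.values())
    m = len(ordered)
    series: Series = []
    running = 0
    for i, (_, n) in enumerate(ordered):
        running += n
        x = (i + 1) / m if normalized else float(i + 1)
        series.append((x, running / total))
    return series


def _plot_series(ax, series: Series, label: Optional[str] = None, **kwargs):
    xs = [x for x, _ in series]
    ys = [y for _, y in series]
    return ax.plot(xs, ys, label=label, **kwargs)


def atd_plot(report: EvaluationReport, ax=None, label: Optional[str] = None):
    """Render the ATD plot for one report; returns the axes."""
    if ax is None:
        _, ax = plt.subplots()
    _plot_series(ax, atd_plot_series(report), label=label, drawstyle="steps-post")
    ax.set_xlabel("fraction of taxa")
    ax.set_ylabel("ATD")
    ax.set_xlim(0, 1)
    ax.set_ylim(-0.02, 1.02)
    return ax


def merged_atd_plot(
    reports: Mapping[str, EvaluationReport],
    plateau: Optional[str] = None,
):
    """Overlay the ATD plots of several methods on shared axes.

    All reports must cover the same taxon set (the same dataset).  The
    report named by `plateau` — the best-achievable reference — is drawn
    as a distinct dashed black line.  Returns the figure.

    Raises
    ------
    ValueError
        On an empty mapping or mismatched taxon sets.
    """
    if not reports:
        raise ValueError("no reports to plot")
    taxon_sets = {name: set(r.taxon_atds()) for name, r in reports.items()}
    reference = next(iter(taxon_sets.values()))
    for name, s in taxon_sets.items():
        if s != reference:
            raise ValueError("report %r covers a different taxon set" % name)
    fig, ax = plt.subplots()
    for name, report in reports.items():
        style = (
            dict(color="black", linestyle="--", linewidth=2.0)
            if plateau is not None and name == plateau
            else {}
        )
        _plot_series(
            ax, atd_plot_series(report), label=name, drawstyle="steps-post", **style
        )
    ax.set_xlabel("fraction of taxa")
    ax.set_ylabel("ATD")
    ax.set_xlim(0, 1)
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return fig


def cumulative_fraction_plot(dataset: Iterable, ax=None, label: Optional[str] = None):
    """Render the cumulative taxon-imbalance plot with the 45-degree guide."""
    if ax is None:
        _, ax = plt.subplots()
    series = cumulative_fraction_series(dataset)
    _plot_series(ax, series, label=label)
    ax.plot([0, 1], [0, 1], color="grey", linestyle=":", linewidth=1)
    ax.set_xlabel("fraction of taxa (descending sequence count)")
    ax.set_ylabel("cumulative sequence fraction")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    return ax


def write_series_tsv(
    series: Series, path: Union[str, Path], header: Sequence[str] = ("x", "y")
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(list(header))
        for x, y in series:
            writer.writerow(["%.10g" % x, "%.10g" % y])
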