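"""Shared hypothesis strategies and independent brute-force oracles."""

from fractions import Fraction
from typing import List, Sequence

import hypothesis.strategies as st
import numpy as np

from taxodist import PredictionRecord, RankedLabel

# A small name pool forces frequent partial matches between random labels.
NAME_POOL = ["alpha", "beta", "gamma", "delta", "epsi", "zeta", "eta", "theta"]

rank_names = st.sampled_from(NAME_POOL)


def ranked_labels(min_depth: int = 0, max_depth: int = 6) -> st.SearchStrategy:
    return st.lists(rank_names, min_size=min_depth, max_size=max_depth).map(
        lambda ranks: RankedLabel(tuple(ranks))
    )


def prediction_tables(
    min_records: int = 1, max_records: int = 30
) -> st.SearchStrategy:
    record = st.tuples(ranked_labels(max_depth=4), ranked_labels(max_depth=4))
    return st.lists(record, min_size=min_records, max_size=max_records).map(
        lambda pairs: [
            PredictionRecord("s%d" % i, t, p) for i, (t, p) in enumerate(pairs)
        ]
    )


def random_label(rng: np.random.Generator, max_depth: int = 5) -> RankedLabel:
    depth = int(rng.integers(0, max_depth + 1))
    return RankedLabel(
        tuple(NAME_POOL[int(rng.integers(len(NAME_POOL)))] for _ in range(depth))
    )


# ----------------------------------------------------------- oracles

def brute_td(a: RankedLabel, b: RankedLabel) -> Fraction:
    """Independent TD: pad the shorter label with None and compare slots."""
    d = max(len(a.ranks), len(b.ranks))
    if d == 0:
        return Fraction(0)
    pa = list(a.ranks) + [None] * (d - len(a.ranks))
    pb = list(b.ranks) + [None] * (d - len(b.ranks))
    wrong = sum(1 for x, y in zip(pa, pb) if x is None or y is None or x != y)
    return Fraction(wrong, d)


def brute_plateau_best_td(
    truth: RankedLabel, training: Sequence[RankedLabel]
) -> Fraction:
    """Enumerate every prefix of every training label and take the min TD."""
    best = None
    for label in training:
        for k in range(len(label.ranks) + 1):
            td = brute_td(truth, RankedLabel(label.ranks[:k]))
            if best is None or td < best:
                best = td
    return best


def brute_evaluate(records: List[PredictionRecord]) -> dict:
    """Naive double-loop recomputation of the overall metrics."""
    taxa = sorted({r.truth for r in records}, key=lambda t: t.ranks)
    atds, errs = [], []
    for taxon in taxa:
        group = [r for r in records if r.truth == taxon]
        atds.append(
            sum((brute_td(r.truth, r.prediction) for r in group), Fraction(0))
            / len(group)
        )
        errs.append(
            Fraction(sum(1 for r in group if r.truth != r.prediction), len(group))
        )
    n = len(records)
    return {
        "atd_by_taxa": sum(atds, Fraction(0)) / len(taxa),
        "err_by_taxa": sum(errs, Fraction(0)) / len(taxa),
        "atd_by_seq": sum(
            (brute_td(r.truth, r.prediction) for r in records), Fraction(0)
        )
        / n,
        "err_by_seq": Fraction(sum(1 for r in records if r.truth != r.prediction), n),
        "sd_by_taxa": float(np.std([float(a) for a in atds])),
        "sd_by_seq": float(
            np.std([float(brute_td(r.truth, r.prediction)) for r in records])
        ),
        "sd_err_by_taxa": float(np.std([float(e) for e in errs])),
    }
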