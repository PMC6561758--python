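"""Minimal k-mer nearest-neighbor classifier.

Demonstrative plumbing so the toolkit can run end to end without external
classifier binaries: each sequence is reduced to counts of its length-w DNA
words (w = 8 by default, the word length typical of k-mer rRNA classifiers)
and a query receives the label of the training sequence with the highest
cosine similarity between raw count profiles.  No fidelity to any specific
production classifier's scoring is claimed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .taxonomy import RankedLabel

__all__ = ["KmerProfile", "kmer_profile", "onenn_classify", "OneNNClassifier"]

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class KmerProfile:
    """Sparse k-mer count profile of one sequence.

    For a sequence over the DNA alphabet the counts sum to
    ``max(0, length - word + 1)``; windows containing non-ACGT characters
    are skipped.
    """

    word: int
    counts: Dict[str, int]
    length: int

    @property
    def norm(self) -> float:
        return math.sqrt(sum(c * c for c in self.counts.values()))


def kmer_profile(sequence: str, word: int = 8) -> KmerProfile:
    """Count every length-`word` window of A/C/G/T characters.

    The sequence is upper-cased first; windows touching any other character
    (N, gaps, ...) contribute nothing.

    Raises
    ------
    ValueError
        If ``word < 1``.
    """
    if word < 1:
        raise ValueError("word length must be >= 1")
    seq = sequence.upper()
    counts: Dict[str, int] = {}
    for i in range(len(seq) - word + 1):
        kmer = seq[i : i + word]
        if all(c in _DNA for c in kmer):
            counts[kmer] = counts.get(kmer, 0) + 1
    return KmerProfile(word=word, counts=counts, length=len(seq))


def _cosine(a: KmerProfile, b: KmerProfile, b_norm: float) -> float:
    a_norm = a.norm
    if a_norm == 0.0 or b_norm == 0.0:
        return 0.0
    small, large = (a.counts, b.counts) if len(a.counts) <= len(b.counts) else (b.counts, a.counts)
    dot = sum(c * large.get(k, 0) for k, c in small.items())
    return dot / (a_norm * b_norm)


def onenn_classify(
    query: KmerProfile,
    references: Sequence[Tuple[KmerProfile, RankedLabel]],
) -> RankedLabel:
    """Label of the reference with the highest cosine similarity to `query`.

    Ties (including the all-orthogonal case) are broken by reference
    insertion order: the earliest reference wins.

    Raises
    ------
    ValueError
        If `references` is empty.
    """
    if not references:
        raise ValueError("at least one reference profile is required")
    best_label = references[0][1]
    best_sim = _cosine(query, references[0][0], references[0][0].norm)
    for profile, label in references[1:]:
        sim = _cosine(query, profile, profile.norm)
        if sim > best_sim:
            best_sim = sim
            best_label = label
    return best_label


class OneNNClassifier:
    """Nearest-neighbor classifier over k-mer count profiles.

    Implements the cross-validation classifier contract
    (:class:`taxodist.cv.Classifier`).  Deterministic given identical
    inputs: training order fixes the tie-break.
    """

    def __init__(self, word: int = 8) -> None:
        self.word = word
        self._references: List[Tuple[KmerProfile, RankedLabel]] = []

    def train(self, sequences: Sequence) -> None:
        refs: List[Tuple[KmerProfile, RankedLabel]] = []
        for s in sequences:
            if s.residues is None:
                raise ValueError("sequence %r has no residues to profile" % s.id)
            refs.append((kmer_profile(s.residues, self.word), s.label))
        if not refs:
            raise ValueError("empty training set")
        self._references = refs

    def predict(self, sequences: Sequence) -> List[RankedLabel]:
        if not self._references:
            raise ValueError("classifier has not been trained")
        out: List[RankedLabel] = []
        for s in sequences:
            if s.residues is None:
                raise ValueError("sequence %r has no residues to profile" % s.id)
            out.append(onenn_classify(kmer_profile(s.residues, self.word), self._references))
        return out
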