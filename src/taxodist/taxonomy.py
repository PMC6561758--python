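"""Ranked lineage labels and the taxonomy tree they span.

A taxonomic label is an ordered path of rank names from a high rank down to
the lowest annotated rank, e.g. ``orderA;familyB;generaD``.  Labels are
compared positionally and string-exactly (case-sensitive after whitespace
trimming): no fixed rank vocabulary (kingdom/phylum/...) is assumed, and a
*taxon* is identified by its full normalized lineage — two sequences share a
taxon iff their labels are equal.

Two on-disk dialects are supported:

* ``mothur`` — semicolon-delimited with a trailing semicolon, optionally with
  per-rank parenthesized bootstrap confidences (``Bacteria(100);``), which are
  stripped on parse and never affect comparison;
* ``sintax`` — the comma form with rank-letter prefixes used inside USEARCH
  ``tax=`` annotations (``d:Bacteria,p:Firmicutes``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple, Union

__all__ = [
    "LabelError",
    "RankedLabel",
    "ROOT",
    "parse_label",
    "format_label",
    "common_prefix_length",
    "trim",
    "TaxonomyTree",
    "build_tree",
    "MOTHUR",
    "SINTAX",
    "SINTAX_RANK_PREFIXES",
]

MOTHUR = "mothur"
SINTAX = "sintax"

#: Default single-letter rank prefixes for the SINTAX dialect
#: (domain, phylum, class, order, family, genus, species).
SINTAX_RANK_PREFIXES: Tuple[str, ...] = ("d", "p", "c", "o", "f", "g", "s")

_CONFIDENCE_RE = re.compile(r"\((\d+(?:\.\d+)?)\)$")


class LabelError(ValueError):
    """A lineage string that cannot be normalized into a :class:`RankedLabel`."""


@dataclass(frozen=True, order=True)
class RankedLabel:
    """An ordered lineage of rank names, position 0 being the highest rank.

    Instances are immutable, hashable and ordered lexicographically by their
    rank tuple, so they can key dictionaries and sort deterministically.
    """

    ranks: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.ranks, tuple):
            object.__setattr__(self, "ranks", tuple(self.ranks))
        for r in self.ranks:
            if not r:
                raise LabelError("empty rank name in %r" % (self.ranks,))

    @property
    def depth(self) -> int:
        """Number of annotated ranks (0 for the root label)."""
        return len(self.ranks)

    def __iter__(self) -> Iterator[str]:
        return iter(self.ranks)

    def __str__(self) -> str:
        return format_label(self, MOTHUR)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return "RankedLabel(%s)" % ";".join(self.ranks)


#: The depth-0 label: a completely unclassified lineage.
ROOT = RankedLabel(())


def _strip_confidence(component: str) -> str:
    """Remove a trailing ``(confidence)`` annotation from one lineage component."""
    if component.endswith(")"):
        m = _CONFIDENCE_RE.search(component)
        if m is None:
            raise LabelError(
                "malformed confidence annotation in component %r" % component
            )
        component = component[: m.start()].strip()
    return component


def parse_label(text: str, dialect: str = MOTHUR) -> RankedLabel:
    """Parse a lineage string into a :class:`RankedLabel`.

    Whitespace is trimmed per component, trailing empty components (from a
    trailing semicolon) are dropped, and parenthesized per-rank confidences
    are stripped.  An input that is empty after normalization yields the
    depth-0 root label, not an error.

    Parameters
    ----------
    text:
        Lineage string, e.g. ``"orderA;familyB;generaD"`` or
        ``"Bacteria(100);Firmicutes(87);"`` (mothur) or
        ``"d:Bacteria,p:Firmicutes"`` (sintax).
    dialect:
        ``"mothur"`` or ``"sintax"``.

    Raises
    ------
    LabelError
        On a malformed confidence annotation or an empty internal component;
        the message names the offending component.
    """
    if dialect == MOTHUR:
        parts = [p.strip() for p in text.split(";")]
        while parts and parts[-1] == "":
            parts.pop()
        ranks: List[str] = []
        for i, p in enumerate(parts):
            if p == "":
                raise LabelError("empty rank name at position %d in %r" % (i, text))
            ranks.append(_strip_confidence(p))
        return RankedLabel(tuple(ranks))
    if dialect == SINTAX:
        text = text.strip()
        if text.endswith(";"):
            text = text[:-1]
        if not text:
            return ROOT
        ranks = []
        for i, item in enumerate(text.split(",")):
            item = item.strip()
            if ":" in item:
                item = item.split(":", 1)[1].strip()
            if not item:
                raise LabelError("empty rank name at position %d in %r" % (i, text))
            ranks.append(_strip_confidence(item))
        return RankedLabel(tuple(ranks))
    raise ValueError("unknown dialect %r" % dialect)


def format_label(
    label: RankedLabel,
    dialect: str = MOTHUR,
    prefixes: Sequence[str] = SINTAX_RANK_PREFIXES,
) -> str:
    """Render a label as a lineage string.

    The mothur dialect joins ranks with semicolons and appends a trailing
    semicolon (``orderA;familyB;``); the sintax dialect emits the comma form
    with rank-letter prefixes (``d:NameA,p:NameB``; ranks deeper than the
    prefix list fall back to ``r<n>``).  The depth-0 label renders as ``""``
    in both dialects, and ``parse_label(format_label(x)) == x`` for any label
    whose rank names are free of the dialect's delimiter characters.
    """
    if dialect == MOTHUR:
        return "".join(r + ";" for r in label.ranks)
    if dialect == SINTAX:
        items = []
        for i, r in enumerate(label.ranks):
            prefix = prefixes[i] if i < len(prefixes) else "r%d" % (i + 1)
            items.append("%s:%s" % (prefix, r))
        return ",".join(items)
    raise ValueError("unknown dialect %r" % dialect)


def common_prefix_length(a: RankedLabel, b: RankedLabel) -> int:
    """Length of the longest shared leading run of rank names.

    Returns the largest ``c`` such that ranks ``0..c-1`` of `a` and `b` are
    pairwise equal strings.  Symmetric; bounded by ``min(a.depth, b.depth)``.
    """
    c = 0
    for x, y in zip(a.ranks, b.ranks):
        if x != y:
            break
        c += 1
    return c


def trim(label: RankedLabel, k: int) -> RankedLabel:
    """The first `k` ranks of `label` ("trimmed" lineage).

    Raises
    ------
    ValueError
        If ``k`` is outside ``0..label.depth``.
    """
    if not 0 <= k <= label.depth:
        raise ValueError("trim depth %d out of range for depth-%d label" % (k, label.depth))
    return RankedLabel(label.ranks[:k])


@dataclass
class TreeNode:
    """One node of a :class:`TaxonomyTree`, keyed by its lineage prefix."""

    key: Tuple[str, ...]
    count: int = 0  #: sequences whose full label passes through this node
    terminal: int = 0  #: sequences whose full label is exactly this node
    children: List[str] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.key)


class TaxonomyTree:
    """Rooted tree over a label set.

    Every lineage prefix of every added label becomes a node; a node's count
    is the number of sequences whose full label passes through it, so the
    root's count equals the total number of sequences and, at every node,
    ``count == terminal + sum(child counts)``.
    """

    def __init__(self) -> None:
        self._nodes: Dict[Tuple[str, ...], TreeNode] = {(): TreeNode(())}

    def add(self, label: RankedLabel, count: int = 1) -> None:
        """Add `count` sequences carrying `label`."""
        if count < 0:
            raise ValueError("negative sequence count")
        key: Tuple[str, ...] = ()
        self._nodes[key].count += count
        for rank in label.ranks:
            parent = self._nodes[key]
            key = key + (rank,)
            node = self._nodes.get(key)
            if node is None:
                node = self._nodes[key] = TreeNode(key)
                parent.children.append(rank)
            node.count += count
        self._nodes[label.ranks].terminal += count

    def __contains__(self, label: RankedLabel) -> bool:
        return tuple(label.ranks) in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, label: RankedLabel) -> TreeNode:
        try:
            return self._nodes[tuple(label.ranks)]
        except KeyError:
            raise KeyError("label %r is not a node of this tree" % str(label)) from None

    def children(self, label: RankedLabel) -> List[RankedLabel]:
        node = self.node(label)
        return [RankedLabel(node.key + (c,)) for c in node.children]

    def nodes(self) -> Iterator[TreeNode]:
        return iter(self._nodes.values())

    @property
    def root(self) -> TreeNode:
        return self._nodes[()]

    @property
    def total_sequences(self) -> int:
        return self.root.count


LabelsWithCounts = Union[Iterable[RankedLabel], Iterable[Tuple[RankedLabel, int]]]


def build_tree(labels: LabelsWithCounts) -> TaxonomyTree:
    """Build a :class:`TaxonomyTree` from labels or ``(label, count)`` pairs.

    Bare labels count as one sequence each; an empty input yields a
    root-only tree.
    """
    tree = TaxonomyTree()
    for item in labels:
        if isinstance(item, RankedLabel):
            tree.add(item, 1)
        else:
            label, count = item
            tree.add(label, count)
    return tree
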