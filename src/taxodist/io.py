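"""Readers and writers for the on-disk formats the toolkit touches.

Formats: plain FASTA, mothur taxonomy TSV (``.tax``: sequence ID, tab,
semicolon-delimited lineage), SINTAX-annotated FASTA
(``>seqID;tax=d:NameA,p:NameB;``), the prediction-table TSV and the
evaluation-report TSV.  All files are UTF-8 text; every reader/writer pair
round-trips losslessly.

Truth and prediction taxonomy files are joined by sequence ID as an inner
join, and unmatched IDs are an error by default — silently dropping
unclassifiable sequences makes evaluation results overly optimistic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from Bio import SeqIO

from .metrics import EvaluationReport, PredictionRecord
from .taxonomy import (
    MOTHUR,
    SINTAX,
    SINTAX_RANK_PREFIXES,
    LabelError,
    RankedLabel,
    format_label,
    parse_label,
)

__all__ = [
    "LabeledSequence",
    "FileFormatError",
    "read_mothur_taxonomy",
    "write_mothur_taxonomy",
    "read_fasta",
    "write_fasta",
    "read_sintax_fasta",
    "write_sintax_fasta",
    "mothur_to_sintax",
    "read_prediction_table",
    "write_prediction_table",
    "write_evaluation_report",
    "join_taxonomy_files",
]

PathLike = Union[str, Path]


class FileFormatError(ValueError):
    """A malformed input file; messages carry line/row numbers."""


@dataclass(frozen=True)
class LabeledSequence:
    """One sequence with its true lineage; residues are optional because
    metric-only workflows need no sequence data."""

    id: str
    label: RankedLabel
    residues: Optional[str] = None


# ---------------------------------------------------------------- mothur .tax

def read_mothur_taxonomy(path: PathLike) -> List[Tuple[str, RankedLabel]]:
    """Read a two-column mothur taxonomy TSV.

    Classifier outputs with per-rank confidences (``Bacteria(100);``) are
    accepted; confidences are stripped.

    Raises
    ------
    FileFormatError
        On a wrong column count, a duplicate sequence ID, or a malformed
        lineage — always with the offending line number.
    """
    out: List[Tuple[str, RankedLabel]] = []
    seen: Dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FileFormatError(
                    "%s, line %d: expected 2 tab-separated columns, found %d"
                    % (path, lineno, len(fields))
                )
            sid, lineage = fields[0].strip(), fields[1]
            if not sid:
                raise FileFormatError("%s, line %d: empty sequence ID" % (path, lineno))
            if sid in seen:
                raise FileFormatError(
                    "%s, line %d: duplicate sequence ID %r (first seen line %d)"
                    % (path, lineno, sid, seen[sid])
                )
            seen[sid] = lineno
            try:
                label = parse_label(lineage, MOTHUR)
            except LabelError as exc:
                raise FileFormatError("%s, line %d: %s" % (path, lineno, exc)) from exc
            out.append((sid, label))
    return out


def write_mothur_taxonomy(
    entries: Iterable[Tuple[str, RankedLabel]], path: PathLike
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, label in entries:
            fh.write("%s\t%s\n" % (sid, format_label(label, MOTHUR)))


# ---------------------------------------------------------------------- FASTA

def _fasta_id(raw_id: str) -> str:
    """Header token before the first whitespace (SeqIO) or semicolon."""
    return raw_id.split(";")[0]


def read_fasta(path: PathLike) -> List[Tuple[str, str]]:
    """Read FASTA records as ``(id, residues)`` pairs.

    Raises
    ------
    FileFormatError
        On an empty sequence or a duplicate ID.
    """
    out: List[Tuple[str, str]] = []
    seen: set = set()
    for record in SeqIO.parse(str(path), "fasta"):
        sid = _fasta_id(record.id)
        residues = str(record.seq)
        if not residues:
            raise FileFormatError("%s: record %r has an empty sequence" % (path, sid))
        if sid in seen:
            raise FileFormatError("%s: duplicate sequence ID %r" % (path, sid))
        seen.add(sid)
        out.append((sid, residues))
    return out


def write_fasta(records: Iterable[Tuple[str, str]], path: PathLike, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, residues in records:
            fh.write(">%s\n" % sid)
            for i in range(0, len(residues), width):
                fh.write(residues[i : i + width] + "\n")


# ------------------------------------------------------- SINTAX-annotated FASTA

def read_sintax_fasta(path: PathLike) -> List[LabeledSequence]:
    """Read a FASTA whose headers carry ``;tax=...;`` annotations.

    Raises
    ------
    FileFormatError
        If a record lacks a ``tax=`` annotation or its lineage is malformed.
    """
    out: List[LabeledSequence] = []
    seen: set = set()
    for record in SeqIO.parse(str(path), "fasta"):
        sid = _fasta_id(record.id)
        if sid in seen:
            raise FileFormatError("%s: duplicate sequence ID %r" % (path, sid))
        seen.add(sid)
        annotation = None
        for part in record.description.split(";"):
            part = part.strip()
            if part.startswith("tax="):
                annotation = part[len("tax=") :]
                break
        if annotation is None:
            raise FileFormatError(
                "%s: record %r has no tax= annotation in its header" % (path, sid)
            )
        try:
            label = parse_label(annotation, SINTAX)
        except LabelError as exc:
            raise FileFormatError("%s: record %r: %s" % (path, sid, exc)) from exc
        out.append(LabeledSequence(id=sid, label=label, residues=str(record.seq)))
    return out


def write_sintax_fasta(
    sequences: Iterable[LabeledSequence],
    path: PathLike,
    prefixes: Sequence[str] = SINTAX_RANK_PREFIXES,
    width: int = 60,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for seq in sequences:
            if seq.residues is None:
                raise ValueError("sequence %r has no residues" % seq.id)
            fh.write(">%s;tax=%s;\n" % (seq.id, format_label(seq.label, SINTAX, prefixes)))
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def mothur_to_sintax(
    tax_path: PathLike,
    fasta_path: PathLike,
    out_path: PathLike,
    prefixes: Sequence[str] = SINTAX_RANK_PREFIXES,
) -> None:
    """Convert a mothur taxonomy + template FASTA pair to SINTAX FASTA.

    Raises
    ------
    FileFormatError
        If any FASTA ID is absent from the taxonomy file; all missing IDs
        are listed.
    """
    labels = dict(read_mothur_taxonomy(tax_path))
    records = read_fasta(fasta_path)
    missing = [sid for sid, _ in records if sid not in labels]
    if missing:
        raise FileFormatError(
            "%s: %d FASTA IDs absent from %s: %s"
            % (fasta_path, len(missing), tax_path, ", ".join(sorted(missing)))
        )
    write_sintax_fasta(
        (LabeledSequence(sid, labels[sid], residues) for sid, residues in records),
        out_path,
        prefixes,
    )


# ----------------------------------------------------------- prediction table

_PREDICTION_HEADER = ("seq_id", "truth", "prediction", "fold")


def read_prediction_table(path: PathLike) -> List[PredictionRecord]:
    """Read a prediction-table TSV (seq_id, truth, prediction, fold).

    Raises
    ------
    FileFormatError
        On a missing/invalid header, a malformed lineage cell (with its row
        number), or a duplicate sequence ID.
    """
    records: List[PredictionRecord] = []
    seen: set = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = tuple(next(reader))
        except StopIteration:
            raise FileFormatError("%s: empty prediction table" % path) from None
        if header != _PREDICTION_HEADER:
            raise FileFormatError(
                "%s: expected header %s, found %s" % (path, _PREDICTION_HEADER, header)
            )
        for rowno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise FileFormatError(
                    "%s, row %d: expected 4 columns, found %d" % (path, rowno, len(row))
                )
            sid = row[0].strip()
            if sid in seen:
                raise FileFormatError("%s, row %d: duplicate sequence ID %r" % (path, rowno, sid))
            seen.add(sid)
            try:
                truth = parse_label(row[1], MOTHUR)
                prediction = parse_label(row[2], MOTHUR)
            except LabelError as exc:
                raise FileFormatError("%s, row %d: %s" % (path, rowno, exc)) from exc
            try:
                fold = int(row[3])
            except ValueError:
                raise FileFormatError(
                    "%s, row %d: fold %r is not an integer" % (path, rowno, row[3])
                ) from None
            records.append(PredictionRecord(sid, truth, prediction, fold))
    return records


def write_prediction_table(records: Iterable[PredictionRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_PREDICTION_HEADER)
        for r in records:
            writer.writerow(
                [
                    r.sequence_id,
                    format_label(r.truth, MOTHUR),
                    format_label(r.prediction, MOTHUR),
                    r.fold,
                ]
            )


# ----------------------------------------------------------- evaluation report

def write_evaluation_report(report: EvaluationReport, path: PathLike) -> None:
    """Write the per-taxon block and the overall-metric summary block.

    The per-taxon block has one row per true taxon (taxon, n, atd, err);
    the summary block pairs each overall metric with its dispersion (the
    sequence-count binary error rate has no separately defined dispersion
    and gets an empty sd cell).
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["taxon", "n", "atd", "err"])
        for t in report.taxon_reports:
            writer.writerow(
                [
                    format_label(t.taxon, MOTHUR),
                    t.n_sequences,
                    "%.6g" % float(t.atd),
                    "%.6g" % float(t.binary_error_rate),
                ]
            )
        writer.writerow([])
        writer.writerow(["metric", "value", "sd"])
        writer.writerow(["atd_by_taxa", "%.6g" % float(report.atd_by_taxa), "%.6g" % report.sd_by_taxa])
        writer.writerow(["atd_by_seq", "%.6g" % float(report.atd_by_seq), "%.6g" % report.sd_by_seq])
        writer.writerow(["err_by_taxa", "%.6g" % float(report.err_by_taxa), "%.6g" % report.sd_err_by_taxa])
        writer.writerow(["err_by_seq", "%.6g" % float(report.err_by_seq), ""])


# ------------------------------------------------------------------ joining

def join_taxonomy_files(
    truth_path: PathLike,
    prediction_path: PathLike,
    strict: bool = True,
) -> List[PredictionRecord]:
    """Join a truth and a prediction mothur taxonomy file by sequence ID.

    Inner join; with ``strict=True`` (the default) any ID present in one
    file but not the other is an error, listed exhaustively, rather than
    being dropped.

    Fold indices are set to -1 (no cross-validation information in the
    inputs).
    """
    truth = dict(read_mothur_taxonomy(truth_path))
    pred = dict(read_mothur_taxonomy(prediction_path))
    only_truth = sorted(set(truth) - set(pred))
    only_pred = sorted(set(pred) - set(truth))
    if strict and (only_truth or only_pred):
        raise FileFormatError(
            "unmatched sequence IDs: %d only in %s (%s), %d only in %s (%s)"
            % (
                len(only_truth),
                truth_path,
                ", ".join(only_truth[:10]) or "-",
                len(only_pred),
                prediction_path,
                ", ".join(only_pred[:10]) or "-",
            )
        )
    return [
        PredictionRecord(sid, truth[sid], pred[sid], fold=-1)
        for sid in truth
        if sid in pred
    ]
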