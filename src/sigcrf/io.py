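"""Readers and writers for the on-disk formats.

The training format is a 3-line FASTA dialect: a header carrying
``id|organism_group|class``, the amino acid sequence, and a per-residue
annotation string over S/T/L/P/I/M/O.  Predictions travel as TSV, region
calls optionally as GFF3 on 1-based inclusive protein coordinates.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence, Union

from Bio import SeqIO

from .crf import Prediction
from .regions import RegionSummary
from .types import (MATURE_ANNOTATION_CHARS, OrganismGroup, SequenceRecord,
                    SpClass, SP_ANNOTATION_CHAR)

PathLike = Union[str, Path]

_VALID_ANNOTATION = set("STLP" + MATURE_ANNOTATION_CHARS)

PREDICTION_COLUMNS = (
    ["id", "predicted_class"]
    + [f"p_{c.value}" for c in SpClass]
    + ["cs", "cs_prob"]
)


class FormatError(ValueError):
    pass


def _check_annotation(record: SequenceRecord, lineno: int) -> None:
    ann, sp_class = record.annotation, record.sp_class
    assert ann is not None
    bad = set(ann) - _VALID_ANNOTATION
    if bad:
        raise FormatError(
            f"line {lineno}: illegal annotation characters {sorted(bad)} "
            f"in record {record.id}")
    sp_chars = set(ann) & set("STLP")
    if sp_class is SpClass.NO_SP:
        if sp_chars:
            raise FormatError(
                f"line {lineno}: record {record.id} is NO_SP but carries "
                f"SP annotation {sorted(sp_chars)}")
    else:
        expected = SP_ANNOTATION_CHAR[sp_class]
        if sp_chars != {expected}:
            raise FormatError(
                f"line {lineno}: record {record.id} of class "
                f"{sp_class.value} must use SP annotation {expected!r}, "
                f"found {sorted(sp_chars)}")


def read_annotated_fasta(path: PathLike) -> list[SequenceRecord]:
    """Parse the 3-line annotated dialect; errors carry line numbers."""
    lines = Path(path).read_text().splitlines()
    records = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        header = lines[i]
        if not header.startswith(">"):
            raise FormatError(f"line {i + 1}: expected '>' header, got "
                              f"{header[:30]!r}")
        fields = header[1:].strip().split("|")
        if len(fields) != 3:
            raise FormatError(
                f"line {i + 1}: header must be 'id|organism_group|class' "
                f"(got {header!r}); is this plain FASTA?")
        rid, group_s, class_s = fields
        if i + 2 >= len(lines):
            raise FormatError(f"line {i + 1}: truncated record {rid}")
        seq, ann = lines[i + 1].strip(), lines[i + 2].strip()
        if ann.startswith(">") or not seq:
            raise FormatError(
                f"line {i + 1}: record {rid} is missing its sequence or "
                "annotation line")
        if len(seq) != len(ann):
            raise FormatError(
                f"line {i + 3}: record {rid} annotation length {len(ann)} "
                f"!= sequence length {len(seq)}")
        try:
            group = OrganismGroup.from_string(group_s)
            sp_class = SpClass.from_string(class_s)
        except ValueError as exc:
            raise FormatError(f"line {i + 1}: {exc}") from None
        try:
            record = SequenceRecord(
                id=rid, sequence=seq, organism_group=group,
                sp_class=sp_class, annotation=ann)
        except ValueError as exc:
            raise FormatError(f"line {i + 1}: {exc}") from None
        _check_annotation(record, i + 3)
        records.append(record)
        i += 3
    return records


def write_annotated_fasta(records: Sequence[SequenceRecord],
                          path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            ann = r.annotation
            if ann is None:
                raise ValueError(f"record {r.id} has no annotation")
            fh.write(f">{r.id}|{r.organism_group.value}|{r.sp_class.value}\n")
            fh.write(r.sequence + "\n")
            fh.write(ann + "\n")


def read_plain_fasta(path: PathLike) -> list[tuple[str, str]]:
    """(id, sequence) pairs from standard FASTA."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, str(rec.seq).upper()))
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


def write_predictions_tsv(predictions: dict[str, Prediction],
                          path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PREDICTION_COLUMNS)
        for rid, p in predictions.items():
            row = [rid, p.predicted_class.value]
            row += [f"{x:.6f}" for x in p.class_probs]
            row += [p.cs if p.cs is not None else "-", f"{p.cs_prob:.6f}"]
            writer.writerow(row)


def read_predictions_tsv(path: PathLike) -> dict[str, dict]:
    out = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != list(PREDICTION_COLUMNS):
            raise FormatError(f"{path}: unexpected prediction TSV columns")
        for row in reader:
            cs = None if row["cs"] == "-" else int(row["cs"])
            out[row["id"]] = {
                "predicted_class": SpClass.from_string(row["predicted_class"]),
                "cs": cs,
                "cs_prob": float(row["cs_prob"]),
                "class_probs": [float(row[f"p_{c.value}"]) for c in SpClass],
            }
    return out


_GFF_REGION_NAME = {
    "n": "n_region", "h": "h_region", "c": "c_region",
    "R": "twin_arginine_motif", "l": "lipobox", "P": "signal_peptide",
}


def write_regions_gff3(per_sequence: dict[str, list[RegionSummary]],
                       path: PathLike) -> None:
    """Region calls as GFF3 features (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rid, summaries in per_sequence.items():
            for s in summaries:
                attrs = (f"Name={_GFF_REGION_NAME.get(s.region, s.region)};"
                         f"hydrophobicity={s.hydrophobicity:.3f};"
                         f"net_charge={s.net_charge:+.1f}")
                fh.write("\t".join([
                    rid, "sigcrf", "polypeptide_region", str(s.start),
                    str(s.end), ".", ".", ".", attrs]) + "\n")


def write_region_summaries_tsv(per_sequence: dict[str, list[RegionSummary]],
                               path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "region", "start", "end", "length",
                         "hydrophobicity", "net_charge"])
        for rid, summaries in per_sequence.items():
            for s in summaries:
                writer.writerow([rid, s.region, s.start, s.end, s.length,
                                 f"{s.hydrophobicity:.4f}",
                                 f"{s.net_charge:+.1f}"])
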