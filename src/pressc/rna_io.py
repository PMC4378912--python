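"""Readers and writers for the formats the pipeline touches.

FASTA input goes through Biopython; Vienna dot-bracket records (sequence
line plus structure line with an optional trailing ``(MFE)`` token) and the
TSV feature tables use small dedicated parsers since no standard library
covers them.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Optional, Union

from Bio import SeqIO

__all__ = [
    "AnnotatedRna",
    "RnaIoError",
    "read_fasta",
    "read_vienna",
    "write_fasta",
    "write_vienna",
    "write_feature_table",
    "read_feature_table",
]

VALID_RESIDUES = frozenset("ACGU")

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"


class RnaIoError(ValueError):
    """Malformed input record."""


@dataclass
class AnnotatedRna:
    """An identified RNA sequence with optional structure annotation.

    Parameters
    ----------
    id:
        Record identifier (first whitespace-delimited token of the header).
    residues:
        Upper-case sequence over ``{A, C, G, U}``.
    structure:
        Optional dot-bracket string of the same length.
    mfe:
        Optional minimum free energy in kcal/mol; finite when present.
    label:
        Optional class: ``"positive"``, ``"negative"`` or ``"unknown"``.
    description:
        Header text after the identifier; retained but never used in
        computation.
    """

    id: str
    residues: str
    structure: Optional[str] = None
    mfe: Optional[float] = None
    label: Optional[str] = None
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise RnaIoError(
                f"record {self.id!r}: invalid residue symbol(s) "
                f"{', '.join(sorted(bad))!s} (alphabet is A/C/G/U)"
            )
        if self.structure is not None and len(self.structure) != len(self.residues):
            raise RnaIoError(
                f"record {self.id!r}: structure length {len(self.structure)} "
                f"!= sequence length {len(self.residues)}"
            )
        if self.mfe is not None and not math.isfinite(self.mfe):
            raise RnaIoError(f"record {self.id!r}: MFE must be finite, got {self.mfe}")
        if self.label is not None and self.label not in (POSITIVE, NEGATIVE, UNKNOWN):
            raise RnaIoError(f"record {self.id!r}: unknown label {self.label!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def with_structure(self, structure: str, mfe: Optional[float] = None) -> "AnnotatedRna":
        return replace(self, structure=structure, mfe=mfe)


def _normalize_residues(record_id: str, raw: str) -> str:
    seq = raw.upper().replace("T", "U")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise RnaIoError(
            f"record {record_id!r}: invalid residue symbol(s) "
            f"{', '.join(sorted(bad))} after normalization (alphabet is A/C/G/U/T)"
        )
    return seq


def _as_text_handle(source: Union[str, IO[str]]) -> IO[str]:
    if isinstance(source, str):
        return open(source, "r", encoding="utf-8", newline=None)
    return source


def read_fasta(source: Union[str, IO[str]]) -> list[AnnotatedRna]:
    """Read FASTA records, normalizing case and T→U.

    Any residue outside A/C/G/U/T (case-insensitive) raises
    :class:`RnaIoError` naming the record and the offending symbol.
    """
    handle = _as_text_handle(source)
    close = isinstance(source, str)
    try:
        records = []
        for rec in SeqIO.parse(handle, "fasta"):
            desc = rec.description[len(rec.id):].strip() if rec.description else ""
            records.append(
                AnnotatedRna(
                    id=rec.id,
                    residues=_normalize_residues(rec.id, str(rec.seq)),
                    description=desc,
                )
            )
        return records
    finally:
        if close:
            handle.close()


# MFE is the last parenthesized token on the structure line, e.g. "(-12.30)".
_MFE_SUFFIX = re.compile(r"^(?P<struct>[^\s]+)(?:\s+\((?P<mfe>[^()]*)\))?\s*$")


def read_vienna(source: Union[str, IO[str]]) -> list[AnnotatedRna]:
    """Read Vienna records: ``>id`` header, sequence line, structure line.

    The structure line may carry a trailing ``(value)`` holding the MFE in
    kcal/mol.
    """
    handle = _as_text_handle(source)
    close = isinstance(source, str)
    try:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in handle if ln.strip()]
    finally:
        if close:
            handle.close()

    records = []
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise RnaIoError(f"expected '>' header, got: {header!r}")
        if i + 2 >= len(lines):
            raise RnaIoError(f"truncated record {header!r}: need sequence and structure lines")
        fields = header[1:].split(None, 1)
        rec_id = fields[0] if fields else ""
        desc = fields[1] if len(fields) > 1 else ""
        residues = _normalize_residues(rec_id, lines[i + 1].strip())

        m = _MFE_SUFFIX.match(lines[i + 2].strip())
        if m is None:
            raise RnaIoError(f"record {rec_id!r}: unparsable structure line {lines[i + 2]!r}")
        structure = m.group("struct")
        mfe: Optional[float] = None
        if m.group("mfe") is not None:
            try:
                mfe = float(m.group("mfe"))
            except ValueError:
                raise RnaIoError(
                    f"record {rec_id!r}: unparsable MFE token ({m.group('mfe')!r})"
                ) from None
        if len(structure) != len(residues):
            raise RnaIoError(
                f"record {rec_id!r}: structure length {len(structure)} "
                f"!= sequence length {len(residues)}"
            )
        records.append(
            AnnotatedRna(id=rec_id, residues=residues, structure=structure, mfe=mfe,
                         description=desc)
        )
        i += 3
    return records


def write_fasta(records: Iterable[AnnotatedRna], stream: IO[str]) -> None:
    for rec in records:
        header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
        stream.write(f"{header}\n{rec.residues}\n")


def write_vienna(records: Iterable[AnnotatedRna], stream: IO[str]) -> None:
    for rec in records:
        if rec.structure is None:
            raise RnaIoError(f"record {rec.id!r}: no structure to write")
        header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
        line = rec.structure
        if rec.mfe is not None:
            line += f" ({rec.mfe:.2f})"
        stream.write(f"{header}\n{rec.residues}\n{line}\n")


def write_feature_table(vectors, stream: IO[str]) -> None:
    """Write feature vectors as a TSV table: id, label, one column per feature.

    All vectors must share parameters/dimension. Values are printed with
    ``repr`` so the table round-trips bit-identically.
    """
    vectors = list(vectors)
    if vectors:
        first = vectors[0]
        names = first.feature_names()
        for v in vectors[1:]:
            if len(v.values) != len(first.values) or v.params != first.params or v.kind != first.kind:
                raise RnaIoError(
                    f"mixed feature tables: {v.record_id!r} has dimension "
                    f"{len(v.values)} / params {v.params}, expected "
                    f"{len(first.values)} / {first.params}"
                )
        header = ["id", "label"] + list(names)
    else:
        header = ["id", "label"]
    stream.write("\t".join(header) + "\n")
    for v in vectors:
        label = "" if v.label is None else v.label
        row = [v.record_id, label] + [repr(float(x)) for x in v.values]
        stream.write("\t".join(row) + "\n")


def read_feature_table(source: Union[str, IO[str]]):
    """Read a TSV feature table back into (ids, labels, matrix, feature_names).

    ``matrix`` is a list of per-record float lists; empty label cells map to
    ``None``.
    """
    handle = _as_text_handle(source)
    close = isinstance(source, str)
    try:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    finally:
        if close:
            handle.close()
    if not lines:
        raise RnaIoError("empty feature table")
    header = lines[0].split("\t")
    if header[:2] != ["id", "label"]:
        raise RnaIoError("feature table must start with 'id' and 'label' columns")
    names = header[2:]
    ids, labels, rows = [], [], []
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise RnaIoError(f"row for {cells[0]!r} has {len(cells)} cells, expected {len(header)}")
        ids.append(cells[0])
        labels.append(cells[1] or None)
        rows.append([float(x) for x in cells[2:]])
    return ids, labels, rows, names


def records_to_stream(records: Iterable[AnnotatedRna], writer) -> str:
    buf = io.StringIO()
    writer(records, buf)
    return buf.getvalue()
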