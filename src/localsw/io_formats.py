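"""Sequence input and hit output.

Input goes through Biopython's SeqIO behind a small reader registry so
additional formats can be plugged in by name (:func:`register_reader`).
Output is either a tab-separated table or SAM v1.6 with five custom tags
per record: AS:i: (raw score, rounded), QC:f: (query coverage), QI:f:
(query identity), RS:f: (relative score) and BS:f: (base score).

SAM conventions: FLAG 0, MAPQ 255 (unavailable), unaligned query ends
soft-clipped so SEQ always carries the full query, one record per hit
and no unmapped records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

from Bio import SeqIO

from .errors import FormatError, InputError

GAP = "-"


@dataclass(frozen=True)
class SequenceRecord:
    """One input sequence.

    ``id`` is the first whitespace-delimited header token, ``description``
    the remainder; ``qualities`` are Phred scores for FASTQ input.
    """

    id: str
    residues: str
    description: str = ""
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise InputError(f"sequence {self.id!r} has no residues")
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise InputError(
                f"sequence {self.id!r}: {len(self.qualities)} quality values "
                f"for {len(self.residues)} residues")

    def __len__(self) -> int:
        return len(self.residues)


def _seqio_reader(fmt: str) -> Callable[[str], list[SequenceRecord]]:
    def read(path: str) -> list[SequenceRecord]:
        records = []
        try:
            for rec in SeqIO.parse(path, fmt):
                quals = rec.letter_annotations.get("phred_quality")
                records.append(SequenceRecord(
                    id=rec.id,
                    residues=str(rec.seq),
                    description=rec.description[len(rec.id):].strip()
                    if rec.description.startswith(rec.id) else rec.description,
                    qualities=tuple(quals) if quals is not None else None,
                ))
        except (ValueError, InputError) as exc:
            raise FormatError(
                f"{path}: malformed {fmt} near record {len(records) + 1}: {exc}"
            ) from exc
        return records

    return read


_READERS: dict[str, Callable[[str], list[SequenceRecord]]] = {
    "fasta": _seqio_reader("fasta"),
    "fastq": _seqio_reader("fastq"),
    "genbank": _seqio_reader("genbank"),
}


def register_reader(format_name: str,
                    reader: Callable[[str], list[SequenceRecord]]) -> None:
    """Register a custom reader; it receives a path and returns records."""
    _READERS[format_name.lower()] = reader


def registered_formats() -> tuple[str, ...]:
    return tuple(sorted(_READERS))


def read_sequences(path: str, format_name: str = "fasta") -> list[SequenceRecord]:
    """Read all records from ``path``; ids must be unique within the file."""
    reader = _READERS.get(format_name.lower())
    if reader is None:
        raise FormatError(
            f"unknown input format {format_name!r}; registered formats: "
            + ", ".join(registered_formats()))
    records = reader(path)
    if not records:
        raise FormatError(f"{path}: no {format_name} records found")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise InputError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
    return records


# -- tab-separated output ---------------------------------------------------

TSV_COLUMNS = (
    "query_id", "target_id", "score",
    "query_start", "query_end", "target_start", "target_end",
    "matches", "mismatches", "gap_columns",
    "query_coverage", "query_identity", "relative_score", "base_score",
    "aligned_query", "aligned_target",
)


def format_default(hits: Iterable) -> str:
    """Hits as a tab-separated table, one row per hit, floats with 3 decimals."""
    lines = ["\t".join(TSV_COLUMNS)]
    for hit in hits:
        m = hit.metrics
        lines.append("\t".join((
            hit.query_id, hit.target_id, f"{hit.score:.3f}",
            str(hit.query_start), str(hit.query_end),
            str(hit.target_start), str(hit.target_end),
            str(hit.matches), str(hit.mismatches), str(hit.gap_columns),
            f"{m.query_coverage:.3f}", f"{m.query_identity:.3f}",
            f"{m.relative_score:.3f}", f"{m.base_score:.3f}",
            hit.aligned_query, hit.aligned_target,
        )))
    return "\n".join(lines) + "\n"


# -- SAM output -------------------------------------------------------------

def build_cigar(hit, query_len: int) -> str:
    """CIGAR from alignment columns: S for unaligned query ends, M for
    aligned columns, I for gaps in the target, D for gaps in the query."""
    ops: list[tuple[int, str]] = []

    def push(op: str, n: int = 1) -> None:
        if n <= 0:
            return
        if ops and ops[-1][1] == op:
            ops[-1] = (ops[-1][0] + n, op)
        else:
            ops.append((n, op))

    push("S", hit.query_start - 1)
    for a, b in zip(hit.aligned_query, hit.aligned_target):
        if a != GAP and b != GAP:
            push("M")
        elif b == GAP:
            push("I")
        else:
            push("D")
    push("S", query_len - hit.query_end)
    return "".join(f"{n}{op}" for n, op in ops)


def _phred_string(qualities) -> str:
    return "".join(chr(min(q, 93) + 33) for q in qualities)


def format_sam(hits: Iterable, queries: Iterable[SequenceRecord],
               targets: Iterable[SequenceRecord]) -> str:
    """Hits as SAM v1.6 text with the AS/QC/QI/RS/BS tags."""
    queries = list(queries)
    targets = list(targets)
    qmap = {rec.id: rec for rec in queries}
    tset = {rec.id for rec in targets}
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for rec in targets:
        lines.append(f"@SQ\tSN:{rec.id}\tLN:{len(rec)}")
    for hit in hits:
        if hit.target_id not in tset:
            raise InputError(
                f"hit references unknown target {hit.target_id!r}")
        query = qmap.get(hit.query_id)
        if query is None:
            raise InputError(f"hit references unknown query {hit.query_id!r}")
        m = hit.metrics
        qual = _phred_string(query.qualities) if query.qualities else "*"
        lines.append("\t".join((
            hit.query_id, "0", hit.target_id, str(hit.target_start), "255",
            build_cigar(hit, len(query)), "*", "0", "0",
            query.residues, qual,
            f"AS:i:{int(hit.score + 0.5)}",
            f"QC:f:{m.query_coverage:.3f}",
            f"QI:f:{m.query_identity:.3f}",
            f"RS:f:{m.relative_score:.3f}",
            f"BS:f:{m.base_score:.3f}",
        )))
    return "\n".join(lines) + "\n"


def write_hits(hits, queries, targets, path: str, output_format: str = "TSV") -> None:
    """Write hits to ``path`` in TSV or SAM form."""
    fmt = output_format.upper()
    if fmt == "TSV":
        text = format_default(hits)
    elif fmt == "SAM":
        text = format_sam(hits, queries, targets)
    else:
        raise FormatError(f"unknown output format {output_format!r} "
                          "(choose TSV or SAM)")
    with open(path, "w") as fh:
        fh.write(text)
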