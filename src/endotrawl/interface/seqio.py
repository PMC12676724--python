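"""FASTA/FASTQ reading and writing.

A deliberately small reader is used instead of a library parser because the
contract requires parse errors that name the offending line and rejection of
duplicate record ids; wrapped FASTA is accepted, FASTQ is the plain 4-line
form (Phred+33).
"""

from __future__ import annotations

from dataclasses import dataclass

from ..errors import ParseError


@dataclass
class SeqRecord:
    id: str
    seq: str
    qual: str | None = None


def read_fasta(path) -> list[SeqRecord]:
    records: list[SeqRecord] = []
    seen: set[str] = set()
    current: str | None = None
    chunks: list[str] = []
    header_line = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if current is not None:
                    _flush_fasta(records, seen, current, chunks, header_line)
                current = line[1:].split()[0] if line[1:].split() else ""
                if not current:
                    raise ParseError("empty FASTA header", lineno)
                chunks = []
                header_line = lineno
            else:
                if current is None:
                    raise ParseError("sequence data before any FASTA header", lineno)
                chunks.append(line.strip())
    if current is not None:
        _flush_fasta(records, seen, current, chunks, header_line)
    return records


def _flush_fasta(records, seen, rec_id, chunks, lineno):
    if rec_id in seen:
        raise ParseError(f"duplicate record id {rec_id!r}", lineno)
    seen.add(rec_id)
    records.append(SeqRecord(rec_id, "".join(chunks).upper()))


def read_fastq(path) -> list[SeqRecord]:
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        lines = [line.rstrip("\n") for line in fh]
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) % 4 != 0:
        raise ParseError("FASTQ file length is not a multiple of 4", len(lines))
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise ParseError("FASTQ record does not start with '@'", lineno)
        if not plus.startswith("+"):
            raise ParseError("FASTQ separator line does not start with '+'", lineno + 2)
        rec_id = head[1:].split()[0] if head[1:].split() else ""
        if not rec_id:
            raise ParseError("empty FASTQ header", lineno)
        if rec_id in seen:
            raise ParseError(f"duplicate record id {rec_id!r}", lineno)
        if len(seq) != len(qual):
            raise ParseError(
                f"sequence length {len(seq)} != quality length {len(qual)}", lineno + 3
            )
        seen.add(rec_id)
        records.append(SeqRecord(rec_id, seq.upper(), qual))
    return records


def read_sequences(path, fmt: str | None = None) -> list[SeqRecord]:
    """Read FASTA or FASTQ; format inferred from the extension if omitted."""
    if fmt is None:
        name = str(path).lower()
        fmt = "fastq" if name.endswith((".fastq", ".fq")) else "fasta"
    if fmt == "fasta":
        return read_fasta(path)
    if fmt == "fastq":
        return read_fastq(path)
    raise ParseError(f"unknown sequence format {fmt!r}")


def write_fasta(records, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            rec_id, seq = _unpack(rec)
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = getattr(rec, "qual", None) or "I" * len(rec.seq)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def _unpack(rec):
    if isinstance(rec, tuple):
        return rec[0], rec[1]
    return rec.id, rec.seq
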