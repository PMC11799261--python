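"""FASTA reading/writing and the two flattening modes.

The codec proper operates on a one-line text over {A,C,G,T,N}. Two ways to
get there from a FASTA file:

* ``paper_preprocess`` — the destructive protocol used for benchmarking
  one-line genomes: newlines, headers, lowercase (soft-masked) bases and
  any character other than uppercase A/C/G/T/N are simply removed. Not
  invertible.
* ``lossless_flatten`` — uppercases soft-masked bases and extracts
  everything else (headers, line lengths, case-mask intervals, dropped
  characters) into a :class:`SidecarMetadata` so ``restore_fasta`` can
  rebuild the original file byte-for-byte.

The reader deliberately preserves the exact line structure (and the
presence or absence of the final newline) instead of normalising it, since
byte-exact reconstruction is part of the contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Iterable

from .errors import InputError
from .labeling import DEFAULT_ALPHABET

_KEEP = set("ACGTN")


@dataclass
class FastaRecord:
    """One FASTA record with its stored line structure.

    ``final_newline`` is only meaningful on the last record of a file and
    records whether the file ended with a newline.
    """

    header: str  # without the leading ">"
    lines: list[str] = field(default_factory=list)
    final_newline: bool = True

    @property
    def sequence(self) -> str:
        return "".join(self.lines)


def read_fasta(stream: str | IO[str], strict: bool = True) -> list[FastaRecord]:
    """Parse FASTA from a string or text stream, preserving line structure.

    In strict mode, sequence data before the first header is an error;
    otherwise it is collected under a record with an empty header marker.
    An empty stream yields an empty list.
    """
    if hasattr(stream, "read"):
        content = stream.read()
    else:
        content = stream
    if content == "":
        return []
    final_newline = content.endswith("\n")
    records: list[FastaRecord] = []
    current: FastaRecord | None = None
    for line in content.splitlines():
        if line.startswith(">"):
            current = FastaRecord(line[1:], [])
            records.append(current)
        else:
            if current is None:
                if strict:
                    raise InputError("sequence data before the first FASTA header")
                current = FastaRecord("", [])
                records.append(current)
            current.lines.append(line)
    if records:
        records[-1].final_newline = final_newline
    return records


def write_fasta(records: Iterable[FastaRecord]) -> str:
    """Inverse of :func:`read_fasta`: byte-exact for what the reader parsed."""
    records = list(records)
    parts: list[str] = []
    for rec in records:
        parts.append(">" + rec.header)
        parts.extend(rec.lines)
    text = "\n".join(parts)
    if records and records[-1].final_newline:
        text += "\n"
    return text


def paper_preprocess(records: Iterable[FastaRecord]) -> str:
    """One-line genome under the destructive benchmarking protocol.

    Concatenates every sequence line of every record and deletes each
    character that is not uppercase A, C, G, T or N. Lowercase
    (soft-masked) bases are deleted, not uppercased. The result may be
    empty.
    """
    chunks = []
    for rec in records:
        for line in rec.lines:
            chunks.append("".join(ch for ch in line if ch in _KEEP))
    return "".join(chunks)


@dataclass
class SidecarMetadata:
    """Everything the one-line text discards, enough to invert exactly.

    Coordinates: ``case_intervals`` are zero-based half-open intervals of
    originally-lowercase runs in the final one-line text; ``dropped``
    records each non-ACGTN character as (position, char), where position is
    the number of kept characters preceding it — i.e. its insertion point
    in final-text coordinates, applied right-to-left on restore.
    """

    headers: list[str]
    line_lengths: list[list[int]]
    case_intervals: list[tuple[int, int]]
    dropped: list[tuple[int, str]]
    final_newline: bool = True

    def to_json(self) -> bytes:
        doc = {
            "headers": self.headers,
            "line_lengths": self.line_lengths,
            "case_intervals": [list(iv) for iv in self.case_intervals],
            "dropped": [[p, c] for p, c in self.dropped],
            "final_newline": self.final_newline,
        }
        return json.dumps(doc, separators=(",", ":")).encode("utf-8")

    @classmethod
    def from_json(cls, data: bytes) -> "SidecarMetadata":
        try:
            doc = json.loads(data.decode("utf-8"))
            return cls(
                headers=list(doc["headers"]),
                line_lengths=[list(x) for x in doc["line_lengths"]],
                case_intervals=[(int(a), int(b)) for a, b in doc["case_intervals"]],
                dropped=[(int(p), str(c)) for p, c in doc["dropped"]],
                final_newline=bool(doc["final_newline"]),
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise InputError(f"malformed sidecar metadata: {exc}") from exc


def lossless_flatten(records: Iterable[FastaRecord]) -> tuple[str, SidecarMetadata]:
    """Flatten FASTA to a one-line ACGTN text plus an exact-restore sidecar.

    Soft-masked (lowercase) bases are uppercased and their runs recorded as
    intervals; characters that are not A/C/G/T/N in either case are pulled
    out into the dropped list with their insertion points.
    """
    records = list(records)
    kept: list[str] = []
    case_intervals: list[tuple[int, int]] = []
    dropped: list[tuple[int, str]] = []
    run_start: int | None = None
    for rec in records:
        for line in rec.lines:
            for ch in line:
                up = ch.upper()
                if up in _KEEP:
                    if ch.islower():
                        if run_start is None:
                            run_start = len(kept)
                    elif run_start is not None:
                        case_intervals.append((run_start, len(kept)))
                        run_start = None
                    kept.append(up)
                else:
                    dropped.append((len(kept), ch))
    if run_start is not None:
        case_intervals.append((run_start, len(kept)))
    meta = SidecarMetadata(
        headers=[rec.header for rec in records],
        line_lengths=[[len(line) for line in rec.lines] for rec in records],
        case_intervals=case_intervals,
        dropped=dropped,
        final_newline=records[-1].final_newline if records else True,
    )
    return "".join(kept), meta


def restore_fasta(text: str, meta: SidecarMetadata) -> str:
    """Byte-exact inverse of :func:`lossless_flatten`."""
    total_seq = sum(sum(lens) for lens in meta.line_lengths)
    if total_seq != len(text) + len(meta.dropped):
        raise InputError(
            "inconsistent metadata: line lengths do not match text plus dropped characters"
        )
    if len(meta.headers) != len(meta.line_lengths):
        raise InputError("inconsistent metadata: headers and line lengths differ in count")
    chars = list(text)
    for start, end in meta.case_intervals:
        if not (0 <= start <= end <= len(chars)):
            raise InputError("inconsistent metadata: case interval out of bounds")
        for i in range(start, end):
            chars[i] = chars[i].lower()
    for pos, ch in reversed(meta.dropped):
        if not (0 <= pos <= len(text)):
            raise InputError("inconsistent metadata: dropped position out of bounds")
        chars.insert(pos, ch)
    seq = "".join(chars)
    records: list[FastaRecord] = []
    cursor = 0
    for header, lens in zip(meta.headers, meta.line_lengths):
        lines = []
        for ln in lens:
            lines.append(seq[cursor : cursor + ln])
            cursor += ln
        records.append(FastaRecord(header, lines))
    if records:
        records[-1].final_newline = meta.final_newline
    return write_fasta(records)


def read_raw(content: str) -> str:
    """Raw mode: a one-line text over the alphabet, optionally ending in a
    single trailing newline (stripped)."""
    if content.endswith("\n"):
        content = content[:-1]
    for off, ch in enumerate(content):
        if ch not in DEFAULT_ALPHABET:
            raise InputError(f"raw input contains {ch!r} at offset {off}")
    return content
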