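"""Archive container: serialize bins + label stream into one file.

Layout (all integers little-endian, strings ASCII):

    magic "OST1"
    u8  format version (=1)
    u8  label length k
    u32 window length w
    u8  backend numeric id
    u8  alphabet length, then alphabet bytes
    u64 original text length t
    32B SHA-256 of the original one-line text
    u32 bin count
    label dictionary: u32 count, then per label:
        u16 byte length, label bytes, u8 code length
    u64 label-stream entry count
    u32 payload byte length, then the bit-packed payload
    per bin, in dictionary order: u32 label id, u64 blob length, blob bytes
    u8  sidecar flag; if 1: u64 length, sidecar blob (backend-compressed)

The label stream ``L`` (one label per window) is entropy-coded with a
canonical Huffman code over label frequencies: the label of a larger bin is
more frequent in ``L`` and therefore gets a shorter code. Only code lengths
are stored; both sides derive identical canonical codewords from them. When
a single label covers the whole text the payload is empty and only the
entry count is stored (its "code length" is recorded as 0).

The trailing sidecar slot carries the lossless-FASTA metadata blob when the
fully lossless mode is used; plain one-line text archives set the flag to 0.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass

from . import backends, binner, labeling
from .binner import BinTable, CodecParams
from .errors import (
    BadMagicError,
    ChecksumMismatchError,
    CorruptArchiveError,
    InputError,
    TruncatedArchiveError,
    UnsupportedVersionError,
)

MAGIC = b"OST1"
FORMAT_VERSION = 1


@dataclass(frozen=True)
class ArchiveHeader:
    version: int
    k: int
    w: int
    backend: str
    alphabet: str
    t: int
    checksum: bytes  # SHA-256 of the original one-line text
    bin_count: int


@dataclass(frozen=True)
class EncodedLabelStream:
    """Huffman-coded per-window label sequence.

    ``labels`` are in first-appearance order (their index is the label id);
    ``code_lengths[i]`` is the canonical Huffman code length of label i,
    or 0 when there is a single label and no payload bits are needed.
    """

    labels: tuple[str, ...]
    code_lengths: tuple[int, ...]
    entry_count: int
    payload: bytes


def _canonical_codes(lengths: list[int]) -> list[tuple[int, int]]:
    """(code, length) per symbol index from canonical Huffman lengths."""
    order = sorted(range(len(lengths)), key=lambda i: (lengths[i], i))
    codes: list[tuple[int, int]] = [(0, 0)] * len(lengths)
    code = 0
    prev_len = lengths[order[0]]
    for j, s in enumerate(order):
        if j:
            code = (code + 1) << (lengths[s] - prev_len)
        codes[s] = (code, lengths[s])
        prev_len = lengths[s]
    return codes


def encode_label_stream(stream: list[str]) -> EncodedLabelStream:
    """Entropy-code ``stream`` with a canonical Huffman code over label ids.

    Ids are assigned in first-appearance order; tie-breaking during tree
    construction matches the window-labelling rules (lower weight, then
    earlier id). A single distinct label yields an empty payload.
    """
    if not stream:
        raise InputError("empty label stream")
    ids: dict[str, int] = {}
    counts: list[int] = []
    seq: list[int] = []
    for label in stream:
        i = ids.setdefault(label, len(ids))
        if i == len(counts):
            counts.append(0)
        counts[i] += 1
        seq.append(i)
    labels = tuple(ids)
    if len(labels) == 1:
        return EncodedLabelStream(labels, (0,), len(stream), b"")
    lengths = labeling.huffman_code_lengths(counts)
    codes = _canonical_codes(lengths)
    buf = bytearray()
    acc = 0
    nbits = 0
    for i in seq:
        code, ln = codes[i]
        acc = (acc << ln) | code
        nbits += ln
        while nbits >= 8:
            nbits -= 8
            buf.append((acc >> nbits) & 0xFF)
            acc &= (1 << nbits) - 1
    if nbits:
        buf.append((acc << (8 - nbits)) & 0xFF)
    return EncodedLabelStream(labels, tuple(lengths), len(stream), bytes(buf))


def decode_label_stream(enc: EncodedLabelStream) -> list[str]:
    """Exact inverse of :func:`encode_label_stream`."""
    n = len(enc.labels)
    if n == 0 or enc.entry_count < 1:
        raise CorruptArchiveError("label stream declares no labels or no entries")
    if n == 1:
        if enc.payload:
            raise CorruptArchiveError("single-label stream must have an empty payload")
        return [enc.labels[0]] * enc.entry_count
    lengths = list(enc.code_lengths)
    if any(ln < 1 for ln in lengths):
        raise CorruptArchiveError("non-positive code length in label dictionary")
    kraft = sum(2 ** -ln for ln in lengths)
    if abs(kraft - 1.0) > 1e-12:
        raise CorruptArchiveError("label code lengths violate Kraft equality")
    # canonical decode tables: symbols sorted by (length, id)
    order = sorted(range(n), key=lambda i: (lengths[i], i))
    first_code: dict[int, int] = {}
    first_index: dict[int, int] = {}
    codes = _canonical_codes(lengths)
    for j, s in enumerate(order):
        ln = lengths[s]
        if ln not in first_code:
            first_code[ln] = codes[s][0]
            first_index[ln] = j
    count_at = {ln: sum(1 for x in lengths if x == ln) for ln in set(lengths)}
    out: list[str] = []
    code = 0
    ln = 0
    total_bits = len(enc.payload) * 8
    bitpos = 0
    payload = enc.payload
    while len(out) < enc.entry_count:
        if bitpos >= total_bits:
            raise CorruptArchiveError("truncated label-stream payload")
        bit = (payload[bitpos >> 3] >> (7 - (bitpos & 7))) & 1
        bitpos += 1
        code = (code << 1) | bit
        ln += 1
        if ln in first_code and 0 <= code - first_code[ln] < count_at[ln]:
            out.append(enc.labels[order[first_index[ln] + code - first_code[ln]]])
            code = 0
            ln = 0
    if ln:
        raise CorruptArchiveError("label-stream payload ends mid-codeword")
    # nothing but zero padding may follow the last codeword
    if (total_bits - bitpos) >= 8:
        raise CorruptArchiveError("label-stream payload has trailing bytes")
    while bitpos < total_bits:
        if (payload[bitpos >> 3] >> (7 - (bitpos & 7))) & 1:
            raise CorruptArchiveError("nonzero padding after label-stream payload")
        bitpos += 1
    return out


@dataclass(frozen=True)
class Archive:
    header: ArchiveHeader
    label_stream: list[str]
    blobs: list[bytes]  # one per bin, dictionary order
    sidecar: bytes | None  # still backend-compressed


def write_archive(
    params: CodecParams,
    stream: list[str],
    compressed_bins: list[bytes],
    t: int,
    checksum: bytes,
    sidecar: bytes | None = None,
) -> bytes:
    """Serialize one archive; identical inputs give identical bytes."""
    enc = encode_label_stream(stream)
    if len(compressed_bins) != len(enc.labels):
        raise InputError("blob count does not match distinct label count")
    if len(checksum) != 32:
        raise InputError("checksum must be 32 bytes (SHA-256)")
    spec = backends.get_backend(params.backend)
    alpha = params.alphabet.encode("ascii")
    out = bytearray()
    out += MAGIC
    out += struct.pack("<BBIB", FORMAT_VERSION, params.k, params.w, spec.numeric_id)
    out += struct.pack("<B", len(alpha)) + alpha
    out += struct.pack("<Q", t)
    out += checksum
    out += struct.pack("<I", len(enc.labels))
    out += struct.pack("<I", len(enc.labels))
    for label, ln in zip(enc.labels, enc.code_lengths):
        lb = label.encode("ascii")
        out += struct.pack("<H", len(lb)) + lb + struct.pack("<B", ln)
    out += struct.pack("<Q", enc.entry_count)
    out += struct.pack("<I", len(enc.payload)) + enc.payload
    for i, blob in enumerate(compressed_bins):
        out += struct.pack("<IQ", i, len(blob)) + blob
    if sidecar is None:
        out += struct.pack("<B", 0)
    else:
        out += struct.pack("<B", 1) + struct.pack("<Q", len(sidecar)) + sidecar
    return bytes(out)


class _Reader:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise TruncatedArchiveError(
                f"archive ends at byte {len(self.data)}, needed {self.pos + n}"
            )
        chunk = self.data[self.pos : self.pos + n]
        self.pos += n
        return chunk

    def unpack(self, fmt: str):
        return struct.unpack(fmt, self.take(struct.calcsize(fmt)))


def read_archive(data: bytes) -> Archive:
    """Parse and validate an archive (checksum is verified after the bins
    are decompressed, in :func:`decompress_text`)."""
    r = _Reader(data)
    if len(data) < 4 or data[:4] != MAGIC:
        raise BadMagicError("not an OST archive (bad magic)")
    r.take(4)
    version, k, w, backend_num = r.unpack("<BBIB")
    if version != FORMAT_VERSION:
        raise UnsupportedVersionError(f"unsupported archive version {version}")
    (alpha_len,) = r.unpack("<B")
    alphabet = r.take(alpha_len).decode("ascii")
    (t,) = r.unpack("<Q")
    checksum = r.take(32)
    (bin_count,) = r.unpack("<I")
    (dict_count,) = r.unpack("<I")
    if dict_count != bin_count:
        raise CorruptArchiveError(
            f"bin count {bin_count} disagrees with label dictionary size {dict_count}"
        )
    labels: list[str] = []
    code_lengths: list[int] = []
    for _ in range(dict_count):
        (lb_len,) = r.unpack("<H")
        labels.append(r.take(lb_len).decode("ascii"))
        (ln,) = r.unpack("<B")
        code_lengths.append(ln)
    if len(set(labels)) != len(labels):
        raise CorruptArchiveError("duplicate label in dictionary")
    (entry_count,) = r.unpack("<Q")
    (payload_len,) = r.unpack("<I")
    payload = r.take(payload_len)
    enc = EncodedLabelStream(tuple(labels), tuple(code_lengths), entry_count, payload)
    stream = decode_label_stream(enc)
    if _dict_order(stream) != labels:
        raise CorruptArchiveError(
            "label dictionary order disagrees with first appearance in the stream"
        )
    blobs: list[bytes] = []
    for i in range(bin_count):
        label_id, blob_len = r.unpack("<IQ")
        if label_id != i:
            raise CorruptArchiveError(f"blob {i} carries label id {label_id}")
        blobs.append(r.take(blob_len))
    (sidecar_flag,) = r.unpack("<B")
    sidecar: bytes | None = None
    if sidecar_flag == 1:
        (sc_len,) = r.unpack("<Q")
        sidecar = r.take(sc_len)
    elif sidecar_flag != 0:
        raise CorruptArchiveError(f"invalid sidecar flag {sidecar_flag}")
    if r.pos != len(data):
        raise CorruptArchiveError(f"{len(data) - r.pos} trailing bytes after archive")
    backend = backends.get_backend_by_numeric(backend_num)
    header = ArchiveHeader(version, k, w, backend.id, alphabet, t, checksum, bin_count)
    return Archive(header, stream, blobs, sidecar)


def text_checksum(text: str) -> bytes:
    return hashlib.sha256(text.encode("ascii")).digest()


def compress_text(text: str, params: CodecParams, sidecar: bytes | None = None) -> bytes:
    """Full pipeline: bin, compress each bin independently, code the label
    stream, and assemble the archive.

    ``sidecar`` (raw metadata bytes, e.g. the lossless-FASTA sidecar) is
    compressed with the same backend and embedded in the trailing slot.
    """
    table, stream = binner.bin_text(text, params)
    spec = backends.get_backend(params.backend)
    blobs = [backends.compress_blob(spec, content.encode("ascii")) for content in table.bins.values()]
    sc = backends.compress_blob(spec, sidecar) if sidecar is not None else None
    return write_archive(params, stream, blobs, len(text), text_checksum(text), sc)


def decompress_archive(data: bytes) -> tuple[str, bytes | None]:
    """Invert :func:`compress_text`; returns (text, raw sidecar or None).

    Raises :class:`ChecksumMismatchError` when the reassembled text does not
    hash to the stored SHA-256.
    """
    ar = read_archive(data)
    spec = backends.get_backend(ar.header.backend)
    decoded: dict[str, str] = {}
    seen: list[str] = []
    for label, blob in zip(_dict_order(ar.label_stream), ar.blobs):
        decoded[label] = backends.decompress_blob(spec, blob).decode("ascii")
        seen.append(label)
    text = binner.unbin(decoded, ar.label_stream, ar.header.w, ar.header.t)
    if text_checksum(text) != ar.header.checksum:
        raise ChecksumMismatchError("decompressed text fails the stored SHA-256 check")
    sidecar = backends.decompress_blob(spec, ar.sidecar) if ar.sidecar is not None else None
    return text, sidecar


def decompress_text(data: bytes) -> str:
    return decompress_archive(data)[0]


def _dict_order(stream: list[str]) -> list[str]:
    """Distinct labels in first-appearance order (the dictionary order)."""
    seen: dict[str, None] = {}
    for label in stream:
        seen.setdefault(label)
    return list(seen)
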