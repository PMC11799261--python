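"""Scan, classify and bin windows; and the inverse reassembly.

Compression side: the one-line text is cut into non-overlapping windows of
length ``w`` (the last window may be shorter), each window is labelled by
its Huffman composition label truncated to ``k`` symbols, and like-labelled
windows are concatenated — in order of appearance — into bins. The
per-window label sequence ``L`` is kept alongside: it is the interleaving
recipe the decompressor needs.

Decompression side (:func:`unbin`) walks ``L`` with one read cursor per bin
and re-emits the windows in original order. Both directions are linear in
the text length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import labeling
from .errors import AlphabetError, InputError, CorruptArchiveError, UnknownBackendError


@dataclass(frozen=True)
class CodecParams:
    """Parameters of one codec run: window length, label length, backend."""

    w: int = 250
    k: int = 2
    backend: str = "bzip2"
    alphabet: str = labeling.DEFAULT_ALPHABET

    def __post_init__(self):
        if self.w < 1:
            raise InputError("window length w must be >= 1")
        if self.k < 1:
            raise InputError("label length k must be >= 1")
        from . import backends  # deferred: avoid import cycle at module load

        if self.backend not in backends.list_backends():
            raise UnknownBackendError(f"unknown backend {self.backend!r}")


@dataclass
class BinTable:
    """Ordered bins keyed by label, in order of first appearance.

    ``bins[label]`` is the concatenation of every window carrying that
    label, in text order; ``window_counts[label]`` the number of windows.
    """

    bins: dict[str, str] = field(default_factory=dict)
    window_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(len(v) for v in self.bins.values())


def split_windows(text: str, w: int) -> list[str]:
    """Non-overlapping left-to-right windows of length ``w``.

    The final window has length ``len(text) % w`` when that is nonzero;
    the concatenation of the windows is exactly ``text``.
    """
    if not text:
        raise InputError("empty text")
    if w < 1:
        raise InputError("window length w must be >= 1")
    return [text[i : i + w] for i in range(0, len(text), w)]


def _encode_indices(text: str, alphabet: str) -> np.ndarray:
    """Map text to alphabet indices, reporting the first bad character."""
    raw = np.frombuffer(text.encode("ascii", errors="strict"), dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for i, s in enumerate(alphabet):
        lut[ord(s)] = i
    idx = lut[raw]
    bad = np.nonzero(idx == 255)[0]
    if bad.size:
        off = int(bad[0])
        raise AlphabetError(text[off], off)
    return idx


def window_count_matrix(text: str, w: int, alphabet: str = labeling.DEFAULT_ALPHABET) -> np.ndarray:
    """Per-window symbol counts, shape (ceil(t/w), len(alphabet)).

    Vectorised: each character is touched once.
    """
    try:
        idx = _encode_indices(text, alphabet)
    except UnicodeEncodeError:
        # locate the first non-ASCII character for a precise error
        for off, ch in enumerate(text):
            if ord(ch) > 127:
                raise AlphabetError(ch, off) from None
        raise
    t = len(idx)
    a = len(alphabet)
    n_windows = math.ceil(t / w)
    win_id = np.arange(t, dtype=np.int64) // w
    flat = np.bincount(win_id * a + idx, minlength=n_windows * a)
    return flat.reshape(n_windows, a)


def bin_text(text: str, params: CodecParams) -> tuple[BinTable, list[str]]:
    """Algorithm-1 pass: label every window and pool like-labelled windows.

    Returns the bin table (bins keyed in first-appearance order) and the
    label stream ``L`` with one entry per window. Raises on empty text or
    out-of-alphabet characters (with the window-relative context preserved
    in the offset).
    """
    if not text:
        raise InputError("empty text")
    w, k, alphabet = params.w, params.k, params.alphabet
    counts = window_count_matrix(text, w, alphabet)
    stream: list[str] = []
    members: dict[str, list[int]] = {}
    for i, row in enumerate(counts):
        label = labeling.label_for_counts(tuple(int(c) for c in row), alphabet, k)
        stream.append(label)
        members.setdefault(label, []).append(i)
    table = BinTable()
    for label, idxs in members.items():
        table.bins[label] = "".join(text[i * w : (i + 1) * w] for i in idxs)
        table.window_counts[label] = len(idxs)
    return table, stream


def unbin(decoded_bins: dict[str, str], stream: list[str], w: int, t: int) -> str:
    """Inverse of :func:`bin_text`: interleave bins back into the text.

    One read cursor per bin; each entry of ``stream`` consumes the next
    window (length ``w``, or ``t mod w`` for the final entry when nonzero)
    from its bin. Exhausting a bin early or leaving bytes unread is a
    corruption error naming the offending bin.
    """
    expected = math.ceil(t / w)
    if len(stream) != expected:
        raise CorruptArchiveError(
            f"label stream has {len(stream)} entries, expected {expected}"
        )
    cursors = {label: 0 for label in decoded_bins}
    pieces: list[str] = []
    last = len(stream) - 1
    for i, label in enumerate(stream):
        if label not in decoded_bins:
            raise CorruptArchiveError(f"label stream names unknown bin {label!r}")
        want = w if i < last or t % w == 0 else t % w
        pos = cursors[label]
        content = decoded_bins[label]
        if pos + want > len(content):
            raise CorruptArchiveError(f"bin {label!r} exhausted before the label stream")
        pieces.append(content[pos : pos + want])
        cursors[label] = pos + want
    for label, content in decoded_bins.items():
        if cursors.get(label, 0) != len(content):
            raise CorruptArchiveError(f"bin {label!r} has leftover bytes after reassembly")
    out = "".join(pieces)
    if len(out) != t:
        raise CorruptArchiveError(f"reassembled length {len(out)} != declared length {t}")
    return out
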