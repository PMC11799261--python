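"""Composition labels for fixed-length sequence windows.

A window over a small alphabet (A, C, G, T, N by default) is summarised by
the code lengths a Huffman tree would assign to its base frequencies: a
window dominated by G with rarer A, T, C might get lengths G:1, A:2, T:3,
C:3, written as the label ``"GATC_1233"``. Windows with the same label have
a similar composition and are pooled into the same bin downstream.

Only the code *lengths* matter here — actual codewords are never emitted —
so the construction is fully canonical: given the same frequencies it yields
the same label on every run and platform. Tie-breaking during tree
construction is fixed as (lower weight first, then earlier node creation
order); leaves are created in alphabet order, so equal-weight leaf ties fall
back to alphabet order.

Labels can be truncated to a length ``k``: keep only the ``k`` symbols with
the shortest codes (most frequent bases). Smaller ``k`` means coarser bins.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from functools import lru_cache

from .errors import InputError, AlphabetError

#: Default DNA alphabet, order fixed: it is the final tie-break for labels
#: and is written into every archive header.
DEFAULT_ALPHABET = "ACGTN"


@dataclass(frozen=True)
class FrequencyTable:
    """Symbol counts for one window.

    ``counts`` maps each alphabet symbol to its multiplicity (zero allowed);
    ``alphabet`` fixes the canonical symbol order. At least one count must
    be positive.
    """

    counts: tuple[int, ...]
    alphabet: str = DEFAULT_ALPHABET

    def __post_init__(self):
        if len(self.counts) != len(self.alphabet):
            raise InputError("counts and alphabet length differ")
        if any(c < 0 for c in self.counts):
            raise InputError("negative count")
        if not any(self.counts):
            raise InputError("all counts are zero")

    @property
    def total(self) -> int:
        return sum(self.counts)

    def as_dict(self) -> dict[str, int]:
        return {s: c for s, c in zip(self.alphabet, self.counts)}


def count_symbols(window: str, alphabet: str = DEFAULT_ALPHABET) -> FrequencyTable:
    """Exact symbol counts of ``window``.

    Raises :class:`InputError` on an empty window and :class:`AlphabetError`
    (naming the character and its offset) on any out-of-alphabet character.
    """
    if not window:
        raise InputError("empty window")
    index = {s: i for i, s in enumerate(alphabet)}
    counts = [0] * len(alphabet)
    for off, ch in enumerate(window):
        i = index.get(ch)
        if i is None:
            raise AlphabetError(ch, off)
        counts[i] += 1
    return FrequencyTable(tuple(counts), alphabet)


def huffman_code_lengths(weights: list[int]) -> list[int]:
    """Canonical Huffman code lengths for positive ``weights``.

    The index order of ``weights`` is the canonical symbol order. Merging
    always takes the two lowest-weight nodes; ties prefer the node created
    earliest (all leaves are created before any internal node, in index
    order). A single symbol gets length 1: a real emitted code needs at
    least one bit.
    """
    n = len(weights)
    if n == 0:
        raise InputError("no symbols")
    if any(w <= 0 for w in weights):
        raise InputError("weights must be positive")
    if n == 1:
        return [1]
    # heap entries: (weight, creation_order, {symbol_index: depth})
    heap = [(w, i, {i: 0}) for i, w in enumerate(weights)]
    heapq.heapify(heap)
    order = n
    while len(heap) > 1:
        w1, _, d1 = heapq.heappop(heap)
        w2, _, d2 = heapq.heappop(heap)
        merged = {s: d + 1 for s, d in d1.items()}
        for s, d in d2.items():
            merged[s] = d + 1
        heapq.heappush(heap, (w1 + w2, order, merged))
        order += 1
    _, _, depths = heap[0]
    return [depths[i] for i in range(n)]


def assign_code_lengths(freqs: FrequencyTable) -> dict[str, int]:
    """Code lengths for the symbols present (count > 0) in ``freqs``.

    Returns a mapping symbol -> positive bit length. The Kraft sum
    ``sum(2**-len)`` is <= 1 always and exactly 1 when two or more symbols
    are present; the weighted total length is optimal among prefix codes.
    """
    present = [(s, c) for s, c in zip(freqs.alphabet, freqs.counts) if c > 0]
    lengths = huffman_code_lengths([c for _, c in present])
    return {s: ln for (s, _), ln in zip(present, lengths)}


def make_label(cla: dict[str, int], freqs: FrequencyTable, k: int) -> str:
    """Format the (possibly truncated) label ``"<symbols>_<digits>"``.

    Symbols are ordered by (code length ascending, frequency descending,
    alphabet order) and the first ``min(k, #present)`` are kept, so a label
    at a smaller ``k`` is always a prefix of the label at a larger ``k``
    in both its symbol part and its digit part.
    """
    if k < 1:
        raise InputError("label length k must be >= 1")
    counts = freqs.as_dict()
    alpha_pos = {s: i for i, s in enumerate(freqs.alphabet)}
    ordered = sorted(cla, key=lambda s: (cla[s], -counts[s], alpha_pos[s]))
    kept = ordered[: min(k, len(ordered))]
    return "".join(kept) + "_" + "".join(str(cla[s]) for s in kept)


@lru_cache(maxsize=1 << 16)
def label_for_counts(counts: tuple[int, ...], alphabet: str, k: int) -> str:
    """Cached label for a raw count vector (hot path for the binner)."""
    ft = FrequencyTable(counts, alphabet)
    return make_label(assign_code_lengths(ft), ft, k)
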