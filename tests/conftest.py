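"""Shared fixtures and the independent prefix-code oracle.

The oracle deliberately avoids the package's Huffman construction: for m
present symbols it enumerates every non-decreasing code-length profile
satisfying the Kraft equality (lengths bounded by m-1, the deepest leaf a
full binary tree with m leaves allows) and, by the rearrangement
inequality, pairs the largest counts with the shortest lengths. The
minimum weighted cost over all profiles is the optimal prefix-code cost.
"""

from fractions import Fraction
from functools import lru_cache
from itertools import combinations_with_replacement

import pytest

from ostdna.synthgen import GeneratorConfig


@lru_cache(maxsize=None)
def kraft_profiles(m: int) -> tuple[tuple[int, ...], ...]:
    """All non-decreasing length profiles for m symbols with Kraft sum 1."""
    if m == 1:
        # degenerate single-symbol case: one emitted bit by convention
        return ((1,),)
    out = []
    for profile in combinations_with_replacement(range(1, m), m):
        if sum(Fraction(1, 2**l) for l in profile) == 1:
            out.append(profile)
    return tuple(out)


def optimal_prefix_cost(counts) -> int:
    """Brute-force optimal weighted code length for positive counts."""
    counts = sorted(counts, reverse=True)
    return min(
        sum(c * l for c, l in zip(counts, profile))
        for profile in kraft_profiles(len(counts))
    )


@pytest.fixture(scope="session")
def small_genome_cfg() -> GeneratorConfig:
    """A 200 kb analogue of the default regime, cheap enough for unit tests."""
    return GeneratorConfig(
        total_length=200_000,
        repeat_families=4,
        repeat_copies=2,
        repeat_length=1_000,
        repeat_spacing=20_000,
        seed=7,
    )
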