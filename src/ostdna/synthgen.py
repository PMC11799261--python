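"""Synthetic genomes with skewed local composition and distant repeats.

Real assemblies show two features this codec exploits: regional windows
whose base composition is far from uniform, and similar subsequences that
recur at distances well beyond the sliding windows of LZ-family codecs.
The generator emulates exactly those two features and nothing else:

* the genome is a concatenation of segments whose base probabilities are
  drawn from a Dirichlet over (A,C,G,T) — small concentration ``alpha``
  means strongly skewed segments;
* a few repeat families are planted: each family is one master sequence
  copied several times at positions at least ``repeat_spacing`` apart,
  each copy independently point-mutated at a small rate;
* short N-runs (assembly gaps) are overlaid last, avoiding the planted
  repeats so that unmutated copies stay exact substrings.

Randomness comes from numpy's PCG64 generator seeded explicitly, so output
is byte-identical across runs and platforms for the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, PlacementError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GeneratorConfig:
    """Defaults model a 10 Mb genome with markedly skewed ~1 kb segments
    and 20 repeat families whose copies sit >= 100 kb apart."""

    total_length: int = 10_000_000
    segment_min: int = 500
    segment_max: int = 2_000
    alpha: float = 0.3  # Dirichlet concentration per base; lower = more skew
    n_run_rate: float = 1e-5  # expected N-runs per base
    n_run_min: int = 10
    n_run_max: int = 100
    repeat_families: int = 20
    repeat_length: int = 2_000
    repeat_copies: int = 3
    repeat_mutation_rate: float = 0.01
    repeat_spacing: int = 100_000  # min start-to-start distance within a family
    seed: int = 0

    def __post_init__(self):
        if self.total_length < 1:
            raise InputError("total_length must be >= 1")
        if not (1 <= self.segment_min <= self.segment_max):
            raise InputError("need 1 <= segment_min <= segment_max")
        if self.alpha <= 0:
            raise InputError("alpha must be > 0")
        for rate in (self.n_run_rate, self.repeat_mutation_rate):
            if not 0.0 <= rate <= 1.0:
                raise InputError("rates must lie in [0, 1]")
        if self.repeat_spacing < 0:
            raise InputError("repeat_spacing must be >= 0")
        if self.repeat_families > 0 and self.repeat_copies > 0:
            if self.repeat_length > self.total_length:
                raise PlacementError("repeat_length exceeds total_length")


@dataclass(frozen=True)
class PlantedRepeat:
    """Where one copy of one repeat family landed."""

    family: int
    start: int
    mutated: bool  # False => the copy is an exact substring of the master


def _place_copies(cfg: GeneratorConfig, rng: np.random.Generator) -> list[list[int]]:
    """Start positions per family: same-family copies >= spacing apart
    (start-to-start) and no overlap between any two planted copies."""
    hi = cfg.total_length - cfg.repeat_length
    occupied: list[tuple[int, int]] = []  # all planted intervals, any family
    out: list[list[int]] = []
    max_tries = 1000
    for _ in range(cfg.repeat_families):
        starts: list[int] = []
        for _ in range(cfg.repeat_copies):
            for _attempt in range(max_tries):
                s = int(rng.integers(0, hi + 1))
                if any(abs(s - p) < cfg.repeat_spacing for p in starts):
                    continue
                if any(s < e and p < s + cfg.repeat_length for p, e in occupied):
                    continue
                starts.append(s)
                occupied.append((s, s + cfg.repeat_length))
                break
            else:
                raise PlacementError(
                    "could not place repeat copies under the spacing constraint; "
                    "reduce families/copies/spacing or enlarge the genome"
                )
        out.append(sorted(starts))
    return out


def generate_with_coordinates(cfg: GeneratorConfig) -> tuple[str, list[PlantedRepeat]]:
    """Generate a genome and report where every repeat copy was planted."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.total_length
    # 1. skewed-composition background, segment by segment
    chunks: list[np.ndarray] = []
    produced = 0
    while produced < n:
        seg_len = int(rng.integers(cfg.segment_min, cfg.segment_max + 1))
        seg_len = min(seg_len, n - produced)
        probs = rng.dirichlet(np.full(4, cfg.alpha))
        chunks.append(rng.choice(4, size=seg_len, p=probs).astype(np.uint8))
        produced += seg_len
    genome = _BASES[np.concatenate(chunks)]
    # 2. plant repeat families (overwrite the background)
    coords: list[PlantedRepeat] = []
    occupied: list[tuple[int, int]] = []
    if cfg.repeat_families > 0 and cfg.repeat_copies > 0:
        placements = _place_copies(cfg, rng)
        for fam, starts in enumerate(placements):
            master = _BASES[rng.integers(0, 4, size=cfg.repeat_length).astype(np.uint8)]
            for s in starts:
                copy = master.copy()
                mutated = False
                if cfg.repeat_mutation_rate > 0:
                    hits = np.nonzero(
                        rng.random(cfg.repeat_length) < cfg.repeat_mutation_rate
                    )[0]
                    mutated = hits.size > 0
                    for h in hits:
                        choices = _BASES[_BASES != copy[h]]
                        copy[h] = choices[rng.integers(0, 3)]
                genome[s : s + cfg.repeat_length] = copy
                coords.append(PlantedRepeat(fam, s, mutated))
        occupied = [(r.start, r.start + cfg.repeat_length) for r in coords]
    # 3. N-runs last, steering clear of the planted repeats; a run that
    # cannot find a clear spot after bounded tries is skipped
    expected_runs = cfg.n_run_rate * n
    n_runs = int(rng.poisson(expected_runs)) if expected_runs > 0 else 0
    for _ in range(n_runs):
        run_len = int(rng.integers(cfg.n_run_min, cfg.n_run_max + 1))
        if run_len >= n:
            run_len = n
        for _attempt in range(100):
            s = int(rng.integers(0, n - run_len + 1))
            if not any(s < e and p < s + run_len for p, e in occupied):
                genome[s : s + run_len] = ord("N")
                break
    return genome.tobytes().decode("ascii"), coords


def generate_genome(cfg: GeneratorConfig) -> str:
    """Deterministic synthetic genome for the given configuration."""
    return generate_with_coordinates(cfg)[0]


def describe_composition(text: str, w: int) -> pd.DataFrame:
    """Per-window base fractions; one row per window, one column per base."""
    from .binner import window_count_matrix
    from .labeling import DEFAULT_ALPHABET

    counts = window_count_matrix(text, w)
    totals = counts.sum(axis=1, keepdims=True)
    frame = pd.DataFrame(counts / totals, columns=list(DEFAULT_ALPHABET))
    frame.insert(0, "start", np.arange(len(frame)) * w)
    return frame


def write_fasta_file(text: str, path, header: str = "synthetic", width: int = 70) -> None:
    """Write the genome as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        fh.write(">" + header + "\n")
        for i in range(0, len(text), width):
            fh.write(text[i : i + width] + "\n")
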