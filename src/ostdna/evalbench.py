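"""Benchmarking: compression ratios, the window x label grid, and the
comparison against the standalone backend.

Compression ratio follows the benchmarking convention used for one-line
genomes: 100 * compressed size / original size, lower is better. Ratios
here are computed on the full archive bytes — header and coded label
stream included — which is the honest cost of the binned codec; the
bins-only byte count is also reported for comparison with pipelines that
keep compressed bins as separate files without container overhead.

Every ratio reported by this module comes from an archive (or standalone
blob) that was decompressed and verified against the input first. Wall
times are recorded for completeness but are hardware-dependent and never
asserted on.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import pandas as pd

from . import backends, container
from .binner import CodecParams
from .errors import InputError, OstError

#: Grid used by the full benchmarking protocol.
DEFAULT_WINDOW_GRID = (25, 50, 100, 125, 150, 250, 500, 750, 1_000, 2_500, 5_000, 10_000)
DEFAULT_LABEL_GRID = (1, 2, 3, 4, 5)

_MB = 1024 * 1024


def compression_ratio(original_size: int, compressed_size: int) -> float:
    """Percent ratio 100 * compressed / original (lower is better)."""
    if original_size <= 0:
        raise InputError("original size must be positive")
    if compressed_size < 0:
        raise InputError("compressed size must be non-negative")
    return 100.0 * compressed_size / original_size


@dataclass(frozen=True)
class RatioReport:
    """Sizes and derived metrics for one verified compression run."""

    original_bytes: int
    compressed_bytes: int
    compress_seconds: float
    decompress_seconds: float

    @property
    def ratio_pct(self) -> float:
        return compression_ratio(self.original_bytes, self.compressed_bytes)

    @property
    def saved_mb(self) -> float:
        return (self.original_bytes - self.compressed_bytes) / _MB

    @property
    def compress_speed_mb_s(self) -> float:
        return (self.original_bytes / _MB) / self.compress_seconds if self.compress_seconds else float("inf")

    @property
    def decompress_speed_mb_s(self) -> float:
        return (self.original_bytes / _MB) / self.decompress_seconds if self.decompress_seconds else float("inf")


def _run_ost(text: str, params: CodecParams) -> tuple[RatioReport, bytes, int]:
    """Compress + verify one OST run; returns (report, archive, bins-only bytes)."""
    t0 = time.perf_counter()
    blob = container.compress_text(text, params)
    t1 = time.perf_counter()
    restored = container.decompress_text(blob)
    t2 = time.perf_counter()
    if restored != text:
        raise OstError("round-trip verification failed")  # pragma: no cover - checksum guards this
    ar = container.read_archive(blob)
    bins_only = sum(len(b) for b in ar.blobs)
    return RatioReport(len(text), len(blob), t1 - t0, t2 - t1), blob, bins_only


def _run_standalone(text: str, backend: str) -> RatioReport:
    spec = backends.get_backend(backend)
    raw = text.encode("ascii")
    t0 = time.perf_counter()
    blob = backends.compress_blob(spec, raw)
    t1 = time.perf_counter()
    restored = backends.decompress_blob(spec, blob)
    t2 = time.perf_counter()
    if restored != raw:
        raise OstError("standalone round-trip verification failed")  # pragma: no cover
    return RatioReport(len(raw), len(blob), t1 - t0, t2 - t1)


#: Stable CSV column order for sweep output.
SWEEP_COLUMNS = ["w", "k", "bins", "compressed_bytes", "binsonly_bytes", "ratio_pct", "comp_s", "decomp_s"]


def sweep_grid(
    text: str,
    windows=DEFAULT_WINDOW_GRID,
    labels=DEFAULT_LABEL_GRID,
    backend: str = "bzip2",
) -> pd.DataFrame:
    """One verified OST run per (w, k) cell plus a standalone baseline row.

    The baseline row carries w = 0 and k = 0. Rows appear in grid order,
    baseline last.
    """
    windows = sorted(set(int(w) for w in windows))
    labels = sorted(set(int(k) for k in labels))
    if not windows or not labels:
        raise InputError("window and label grids must be non-empty")
    rows = []
    for w in windows:
        for k in labels:
            params = CodecParams(w=w, k=k, backend=backend)
            report, blob, bins_only = _run_ost(text, params)
            ar = container.read_archive(blob)
            rows.append(
                {
                    "w": w,
                    "k": k,
                    "bins": ar.header.bin_count,
                    "compressed_bytes": report.compressed_bytes,
                    "binsonly_bytes": bins_only,
                    "ratio_pct": report.ratio_pct,
                    "comp_s": report.compress_seconds,
                    "decomp_s": report.decompress_seconds,
                }
            )
    base = _run_standalone(text, backend)
    rows.append(
        {
            "w": 0,
            "k": 0,
            "bins": 0,
            "compressed_bytes": base.compressed_bytes,
            "binsonly_bytes": base.compressed_bytes,
            "ratio_pct": base.ratio_pct,
            "comp_s": base.compress_seconds,
            "decomp_s": base.decompress_seconds,
        }
    )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def best_cell(table: pd.DataFrame) -> pd.Series:
    """Grid row with the minimum ratio; ties go to smaller w, then smaller k."""
    grid = table[(table["w"] > 0)]
    if grid.empty:
        raise InputError("sweep table has no grid rows")
    ordered = grid.sort_values(["ratio_pct", "w", "k"], kind="mergesort")
    return ordered.iloc[0]


def compare_vs_standalone(
    text: str, params: CodecParams, backend: str | None = None
) -> tuple[RatioReport, RatioReport, float]:
    """(OST report, standalone report, delta saved in MB).

    ``delta`` is standalone-compressed minus OST-archive bytes, in MB:
    positive when binning beats the plain backend on the same input. Both
    paths are round-trip-verified before their sizes are reported.
    """
    backend = backend or params.backend
    ost, _, _ = _run_ost(text, params)
    base = _run_standalone(text, backend)
    delta_mb = (base.compressed_bytes - ost.compressed_bytes) / _MB
    return ost, base, delta_mb
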