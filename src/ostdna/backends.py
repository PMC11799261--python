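"""Pluggable general-purpose codecs used to compress each bin.

Each bin's concatenated content is handed to one of these backends as an
opaque byte blob; the backend id is recorded in the archive header so the
decompressor can invert it. Bundled backends use the standard-library
codecs (zlib/deflate, bzip2, xz/LZMA) plus a do-nothing ``identity``
backend useful for overhead accounting and testing. ``zstd`` and ``brotli``
are registered when their modules are importable; they are optional plugins,
never hard dependencies.

Numeric ids are frozen for archive compatibility:
0=identity, 1=deflate, 2=bzip2, 3=xz, 4=zstd, 5=brotli.

All backends run single-threaded with their library-default settings.
"""

from __future__ import annotations

import bz2
import lzma
import zlib
from dataclasses import dataclass
from typing import Callable

from .errors import CorruptArchiveError, UnknownBackendError


@dataclass(frozen=True)
class BackendSpec:
    """A registered codec: frozen numeric id plus compress/decompress pair."""

    id: str
    numeric_id: int
    compress: Callable[[bytes], bytes]
    decompress: Callable[[bytes], bytes]


_REGISTRY: dict[str, BackendSpec] = {}
_BY_NUMERIC: dict[int, BackendSpec] = {}


def register_backend(
    id: str,
    numeric_id: int,
    compress: Callable[[bytes], bytes],
    decompress: Callable[[bytes], bytes],
) -> None:
    if id in _REGISTRY:
        raise ValueError(f"backend {id!r} already registered")
    if numeric_id in _BY_NUMERIC:
        raise ValueError(f"numeric backend id {numeric_id} already registered")
    spec = BackendSpec(id, numeric_id, compress, decompress)
    _REGISTRY[id] = spec
    _BY_NUMERIC[numeric_id] = spec


def get_backend(id: str) -> BackendSpec:
    try:
        return _REGISTRY[id]
    except KeyError:
        raise UnknownBackendError(f"unknown backend {id!r}") from None


def get_backend_by_numeric(numeric_id: int) -> BackendSpec:
    try:
        return _BY_NUMERIC[numeric_id]
    except KeyError:
        raise UnknownBackendError(f"unknown numeric backend id {numeric_id}") from None


def list_backends() -> list[str]:
    """Registered backend ids, in frozen numeric-id order."""
    return [spec.id for _, spec in sorted(_BY_NUMERIC.items())]


def compress_blob(spec: BackendSpec | str, data: bytes) -> bytes:
    """Compress ``data`` under ``spec`` (a BackendSpec or a backend id)."""
    if isinstance(spec, str):
        spec = get_backend(spec)
    return spec.compress(data)


def decompress_blob(spec: BackendSpec | str, data: bytes) -> bytes:
    """Exact inverse of :func:`compress_blob`; malformed input raises
    :class:`CorruptArchiveError`."""
    if isinstance(spec, str):
        spec = get_backend(spec)
    try:
        return spec.decompress(data)
    except CorruptArchiveError:
        raise
    except Exception as exc:  # codec-specific error types vary
        raise CorruptArchiveError(f"backend {spec.id!r} failed to decompress: {exc}") from exc


register_backend("identity", 0, lambda b: b, lambda b: b)
register_backend("deflate", 1, zlib.compress, zlib.decompress)
register_backend("bzip2", 2, bz2.compress, bz2.decompress)
register_backend("xz", 3, lzma.compress, lzma.decompress)

try:  # optional plugin
    import zstandard as _zstd

    register_backend(
        "zstd",
        4,
        lambda b: _zstd.ZstdCompressor().compress(b),
        lambda b: _zstd.ZstdDecompressor().decompressobj().decompress(b),
    )
except ImportError:  # pragma: no cover - depends on runtime extras
    pass

try:  # optional plugin
    import brotli as _brotli

    register_backend("brotli", 5, _brotli.compress, _brotli.decompress)
except ImportError:  # pragma: no cover - depends on runtime extras
    pass
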