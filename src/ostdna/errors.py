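"""Exception hierarchy for the codec.

All failures raised by this package derive from :class:`OstError` so callers
can catch one type at the CLI boundary. Corruption of an archive (bad magic,
truncation, invalid code, checksum mismatch) is kept distinct from misuse of
the API (bad parameters, out-of-alphabet input).
"""


class OstError(Exception):
    """Base class for all errors raised by ostdna."""


class InputError(OstError, ValueError):
    """Invalid input data or parameters (caller error)."""


class AlphabetError(InputError):
    """A character outside the configured alphabet was encountered."""

    def __init__(self, char: str, offset: int):
        self.char = char
        self.offset = offset
        super().__init__(f"character {char!r} at offset {offset} is not in the alphabet")


class CorruptArchiveError(OstError):
    """The archive bytes are structurally invalid or inconsistent."""


class BadMagicError(CorruptArchiveError):
    """The input does not start with the archive magic."""


class UnsupportedVersionError(CorruptArchiveError):
    """The archive declares a format version this build cannot read."""


class TruncatedArchiveError(CorruptArchiveError):
    """The archive ends before a declared field or payload."""


class ChecksumMismatchError(CorruptArchiveError):
    """Decompressed text does not match the stored SHA-256 checksum."""


class UnknownBackendError(InputError):
    """The requested backend id is not registered."""


class PlacementError(InputError):
    """Synthetic repeat copies cannot be placed under the spacing constraints."""
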