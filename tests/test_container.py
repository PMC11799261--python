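"""Archive serialization, label-stream coding, and fault injection."""

import struct

import pytest
from hypothesis import given, settings, strategies as st

from ostdna import backends, container
from ostdna.binner import CodecParams, bin_text
from ostdna.container import (
    EncodedLabelStream,
    decode_label_stream,
    encode_label_stream,
    read_archive,
    write_archive,
)
from ostdna.errors import (
    BadMagicError,
    ChecksumMismatchError,
    CorruptArchiveError,
    TruncatedArchiveError,
    UnsupportedVersionError,
)


class TestLabelStreamCoding:
    def test_single_label_stores_count_only(self):
        enc = encode_label_stream(["A_1"] * 7)
        assert enc.labels == ("A_1",)
        assert enc.payload == b""
        assert enc.entry_count == 7
        assert decode_label_stream(enc) == ["A_1"] * 7

    def test_two_labels_get_one_bit_each(self):
        enc = encode_label_stream(["a", "a", "a", "b"])
        assert enc.code_lengths == (1, 1)
        assert len(enc.payload) == 1  # 4 bits padded to one byte
        assert decode_label_stream(enc) == ["a", "a", "a", "b"]

    @given(
        stream=st.lists(st.sampled_from(["A_1", "T_1", "GA_12", "CT_11", "N_1"]), min_size=1, max_size=200)
    )
    @settings(derandomize=True, max_examples=300)
    def test_decode_inverts_encode(self, stream):
        assert decode_label_stream(encode_label_stream(stream)) == stream

    @given(stream=st.lists(st.sampled_from(list("abcdefgh")), min_size=2, max_size=300))
    @settings(derandomize=True, max_examples=200)
    def test_more_frequent_labels_get_shorter_codes(self, stream):
        enc = encode_label_stream(stream)
        if len(enc.labels) < 2:
            return
        freq = {lab: stream.count(lab) for lab in enc.labels}
        lengths = dict(zip(enc.labels, enc.code_lengths))
        for a in enc.labels:
            for b in enc.labels:
                if freq[a] > freq[b]:
                    assert lengths[a] <= lengths[b]

    def test_truncated_payload_detected(self):
        enc = encode_label_stream(["a", "b", "a", "b", "a", "b", "a", "b", "a"])
        bad = EncodedLabelStream(enc.labels, enc.code_lengths, enc.entry_count + 9, enc.payload)
        with pytest.raises(CorruptArchiveError):
            decode_label_stream(bad)

    def test_kraft_violation_detected(self):
        bad = EncodedLabelStream(("a", "b"), (2, 2), 2, b"\x00")
        with pytest.raises(CorruptArchiveError, match="Kraft"):
            decode_label_stream(bad)


def _build(text="ACGTACGTAAAATTTT", w=4, k=5, backend="identity"):
    params = CodecParams(w=w, k=k, backend=backend)
    blob = container.compress_text(text, params)
    return text, params, blob


class TestArchiveFormat:
    def test_magic_is_first_four_bytes(self):
        _, _, blob = _build()
        assert blob[:4] == b"OST1"

    def test_round_trip_preserves_header_fields(self):
        text, params, blob = _build(backend="deflate")
        ar = read_archive(blob)
        assert ar.header.w == params.w
        assert ar.header.k == params.k
        assert ar.header.backend == "deflate"
        assert ar.header.t == len(text)
        assert ar.header.alphabet == params.alphabet
        assert ar.header.bin_count == len(ar.blobs)

    def test_write_read_identity_on_components(self):
        text = "ACGTACGTAAAATTTTNNNN"
        params = CodecParams(w=4, k=3, backend="identity")
        table, stream = bin_text(text, params)
        blobs = [content.encode() for content in table.bins.values()]
        data = write_archive(params, stream, blobs, len(text), container.text_checksum(text))
        ar = read_archive(data)
        assert ar.label_stream == stream
        assert ar.blobs == blobs
        assert ar.sidecar is None

    def test_changing_k_changes_only_the_k_byte(self):
        # single-symbol windows: labels and bins are identical for any k
        text = "AAAATTTTAAAA"
        blob1 = container.compress_text(text, CodecParams(w=4, k=1, backend="identity"))
        blob2 = container.compress_text(text, CodecParams(w=4, k=2, backend="identity"))
        assert len(blob1) == len(blob2)
        diffs = [i for i, (a, b) in enumerate(zip(blob1, blob2)) if a != b]
        assert diffs == [5]  # magic(4) + version(1), then the k field

    def test_determinism(self):
        _, _, blob1 = _build(backend="bzip2")
        _, _, blob2 = _build(backend="bzip2")
        assert blob1 == blob2

    def test_identity_backend_exact_size_accounting(self):
        text, params, blob = _build(text="A" * 1000, w=25, k=2)
        table, stream = bin_text(text, params)
        enc = encode_label_stream(stream)
        assert list(table.bins) == ["A_1"] and enc.payload == b""
        header = 4 + 1 + 1 + 4 + 1 + 1 + len(params.alphabet) + 8 + 32 + 4
        label_dict = 4 + sum(2 + len(lab) + 1 for lab in enc.labels)
        stream_part = 8 + 4 + len(enc.payload)
        bins_part = sum(4 + 8 + len(content) for content in table.bins.values())
        assert len(blob) == header + label_dict + stream_part + bins_part + 1  # +1 sidecar flag

    def test_sidecar_round_trip(self):
        params = CodecParams(w=4, k=2, backend="deflate")
        blob = container.compress_text("ACGTACGT", params, sidecar=b'{"x":1}')
        text, sidecar = container.decompress_archive(blob)
        assert text == "ACGTACGT"
        assert sidecar == b'{"x":1}'


class TestFaultInjection:
    def test_empty_input_is_bad_magic(self):
        with pytest.raises(BadMagicError):
            read_archive(b"")

    def test_wrong_magic(self):
        with pytest.raises(BadMagicError):
            read_archive(b"NOPE" + b"\x00" * 100)

    def test_unsupported_version(self):
        _, _, blob = _build()
        bad = blob[:4] + bytes([99]) + blob[5:]
        with pytest.raises(UnsupportedVersionError):
            read_archive(bad)

    def test_truncation_detected(self):
        _, _, blob = _build()
        with pytest.raises(TruncatedArchiveError):
            read_archive(blob[:-3])

    def test_trailing_garbage_detected(self):
        _, _, blob = _build()
        with pytest.raises(CorruptArchiveError):
            read_archive(blob + b"\x00")

    def test_bit_flip_in_blob_fails_checksum(self):
        text, params, blob = _build(text="ACGT" * 50, w=8, k=5, backend="identity")
        # flip one bit inside the last bin blob (identity => text bytes)
        idx = len(blob) - 2  # inside final blob, before the sidecar flag
        bad = bytearray(blob)
        bad[idx] ^= 0x01
        with pytest.raises((ChecksumMismatchError, CorruptArchiveError)):
            container.decompress_text(bytes(bad))


class TestEndToEnd:
    @pytest.mark.parametrize("backend", backends.list_backends())
    def test_round_trip_every_backend(self, backend):
        text = "ACGTNACGTNAAAACCCCGGGGTTTTNN" * 10
        params = CodecParams(w=7, k=3, backend=backend)
        assert container.decompress_text(container.compress_text(text, params)) == text

    def test_homogeneous_text_single_bin_empty_payload(self):
        blob = container.compress_text("A" * 1000, CodecParams(w=25, k=2, backend="identity"))
        ar = read_archive(blob)
        assert ar.header.bin_count == 1
        assert ar.label_stream == ["A_1"] * 40
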