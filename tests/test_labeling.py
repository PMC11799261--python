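"""Composition labelling: Huffman code lengths and label formatting."""

import pytest
from hypothesis import given, settings, strategies as st

from ostdna import labeling
from ostdna.errors import AlphabetError, InputError
from ostdna.labeling import (
    FrequencyTable,
    assign_code_lengths,
    count_symbols,
    huffman_code_lengths,
    make_label,
)

from conftest import optimal_prefix_cost


def kraft_sum(lengths: dict) -> float:
    return sum(2.0 ** -ln for ln in lengths.values())


class TestCountSymbols:
    @pytest.mark.parametrize(
        "window,expected",
        [
            ("GGGGA", {"A": 1, "C": 0, "G": 4, "T": 0, "N": 0}),
            ("ACGTN", {"A": 1, "C": 1, "G": 1, "T": 1, "N": 1}),
            ("NNNNNNN", {"A": 0, "C": 0, "G": 0, "T": 0, "N": 7}),
        ],
    )
    def test_exact_multiplicities(self, window, expected):
        ft = count_symbols(window)
        assert ft.as_dict() == expected
        assert ft.total == len(window)

    def test_empty_window_rejected(self):
        with pytest.raises(InputError, match="empty window"):
            count_symbols("")

    def test_out_of_alphabet_names_character_and_offset(self):
        with pytest.raises(AlphabetError, match=r"'X' at offset 3"):
            count_symbols("ACGX")


class TestCodeLengths:
    def test_paper_schema_g1_a2_t3_c3(self):
        """Frequencies realizing codes G:0, A:10, T:110, C:111."""
        ft = count_symbols("G" * 8 + "A" * 4 + "T" * 2 + "C")
        assert assign_code_lengths(ft) == {"G": 1, "A": 2, "T": 3, "C": 3}

    def test_uniform_four_symbols_all_length_two(self):
        ft = FrequencyTable((1, 1, 1, 1, 0))
        assert assign_code_lengths(ft) == {"A": 2, "C": 2, "G": 2, "T": 2}

    def test_single_present_symbol_gets_length_one(self):
        ft = FrequencyTable((7, 0, 0, 0, 0))
        assert assign_code_lengths(ft) == {"A": 1}

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=500), min_size=5, max_size=5).filter(
            lambda c: any(c)
        )
    )
    @settings(derandomize=True, max_examples=300)
    def test_matches_bruteforce_optimal_cost_and_kraft(self, counts):
        ft = FrequencyTable(tuple(counts))
        cla = assign_code_lengths(ft)
        present = {s: c for s, c in ft.as_dict().items() if c > 0}
        assert set(cla) == set(present)
        cost = sum(present[s] * cla[s] for s in cla)
        assert cost == optimal_prefix_cost(list(present.values()))
        if len(present) >= 2:
            assert kraft_sum(cla) == pytest.approx(1.0)
        else:
            assert kraft_sum(cla) <= 1.0

    def test_label_stream_order_is_creation_order(self):
        # equal weights: the two earliest leaves merge first and end up deepest
        assert huffman_code_lengths([1, 1, 1]) == [2, 2, 1]

    def test_rejects_nonpositive_weights(self):
        with pytest.raises(InputError):
            huffman_code_lengths([])
        with pytest.raises(InputError):
            huffman_code_lengths([3, 0])


class TestMakeLabel:
    @pytest.fixture()
    def paper_schema(self):
        ft = count_symbols("G" * 8 + "A" * 4 + "T" * 2 + "C")
        return assign_code_lengths(ft), ft

    @pytest.mark.parametrize("k,expected", [(4, "GATC_1233"), (2, "GA_12"), (1, "G_1"), (9, "GATC_1233")])
    def test_printed_examples_and_truncation(self, paper_schema, k, expected):
        cla, ft = paper_schema
        assert make_label(cla, ft, k) == expected

    def test_single_symbol_window(self):
        ft = count_symbols("AAAA")
        assert make_label(assign_code_lengths(ft), ft, 3) == "A_1"

    def test_equal_length_equal_freq_falls_back_to_alphabet_order(self):
        ft = FrequencyTable((0, 1, 0, 1, 0))  # C and T once each
        assert make_label(assign_code_lengths(ft), ft, 5) == "CT_11"

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=50), min_size=5, max_size=5).filter(
            lambda c: any(c)
        ),
        k1=st.integers(min_value=1, max_value=5),
        k2=st.integers(min_value=1, max_value=5),
    )
    @settings(derandomize=True, max_examples=200)
    def test_truncation_prefix_property_and_digit_monotonicity(self, counts, k1, k2):
        if k1 > k2:
            k1, k2 = k2, k1
        ft = FrequencyTable(tuple(counts))
        cla = assign_code_lengths(ft)
        short, long = make_label(cla, ft, k1), make_label(cla, ft, k2)
        s1, d1 = short.split("_")
        s2, d2 = long.split("_")
        assert s2.startswith(s1) and d2.startswith(d1)
        assert len(s1) == len(d1) == min(k1, sum(1 for c in counts if c))
        assert list(d2) == sorted(d2)  # digits non-decreasing

    def test_determinism_across_calls(self):
        ft = FrequencyTable((3, 1, 4, 1, 5))
        labels = {make_label(assign_code_lengths(ft), ft, 4) for _ in range(20)}
        assert len(labels) == 1

    def test_k_below_one_rejected(self):
        ft = count_symbols("ACGT")
        with pytest.raises(InputError):
            make_label(assign_code_lengths(ft), ft, 0)
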