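"""Retrieval metrics: hand-computed values, properties, permutation oracle."""

import itertools
import math

import numpy as np
import pytest

from modhash.core_types import CharacteristicLabels, CodeStructure, StructuredHashCode
from modhash.metrics import (
    CharacteristicSpec,
    average_precision_at_p,
    dcg_at_p,
    evaluate,
    ndcg_at_p,
    relevance_map,
    relevance_ndcg,
)
from modhash.retrieval import GalleryIndex


def L(m, o, d):
    return CharacteristicLabels(m, o, d)


# -- independent naive oracles (pure-python, no numpy) ----------------------

def naive_ap(rel):
    hits = 0
    acc = 0.0
    for r, v in enumerate(rel, start=1):
        if v:
            hits += 1
            acc += hits / r
    total = sum(rel)
    return acc / total if total else 0.0


def naive_ndcg(gains):
    def dcg(seq):
        return sum((2 ** v - 1) / math.log2(r + 1)
                   for r, v in enumerate(seq, start=1))
    ideal = dcg(sorted(gains, reverse=True))
    return dcg(gains) / ideal if ideal else 1.0


class TestRelevance:
    @pytest.mark.parametrize(
        "spec, yr, yq, expected",
        [
            ("MOD", L(1, 1, 3), L(1, 1, 3), 1),
            ("MOD", L(1, 1, 3), L(1, 1, 4), 0),
            ("D", L(2, 1, 4), L(1, 1, 4), 1),   # disease matches, modality differs
            ("MO", L(1, 0, 3), L(1, 1, 3), 0),  # organ differs
            ("M", L(1, 0, 0), L(1, 1, 3), 1),
        ],
    )
    def test_map_relevance(self, spec, yr, yq, expected):
        assert relevance_map(yr, yq, CharacteristicSpec.from_name(spec)) == expected

    @pytest.mark.parametrize(
        "spec, yr, yq, expected",
        [
            ("MOD", L(1, 1, 4), L(1, 1, 3), 2),  # modality+organ match
            ("MD", L(1, 0, 4), L(1, 1, 3), 1),   # only modality
            ("OD", L(0, 0, 0), L(1, 1, 3), 0),
            ("MOD", L(1, 1, 3), L(1, 1, 3), 3),
        ],
    )
    def test_ndcg_gain(self, spec, yr, yq, expected):
        assert relevance_ndcg(yr, yq, CharacteristicSpec.from_name(spec)) == expected

    def test_mod_binary_gain_correspondence(self, rng):
        spec = CharacteristicSpec.from_name("MOD")
        for _ in range(100):
            a = L(int(rng.integers(3)), int(rng.integers(3)), int(rng.integers(3)))
            b = L(int(rng.integers(3)), int(rng.integers(3)), int(rng.integers(3)))
            assert (relevance_map(a, b, spec) == 1) == (relevance_ndcg(a, b, spec) == 3)


class TestAveragePrecision:
    @pytest.mark.parametrize(
        "rel, expected",
        [
            ([1, 1, 1], 1.0),
            ([0, 0, 0], 0.0),
            ([1, 0, 1], (1.0 + 2.0 / 3.0) / 2.0),
            ([0, 1], 0.5),
        ],
    )
    def test_hand_values(self, rel, expected):
        assert average_precision_at_p(rel) == pytest.approx(expected, rel=1e-12)

    def test_prepending_irrelevant_never_increases(self, rng):
        for _ in range(50):
            rel = list(rng.integers(0, 2, size=8))
            assert average_precision_at_p([0] + rel) <= average_precision_at_p(rel) + 1e-12

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            average_precision_at_p([0, 2, 1])


class TestDCG:
    @pytest.mark.parametrize(
        "gains, expected",
        [
            ([3, 0, 1], 7.0 + 0.0 + 0.5),
            ([0, 0], 0.0),
            ([1], 1.0),
        ],
    )
    def test_hand_values(self, gains, expected):
        assert dcg_at_p(gains) == pytest.approx(expected, rel=1e-12)


class TestNDCG:
    def test_sorted_gains_are_ideal(self, rng):
        gains = sorted(rng.integers(0, 4, size=6), reverse=True)
        if sum(gains):
            assert ndcg_at_p(gains) == pytest.approx(1.0)

    def test_hand_value_two_items(self):
        assert ndcg_at_p([0, 3]) == pytest.approx((7.0 / math.log2(3)) / 7.0, rel=1e-12)

    def test_hand_value_three_items(self):
        assert ndcg_at_p([3, 0, 1]) == pytest.approx(
            7.5 / (7.0 + 1.0 / math.log2(3)), rel=1e-12)

    def test_empty_relevance_defined_as_one(self):
        assert ndcg_at_p([0, 0, 0]) == 1.0

    def test_promoting_higher_gain_never_decreases(self, rng):
        for _ in range(50):
            g = list(rng.integers(0, 4, size=6))
            i = int(rng.integers(1, 6))
            if g[i] > g[i - 1]:
                swapped = g.copy()
                swapped[i - 1], swapped[i] = swapped[i], swapped[i - 1]
                assert ndcg_at_p(swapped) >= ndcg_at_p(g) - 1e-12

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(200):
            g = rng.integers(0, 4, size=int(rng.integers(1, 8)))
            assert 0.0 <= ndcg_at_p(g) <= 1.0 + 1e-12


class TestOracleEquivalence:
    def test_ap_all_binary_sequences_up_to_six(self):
        for n in range(1, 7):
            for rel in itertools.product([0, 1], repeat=n):
                assert average_precision_at_p(rel) == pytest.approx(
                    naive_ap(rel), abs=1e-12)

    def test_ndcg_all_gain_sequences_up_to_five(self):
        for n in range(1, 6):
            for gains in itertools.product([0, 1, 2, 3], repeat=n):
                assert ndcg_at_p(gains) == pytest.approx(naive_ndcg(gains), abs=1e-12)


class TestEvaluate:
    def _setup(self, gallery_labels, query_label, gallery_bits, query_bits, cs):
        codes = [StructuredHashCode(bits=b, structure=cs) for b in gallery_bits]
        gal = GalleryIndex(codes=codes, labels=gallery_labels,
                           ids=[f"g{i}" for i in range(len(codes))])
        q = StructuredHashCode(bits=query_bits, structure=cs)
        return q, gal

    def test_all_matching_gallery_gives_ones(self, rng):
        cs = CodeStructure(2, 2, 2)
        bits = [rng.choice([-1, 1], 6) for _ in range(5)]
        labels = [L(0, 0, 0)] * 5
        q, gal = self._setup(labels, L(0, 0, 0), bits, rng.choice([-1, 1], 6), cs)
        rep = evaluate([q], [L(0, 0, 0)], gal, specs=["MOD"], p_list=[5])
        assert rep.map_at[("MOD", 5)] == 1.0
        assert rep.ndcg_at[("MOD", 5)] == pytest.approx(1.0)

    def test_hand_computed_toy_gallery(self):
        """Four gallery items at known distances; AP computed by hand."""
        cs = CodeStructure(2, 2, 2)
        ones = np.ones(6, dtype=int)
        def flip(k):
            b = ones.copy()
            b[:k] = -1
            return b
        # distances 0,1,2,3 -> ranking g0,g1,g2,g3
        bits = [flip(0), flip(1), flip(2), flip(3)]
        labels = [L(0, 0, 0), L(1, 0, 0), L(0, 0, 0), L(1, 1, 1)]
        q, gal = self._setup(labels, L(0, 0, 0), bits, ones, cs)
        rep = evaluate([q], [L(0, 0, 0)], gal, specs=["MOD"], p_list=[4])
        # relevant at ranks 1 and 3: AP = (1/1 + 2/3)/2
        assert rep.map_at[("MOD", 4)] == pytest.approx((1 + 2 / 3) / 2)

    def test_permutation_oracle_five_items(self, rng):
        """Brute-force scorer over every permutation of a 5-item gallery."""
        cs = CodeStructure(2, 2, 2)
        yq = L(0, 0, 0)
        labels = [L(0, 0, 0), L(0, 0, 1), L(1, 0, 0), L(0, 0, 0), L(1, 1, 1)]
        spec = CharacteristicSpec.from_name("MOD")
        for perm in itertools.permutations(range(5)):
            # force the ranking to be exactly `perm` via distances 0..4
            ones = np.ones(6, dtype=int)
            bits_by_rank = []
            for rank, item in enumerate(perm):
                b = ones.copy()
                b[:rank] = -1
                bits_by_rank.append((item, b))
            bits = [b for _, b in sorted(bits_by_rank)]
            perm_labels = [labels[i] for i in range(5)]
            q, gal = self._setup(perm_labels, yq, bits, ones, cs)
            rep = evaluate([q], [yq], gal, specs=["MOD"], p_list=[5])
            ranked = [labels[i] for i in perm]
            rel = [relevance_map(y, yq, spec) for y in ranked]
            gains = [relevance_ndcg(y, yq, spec) for y in ranked]
            assert rep.map_at[("MOD", 5)] == pytest.approx(naive_ap(rel), abs=1e-12)
            assert rep.ndcg_at[("MOD", 5)] == pytest.approx(naive_ndcg(gains), abs=1e-12)

    def test_empty_query_set_rejected(self, rng):
        cs = CodeStructure(2, 2, 2)
        codes = [StructuredHashCode(bits=np.ones(6, dtype=int), structure=cs)]
        gal = GalleryIndex(codes=codes, labels=[L(0, 0, 0)], ids=["g0"])
        with pytest.raises(ValueError):
            evaluate([], [], gal)
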