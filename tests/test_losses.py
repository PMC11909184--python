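"""Loss contracts: closed-form values, algebraic identities, monotonicity."""

import numpy as np
import pytest

from modhash._nn import Tensor
from modhash.core_types import CharacteristicLabels, CodeStructure, RelaxedHashCode
from modhash.losses import (
    LossConfig,
    batch_cauchy_loss,
    batch_classification_loss,
    batch_quantization_loss,
    cauchy_loss,
    cauchy_loss_direct,
    cauchy_similarity,
    classification_loss,
    continuous_hamming,
    quantization_loss,
    total_loss,
)
from modhash.training import similarity_matrix


class TestClassificationLoss:
    def test_certain_prediction_gives_zero(self):
        logits = [np.array([50.0, -50, -50, -50, -50]),
                  np.array([-50.0, 50, -50, -50]),
                  np.array([-50.0] * 12 + [50.0])]
        labels = CharacteristicLabels(0, 1, 12)
        assert classification_loss(logits, labels) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_logits_closed_form(self):
        logits = [np.zeros(5), np.zeros(4), np.zeros(13)]
        labels = CharacteristicLabels(2, 0, 7)
        expected = np.log(5) + np.log(4) + np.log(13)
        assert classification_loss(logits, labels) == pytest.approx(expected, rel=1e-12)

    def test_joint_permutation_invariance(self, rng):
        logits = [rng.standard_normal(5), rng.standard_normal(4), rng.standard_normal(13)]
        labels = CharacteristicLabels(2, 1, 7)
        perm = rng.permutation(5)
        permuted = [logits[0][perm], logits[1], logits[2]]
        new_m = int(np.where(perm == 2)[0][0])
        assert classification_loss(permuted, CharacteristicLabels(new_m, 1, 7)) == \
            pytest.approx(classification_loss(logits, labels), rel=1e-12)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            classification_loss([np.zeros(5), np.zeros(4), np.zeros(13)],
                                CharacteristicLabels(0, 0, 13))

    def test_batch_sums_over_samples(self, rng):
        logits = [np.zeros((3, 5)), np.zeros((3, 4)), np.zeros((3, 13))]
        labels = [CharacteristicLabels(0, 0, 0)] * 3
        single = np.log(5) + np.log(4) + np.log(13)
        assert classification_loss(logits, labels) == pytest.approx(3 * single, rel=1e-12)


class TestContinuousHamming:
    def test_identical_codes_distance_zero(self, rng):
        h = rng.uniform(-1, 1, 24)
        assert continuous_hamming(h, h) == pytest.approx(0.0, abs=1e-12)

    def test_opposite_codes_distance_k(self, rng):
        h = rng.choice([-1.0, 1.0], 24)
        assert continuous_hamming(h, -h) == pytest.approx(24.0)

    def test_equals_mismatch_count_on_binary_codes(self, rng):
        for _ in range(200):
            k = int(rng.integers(4, 60))
            a = rng.choice([-1.0, 1.0], k)
            b = rng.choice([-1.0, 1.0], k)
            mism = int((a != b).sum())
            assert continuous_hamming(a, b) == pytest.approx(mism, abs=1e-9)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            continuous_hamming(np.zeros(4), np.ones(4))


class TestCauchySimilarity:
    def test_zero_distance_gives_one(self, rng):
        h = rng.uniform(-1, 1, 24)
        assert cauchy_similarity(h, h, gamma=6.0) == pytest.approx(1.0)

    def test_distance_equal_gamma_gives_half(self):
        a = np.ones(24)
        b = np.concatenate([-np.ones(6), np.ones(18)])  # d = 6
        assert cauchy_similarity(a, b, gamma=6.0) == pytest.approx(0.5)

    def test_gamma_six_distance_eighteen(self):
        a = np.ones(24)
        b = np.concatenate([-np.ones(18), np.ones(6)])  # d = 18
        assert cauchy_similarity(a, b, gamma=6.0) == pytest.approx(0.25)

    def test_strictly_decreasing_in_distance(self):
        a = np.ones(24)
        sims = []
        for m in range(0, 25, 4):
            b = np.concatenate([-np.ones(m), np.ones(24 - m)])
            sims.append(cauchy_similarity(a, b, gamma=6.0))
        assert all(x > y for x, y in zip(sims, sims[1:]))


class TestCauchyLoss:
    def test_similar_pair_at_zero_distance(self, rng):
        h = rng.uniform(-1, 1, 24)
        assert cauchy_loss(h, h, s=1, gamma=6.0) == pytest.approx(0.0, abs=1e-5)

    def test_dissimilar_pair_at_gamma_distance_is_log2(self):
        a = np.ones(24)
        b = np.concatenate([-np.ones(6), np.ones(18)])  # d = 6 = gamma
        assert cauchy_loss(a, b, s=0, gamma=6.0) == pytest.approx(np.log(2), rel=1e-9)

    def test_dissimilar_pair_vanishes_at_large_distance(self):
        a = np.ones(24)
        assert cauchy_loss(a, -a, s=0, gamma=0.1) < 0.01

    def test_cross_entropy_and_expanded_forms_agree(self, rng):
        """The -[s log ŝ + (1-s) log(1-ŝ)] form equals the expanded
        s·log(d/γ) + log(1 + γ/d) form for s in {0, 1}."""
        k = 24
        for gamma in (1.0, k / 4, k / 2):
            for _ in range(1000):
                a = rng.uniform(-1, 1, k)
                b = rng.uniform(-1, 1, k)
                for s in (0, 1):
                    assert cauchy_loss(a, b, s, gamma) == pytest.approx(
                        cauchy_loss_direct(a, b, s, gamma), abs=1e-9)

    def test_monotonicity_in_distance(self):
        a = np.ones(24)
        s1, s0 = [], []
        for m in range(1, 24, 3):
            b = np.concatenate([-np.ones(m), np.ones(24 - m)])
            s1.append(cauchy_loss(a, b, 1, gamma=6.0))
            s0.append(cauchy_loss(a, b, 0, gamma=6.0))
        assert all(x < y for x, y in zip(s1, s1[1:]))  # s=1: increasing
        assert all(x > y for x, y in zip(s0, s0[1:]))  # s=0: decreasing


class TestQuantizationLoss:
    def test_binary_code_gives_zero(self, rng):
        assert quantization_loss(rng.choice([-1.0, 1.0], 24)) == 0.0

    def test_zero_vector_norm(self):
        h = RelaxedHashCode(values=np.zeros(24), structure=CodeStructure(8, 8, 8))
        assert quantization_loss(h) == pytest.approx(np.sqrt(24), rel=1e-12)

    def test_sign_flip_invariance(self, rng):
        h = rng.uniform(0.01, 1, 24)  # keep away from the sign(0) tie
        flips = rng.choice([-1.0, 1.0], 24)
        assert quantization_loss(h * flips) == pytest.approx(
            quantization_loss(h), rel=1e-12)

    def test_zero_iff_binary(self, rng):
        h = rng.uniform(-0.99, 0.99, 24)
        assert quantization_loss(h) > 0
        assert quantization_loss(np.sign(h)) == 0.0


class TestTotalLoss:
    def test_arithmetic(self):
        out = total_loss(1.0, 2.0, 3.0, LossConfig(gamma=6.0, alpha=0.01))
        assert out.L == pytest.approx(3.03)

    def test_default_alpha(self):
        assert LossConfig().alpha == 0.01

    def test_ablation_subset(self):
        cfg = LossConfig(loss_subset=frozenset({"L1"}))
        out = total_loss(1.0, 2.0, 3.0, cfg)
        assert out.L == 1.0 and out.L2 == 0.0 and out.L3 == 0.0

    def test_gamma_defaults_to_quarter_code_length(self):
        assert LossConfig().resolve_gamma(58) == pytest.approx(14.5)


class TestBatchVersionsMatchReference:
    def test_classification(self, rng):
        logits = {c: Tensor(rng.standard_normal((6, n)))
                  for c, n in (("modality", 5), ("organ", 4), ("disease", 13))}
        labels = [CharacteristicLabels(int(rng.integers(5)), int(rng.integers(4)),
                                       int(rng.integers(13))) for _ in range(6)]
        ref = classification_loss(
            [logits["modality"].data, logits["organ"].data, logits["disease"].data],
            labels)
        assert batch_classification_loss(logits, labels).item() == pytest.approx(
            ref, rel=1e-9)

    def test_cauchy_pairs(self, rng):
        h = rng.uniform(-0.99, 0.99, (8, 24))
        labels = [CharacteristicLabels(int(rng.integers(2)), 0, 0) for _ in range(8)]
        s = similarity_matrix(labels)
        gamma = 6.0
        ref = np.mean([
            cauchy_loss(h[i], h[j], int(s[i, j]), gamma)
            for i in range(8) for j in range(i + 1, 8)
        ])
        out = batch_cauchy_loss(Tensor(h), s, gamma).item()
        assert out == pytest.approx(ref, abs=1e-5)

    def test_quantization(self, rng):
        h = rng.uniform(-0.99, 0.99, (5, 24))
        assert batch_quantization_loss(Tensor(h)).item() == pytest.approx(
            quantization_loss(h), abs=1e-5)
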