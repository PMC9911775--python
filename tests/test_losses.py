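"""Objective components: semantic consistency, manifold preservation,
Laplacian probe, quantization regularizer and their combination."""

import numpy as np
import pytest

from dcpha import (
    CodeMatrix,
    LabelSet,
    LossWeights,
    PredictionSet,
    laplacian_embedding_loss,
    manifold_preserving_fixed_point,
    manifold_preserving_loss,
    multi_manifold_similarity,
    quantization_regularizer,
    semantic_consistency_loss,
    total_objective,
)
from dcpha import autodiff as ad
from dcpha.exceptions import DegenerateInputError, DimensionError
from dcpha.losses import (
    manifold_pair_term,
    manifold_preserving_kernel,
    quantization_kernel,
)


class TestSemanticConsistency:
    def test_zero_at_perfect_predictions(self):
        onehot = np.eye(3)[[0, 1, 2, 0]]
        y = np.stack([onehot, onehot])
        preds = PredictionSet(y=y, r=y.copy())
        labels = LabelSet(onehot.astype(int))
        assert semantic_consistency_loss(preds, labels) == 0.0

    def test_worked_two_class_example(self):
        # M=1, N=1, C=2: ℓ=(0,1), y=(1,0), r=(0,1) → √2 + 0 + √2 = 2√2
        preds = PredictionSet(y=np.array([[[1.0, 0.0]]]), r=np.array([[[0.0, 1.0]]]))
        labels = LabelSet(np.array([[0, 1]]))
        assert semantic_consistency_loss(preds, labels) == pytest.approx(
            2.0 * np.sqrt(2.0), abs=1e-12)

    def test_duplicating_samples_doubles_loss(self, rng):
        n, c = 4, 3
        onehot = np.eye(c)[rng.integers(0, c, n)]
        y = ad.softmax(rng.normal(size=(2, n, c)))
        r = ad.softmax(rng.normal(size=(2, n, c)))
        base = semantic_consistency_loss(PredictionSet(y, r), LabelSet(onehot.astype(int)))
        y2 = np.concatenate([y, y], axis=1)
        r2 = np.concatenate([r, r], axis=1)
        lab2 = LabelSet(np.concatenate([onehot, onehot]).astype(int))
        assert semantic_consistency_loss(PredictionSet(y2, r2), lab2) == pytest.approx(
            2.0 * base, rel=1e-12)

    def test_shape_mismatch(self):
        preds = PredictionSet(y=np.full((1, 2, 2), 0.5), r=np.full((1, 2, 2), 0.5))
        with pytest.raises(DimensionError):
            semantic_consistency_loss(preds, LabelSet(np.array([[1, 0]])))


class TestManifoldPreserving:
    def test_pair_term_at_zero_similarity(self):
        assert manifold_pair_term(0.0, True) == pytest.approx(np.log(2.0), abs=1e-12)
        assert manifold_pair_term(0.0, False) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_pair_terms_nonnegative(self):
        for s in np.linspace(-3, 3, 50):
            assert manifold_pair_term(s, True) >= 0.0
            assert manifold_pair_term(s, False) >= 0.0

    def test_loss_matches_similarity_matrix_recomputation(self, random_codes):
        codes, labels = random_codes
        tau = 0.8
        got = manifold_preserving_loss(codes, labels, tau=tau)
        sim = multi_manifold_similarity(codes, labels, tau=tau).matrix
        same = labels.same_label_matrix()
        big_i = np.tile(same, (2, 2))
        want = float(np.sum(np.log1p(np.exp(sim)) - big_i * sim))
        assert got == pytest.approx(want, rel=1e-12)

    def test_self_pair_exclusion_removes_diagonal(self, random_codes):
        codes, labels = random_codes
        with_self = manifold_preserving_loss(codes, labels, include_self_pairs=True)
        without = manifold_preserving_loss(codes, labels, include_self_pairs=False)
        # self pairs have homogeneous similarity 1 and I = 1
        n_self = 2 * codes[0].n_samples
        expected_delta = n_self * manifold_pair_term(1.0, True)
        assert with_self - without == pytest.approx(expected_delta, rel=1e-9)

    def test_fixed_point_is_log_golden_ratio(self):
        root = manifold_preserving_fixed_point()
        assert abs(root - np.log((1.0 + np.sqrt(5.0)) / 2.0)) < 1e-12
        assert np.log1p(np.exp(root)) == pytest.approx(2.0 * root, abs=1e-12)


class TestLaplacianProbe:
    def test_zero_when_codes_identical(self):
        vals = np.tile([1.0, -1.0], (3, 1))
        codes = [CodeMatrix(vals, modality_index=m) for m in range(2)]
        sim = np.ones((6, 6))
        assert laplacian_embedding_loss(codes, sim) == pytest.approx(0.0, abs=1e-12)

    def test_orthonormal_pair(self):
        codes = [CodeMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]))]
        sim = np.ones((2, 2))
        # ordered pairs (1,2) and (2,1): each ½·1·2 = 1 → total 2
        assert laplacian_embedding_loss(codes, sim) == pytest.approx(2.0, abs=1e-12)

    def test_row_scaling_invariance(self, rng):
        vals = rng.uniform(-1, 1, (4, 3))
        codes = [CodeMatrix(vals)]
        sim = np.abs(rng.normal(size=(4, 4)))
        sim = (sim + sim.T) / 2
        base = laplacian_embedding_loss(codes, sim)
        scaled = [CodeMatrix(np.clip(vals * 0.5, -1, 1))]
        assert laplacian_embedding_loss(scaled, sim) == pytest.approx(base, rel=1e-9)

    def test_zero_norm_row_rejected(self):
        codes = [CodeMatrix(np.array([[0.0, 0.0], [1.0, 0.0]]))]
        with pytest.raises(DegenerateInputError):
            laplacian_embedding_loss(codes, np.ones((2, 2)))


class TestQuantization:
    def test_all_ones_is_zero(self):
        codes = [CodeMatrix(np.ones((3, 5)), is_binary=True)]
        assert quantization_regularizer(codes) == 0.0

    def test_single_code_counted_once(self):
        minus = [CodeMatrix(-np.ones((1, 8)), is_binary=True)]
        assert quantization_regularizer(minus, count_multiplicity=False) == pytest.approx(16.0)
        zeros = [CodeMatrix(np.zeros((1, 8)))]
        assert quantization_regularizer(zeros, count_multiplicity=False) == pytest.approx(8.0)

    def test_printed_multiplicity(self):
        # Eq. 10 counts each code 2·M·N times
        minus = [CodeMatrix(-np.ones((2, 4)), is_binary=True) for _ in range(2)]
        per_code = 8.0  # ‖−1 − 1‖₁ over K = 4
        assert quantization_regularizer(minus) == pytest.approx(2 * 2 * 2 * (4 * per_code))

    def test_magnitude_variant_zero_at_binary(self):
        codes = [CodeMatrix(np.array([[1.0, -1.0, 1.0]]), is_binary=True)]
        assert quantization_regularizer(codes, variant="magnitude") == 0.0
        assert quantization_regularizer(codes, variant="literal",
                                        count_multiplicity=False) == pytest.approx(2.0)


class TestTotalObjective:
    def _inputs(self, rng):
        n, c = 4, 2
        onehot = np.eye(c)[rng.integers(0, c, n)].astype(int)
        labels = LabelSet(onehot)
        codes = [CodeMatrix(rng.uniform(-0.9, 0.9, (n, 3)), modality_index=m)
                 for m in range(2)]
        preds = PredictionSet(ad.softmax(rng.normal(size=(2, n, c))),
                              ad.softmax(rng.normal(size=(2, n, c))))
        return preds, codes, labels

    def test_zero_when_everything_perfect(self):
        onehot = np.array([[1, 0]])
        labels = LabelSet(onehot)
        preds = PredictionSet(np.array([[[1.0, 0.0]]]), np.array([[[1.0, 0.0]]]))
        codes = [CodeMatrix(np.ones((1, 4)), is_binary=True)]
        assert total_objective(preds, codes, labels,
                               weights=LossWeights(alpha=0.0, beta=0.0)) == 0.0
        assert total_objective(preds, codes, labels,
                               weights=LossWeights(alpha=1.0, beta=0.0)) == 0.0

    def test_equals_hand_combination(self, rng):
        preds, codes, labels = self._inputs(rng)
        w = LossWeights(alpha=0.7, beta=1.3)
        got = total_objective(preds, codes, labels, tau=0.9, weights=w)
        want = (w.alpha * semantic_consistency_loss(preds, labels)
                + w.beta * manifold_preserving_loss(codes, labels, tau=0.9)
                + quantization_regularizer(codes))
        assert got == pytest.approx(want, rel=1e-10)

    def test_ablation_identities(self, rng):
        preds, codes, labels = self._inputs(rng)
        dcha = total_objective(preds, codes, labels, weights=LossWeights(0.5, 0.0))
        assert dcha == pytest.approx(
            0.5 * semantic_consistency_loss(preds, labels)
            + quantization_regularizer(codes), rel=1e-12)
        dpha = total_objective(preds, codes, labels, weights=LossWeights(0.0, 0.5))
        assert dpha == pytest.approx(
            0.5 * manifold_preserving_loss(codes, labels)
            + quantization_regularizer(codes), rel=1e-12)


class TestGradients:
    """Central finite differences against the autodiff gradients."""

    @staticmethod
    def _fd_grad(fn, arrays, mi, eps=1e-6):
        fd = np.zeros_like(arrays[mi])
        for idx in np.ndindex(*arrays[mi].shape):
            plus = [a.copy() for a in arrays]
            plus[mi][idx] += eps
            minus = [a.copy() for a in arrays]
            minus[mi][idx] -= eps
            fd[idx] = (fn(plus) - fn(minus)) / (2 * eps)
        return fd

    def test_manifold_loss_gradient(self, rng):
        n, k = 4, 3
        arrays = [rng.uniform(-0.9, 0.9, (n, k)) for _ in range(2)]
        same = rng.integers(0, 2, n)
        mask = same[:, None] == same[None, :]

        def fn(arrs):
            return float(manifold_preserving_kernel(arrs, mask, tau=1.0))

        tens = [ad.Tensor(a, requires_grad=True) for a in arrays]
        manifold_preserving_kernel(tens, mask, tau=1.0).backward()
        for mi, t in enumerate(tens):
            fd = self._fd_grad(fn, arrays, mi)
            rel = np.abs(fd - t.grad) / (np.abs(fd) + 1e-8)
            assert rel.max() < 1e-4

    def test_quantization_gradient(self, rng):
        arrays = [rng.uniform(-0.9, 0.9, (3, 4)) for _ in range(2)]
        for variant in ("literal", "magnitude"):
            def fn(arrs):
                return float(quantization_kernel(arrs, variant))

            tens = [ad.Tensor(a, requires_grad=True) for a in arrays]
            quantization_kernel(tens, variant).backward()
            for mi, t in enumerate(tens):
                fd = self._fd_grad(fn, arrays, mi)
                rel = np.abs(fd - t.grad) / (np.abs(fd) + 1e-8)
                assert rel.max() < 1e-4
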