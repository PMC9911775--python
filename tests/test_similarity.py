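"""The heterogeneous / homogeneous / multi-manifold similarity constructions."""

import numpy as np
import pytest

from dcpha import (
    CodeMatrix,
    DegenerateInputError,
    DimensionError,
    LabelSet,
    ParameterError,
    euclidean_distance,
    heterogeneous_pair_similarity,
    heterogeneous_similarity_matrix,
    homogeneous_similarity_matrix,
    modified_distance,
    multi_manifold_similarity,
)


class TestScalarDistances:
    @pytest.mark.parametrize("a,b,expected", [
        ((1, -1, 1), (1, -1, 1), 0.0),
        ((1, 1), (-1, -1), 2.0 * np.sqrt(2.0)),
        ((1, 0), (0, 1), np.sqrt(2.0)),
    ])
    def test_euclidean(self, a, b, expected):
        assert euclidean_distance(a, b) == pytest.approx(expected, abs=1e-12)
        assert euclidean_distance(b, a) == pytest.approx(expected, abs=1e-12)

    def test_euclidean_length_mismatch(self):
        with pytest.raises(DimensionError):
            euclidean_distance((1, 2), (1, 2, 3))

    def test_modified_distance_closed_forms(self):
        a = np.array([1.0, 0.0])
        assert modified_distance(a, a, same_label=True) == pytest.approx(0.0)
        assert modified_distance(a, a, same_label=False) == pytest.approx(1.0)
        # different labels at d = ln 2: sqrt(e^(-ln 2)) = 1/sqrt(2)
        b = a + np.array([np.log(2.0), 0.0])
        assert modified_distance(a, b, same_label=False) == pytest.approx(
            1.0 / np.sqrt(2.0), abs=1e-12)

    def test_modified_distance_monotonicity(self):
        a = np.zeros(3)
        ds = np.linspace(0.0, 5.0, 30)
        same = [modified_distance(a, a + [d, 0, 0], True) for d in ds]
        diff = [modified_distance(a, a + [d, 0, 0], False) for d in ds]
        assert np.all(np.diff(same) >= 0)
        assert np.all(np.diff(diff) <= 0)


class TestPairSimilarity:
    def test_same_label_zero_distance_is_one(self):
        a = np.array([1.0, 1.0])
        for tau in (0.3, 1.0, 5.0):
            assert heterogeneous_pair_similarity(a, a, True, tau) == pytest.approx(1.0)

    def test_diff_label_zero_distance(self):
        a = np.array([1.0, 1.0])
        assert heterogeneous_pair_similarity(a, a, False, 1.0) == pytest.approx(
            np.exp(-1.0), abs=1e-12)

    def test_same_label_antipodal(self):
        # exp(-(1 - e^(-2*sqrt(2))))
        a, b = np.array([1.0, 1.0]), np.array([-1.0, -1.0])
        expected = np.exp(-(1.0 - np.exp(-2.0 * np.sqrt(2.0))))
        got = heterogeneous_pair_similarity(a, b, True, 1.0)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.39028, abs=5e-5)

    def test_invalid_tau(self):
        with pytest.raises(ParameterError):
            heterogeneous_pair_similarity(np.ones(2), np.ones(2), True, 0.0)

    def test_same_label_monotone_nonincreasing_in_distance(self):
        a = np.zeros(2)
        vals = [heterogeneous_pair_similarity(a, a + [d, 0.0], True, 1.0)
                for d in np.linspace(0, 6, 40)]
        assert np.all(np.diff(vals) <= 1e-15)

    def test_diff_label_monotone_nondecreasing_with_floor(self):
        a = np.zeros(2)
        vals = [heterogeneous_pair_similarity(a, a + [d, 0.0], False, 1.0)
                for d in np.linspace(0, 6, 40)]
        assert np.all(np.diff(vals) >= -1e-15)
        assert vals[0] == pytest.approx(np.exp(-1.0))


class TestMatrices:
    def test_heterogeneous_single_sample(self):
        cm = CodeMatrix([[1.0, 1.0]], modality_index=0)
        cn = CodeMatrix([[1.0, 1.0]], modality_index=1)
        labels = LabelSet.from_class_index([0], 2)
        mat = heterogeneous_similarity_matrix(cm, cn, labels, tau=1.0)
        assert mat.shape == (1, 1)
        assert mat[0, 0] == pytest.approx(1.0)

    def test_heterogeneous_identical_codes_different_labels(self):
        vals = np.array([[1.0, -1.0], [1.0, -1.0]])
        cm = CodeMatrix(vals, modality_index=0)
        cn = CodeMatrix(vals, modality_index=1)
        labels = LabelSet.from_class_index([0, 1], 2)
        for tau in (0.5, 1.0, 2.0):
            mat = heterogeneous_similarity_matrix(cm, cn, labels, tau=tau)
            assert mat[0, 1] == pytest.approx(np.exp(-1.0 / tau))
            assert mat[1, 0] == pytest.approx(np.exp(-1.0 / tau))

    def test_heterogeneous_range(self, rng):
        cm = CodeMatrix(rng.uniform(-1, 1, (7, 5)), modality_index=0)
        cn = CodeMatrix(rng.uniform(-1, 1, (7, 5)), modality_index=1)
        labels = LabelSet.from_class_index(rng.integers(0, 3, 7), 3)
        mat = heterogeneous_similarity_matrix(cm, cn, labels)
        assert np.all(mat > 0.0) and np.all(mat <= 1.0)

    def test_heterogeneous_requires_distinct_modalities(self):
        cm = CodeMatrix([[1.0]], modality_index=0)
        labels = LabelSet.from_class_index([0], 2)
        with pytest.raises(ParameterError):
            heterogeneous_similarity_matrix(cm, cm, labels)

    def test_homogeneous_identities(self):
        vals = np.array([[1.0, 1.0, -1.0, -1.0],
                         [1.0, -1.0, 1.0, -1.0],
                         [-1.0, -1.0, 1.0, 1.0]])
        mat = homogeneous_similarity_matrix(CodeMatrix(vals, is_binary=True))
        assert np.allclose(np.diag(mat), 1.0)
        assert mat[0, 1] == pytest.approx(0.0)   # orthogonal ±1 codes
        assert mat[0, 2] == pytest.approx(-1.0)  # antipodal

    def test_homogeneous_zero_row_rejected(self):
        with pytest.raises(DegenerateInputError):
            homogeneous_similarity_matrix(CodeMatrix([[0.0, 0.0], [1.0, 0.0]]))

    def test_single_modality_equals_homogeneous(self, rng):
        cm = CodeMatrix(rng.uniform(-1, 1, (4, 3)))
        labels = LabelSet.from_class_index(rng.integers(0, 2, 4), 2)
        sim = multi_manifold_similarity([cm], labels)
        assert np.allclose(sim.matrix, homogeneous_similarity_matrix(cm))

    def test_two_modalities_single_subject_all_ones(self):
        cm = [CodeMatrix([[1.0, 0.0]], modality_index=m) for m in range(2)]
        labels = LabelSet.from_class_index([0], 2)
        mat = multi_manifold_similarity(cm, labels).matrix
        assert np.allclose(mat, np.ones((2, 2)))

    def test_assembled_symmetry(self, rng):
        codes = [CodeMatrix(np.where(rng.normal(size=(3, 4)) >= 0, 1.0, -1.0),
                            modality_index=m, is_binary=True) for m in range(2)]
        labels = LabelSet.from_class_index(rng.integers(0, 2, 3), 2)
        mat = multi_manifold_similarity(codes, labels).matrix
        assert mat.shape == (6, 6)
        assert np.max(np.abs(mat - mat.T)) < 1e-12

    def test_shape_mismatch_rejected(self, rng):
        c1 = CodeMatrix(rng.uniform(-1, 1, (3, 4)), modality_index=0)
        c2 = CodeMatrix(rng.uniform(-1, 1, (4, 4)), modality_index=1)
        labels = LabelSet.from_class_index([0, 1, 0], 2)
        with pytest.raises(DimensionError):
            multi_manifold_similarity([c1, c2], labels)

    def test_multilabel_rejected(self):
        with pytest.raises(ParameterError):
            LabelSet(np.array([[1, 1], [0, 1]]))


def _scalar_oracle(codes, labels, tau):
    """Entry-by-entry recomputation of the assembled multi-manifold matrix."""
    m_mod, n = len(codes), codes[0].n_samples
    full = np.zeros((m_mod * n, m_mod * n))
    cls = labels.class_index
    for m in range(m_mod):
        for nn in range(m_mod):
            for i in range(n):
                for j in range(n):
                    a = codes[m].values[i]
                    b = codes[nn].values[j]
                    if m == nn:
                        v = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
                    else:
                        v = heterogeneous_pair_similarity(a, b, cls[i] == cls[j], tau)
                    full[m * n + i, nn * n + j] = v
    return full


@pytest.mark.parametrize("m_mod,n,k,seed", [(1, 3, 2, 0), (2, 4, 3, 1),
                                            (3, 5, 4, 2), (2, 2, 4, 3)])
def test_vectorized_matches_scalar_oracle(m_mod, n, k, seed):
    rng = np.random.default_rng(seed)
    codes = [CodeMatrix(rng.uniform(-0.9, 0.9, (n, k)), modality_index=m)
             for m in range(m_mod)]
    labels = LabelSet.from_class_index(rng.integers(0, 2, n), 2)
    tau = float(rng.uniform(0.5, 2.0))
    got = multi_manifold_similarity(codes, labels, tau=tau).matrix
    want = _scalar_oracle(codes, labels, tau)
    assert np.max(np.abs(got - want)) < 1e-10
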