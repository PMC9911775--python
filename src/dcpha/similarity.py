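"""Multi-manifold similarity between hash codes.

Samples of one modality lie on a shared sub-manifold, so their affinity is
measured with cosine similarity (*homogeneous* similarity).  Samples of two
different modalities live on different sub-manifolds; their affinity is a
heat-kernel similarity ``exp(-D²/τ)`` of a label-aware *modified distance*

    D(a, b) = sqrt(1 - exp(-d(a, b)))   if the labels agree,
    D(a, b) = sqrt(exp(-d(a, b)))       otherwise,

with ``d`` the Euclidean distance (*heterogeneous* similarity).  Stacking the
per-modality homogeneous matrices on the block diagonal and the pairwise
heterogeneous matrices off-diagonal yields the MN×MN *multi-manifold
similarity* used by the similarity-preserving loss.

All matrix kernels accept either ``ndarray`` or autodiff ``Tensor`` input;
the Tensor path is differentiable (an ε guards the sqrt at zero distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .exceptions import DegenerateInputError, DimensionError, ParameterError

_SQRT_EPS = 1e-12  # guards d/dx sqrt(x) at x = 0 on the differentiable path


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CodeMatrix:
    """N×K matrix of hash codes for one modality.

    Relaxed codes live in [-1, 1]; binary codes in {-1, +1}.
    """

    values: np.ndarray
    modality_index: int = 0
    is_binary: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DimensionError("code matrix must be 2-D (N samples × K bits)")
        if self.is_binary:
            if not np.all(np.isin(self.values, (-1.0, 1.0))):
                raise ParameterError("binary code matrix must contain only -1 and +1")
        elif self.values.size and (self.values.min() < -1.0 or self.values.max() > 1.0):
            raise ParameterError("relaxed codes must lie in [-1, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bits(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelSet:
    """One-hot labels with the derived integer class index."""

    onehot: np.ndarray
    class_index: np.ndarray = field(init=False)

    def __post_init__(self):
        self.onehot = np.asarray(self.onehot)
        if self.onehot.ndim != 2:
            raise DimensionError("one-hot labels must be 2-D (N × C)")
        if not np.all(np.isin(self.onehot, (0, 1))):
            raise ParameterError("one-hot labels must be binary")
        if self.onehot.size and not np.all(self.onehot.sum(axis=1) == 1):
            raise ParameterError("each label row must have exactly one 1 (single-label)")
        self.class_index = self.onehot.argmax(axis=1)

    @classmethod
    def from_class_index(cls, idx, n_classes: int) -> "LabelSet":
        idx = np.asarray(idx, dtype=int)
        onehot = np.zeros((idx.size, n_classes), dtype=np.int64)
        onehot[np.arange(idx.size), idx] = 1
        return cls(onehot)

    @property
    def n_samples(self) -> int:
        return self.onehot.shape[0]

    @property
    def n_classes(self) -> int:
        return self.onehot.shape[1]

    def same_label_matrix(self) -> np.ndarray:
        """N×N boolean indicator I(ℓ_i, ℓ_j)."""
        return self.class_index[:, None] == self.class_index[None, :]


@dataclass
class MultiManifoldSimilarity:
    """M×M grid of N×N similarity blocks plus its assembled MN×MN matrix."""

    blocks: list  # blocks[m][n] is an N×N ndarray
    tau: float

    @property
    def n_modalities(self) -> int:
        return len(self.blocks)

    @property
    def matrix(self) -> np.ndarray:
        return np.block(self.blocks)


# ---------------------------------------------------------------------------
# Scalar operations
# ---------------------------------------------------------------------------

def euclidean_distance(a, b) -> float:
    """ℓ2 distance between two code vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise DimensionError(f"vector length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def modified_distance(a, b, same_label: bool) -> float:
    """Label-aware distance in [0, 1) / (0, 1] built from the Euclidean one."""
    d = euclidean_distance(a, b)
    if same_label:
        return float(np.sqrt(1.0 - np.exp(-d)))
    return float(np.sqrt(np.exp(-d)))


def heterogeneous_pair_similarity(a, b, same_label: bool, tau: float = 1.0) -> float:
    """Heat-kernel similarity exp(-D²/τ) of the modified distance."""
    if tau <= 0:
        raise ParameterError(f"heat kernel constant tau must be positive, got {tau}")
    big_d = modified_distance(a, b, same_label)
    return float(np.exp(-(big_d**2) / tau))


# ---------------------------------------------------------------------------
# Differentiable matrix kernels (ndarray or Tensor)
# ---------------------------------------------------------------------------

def _pairwise_euclidean(A, B):
    """All-pairs ℓ2 distances between rows of A (N×K) and B (N'×K)."""
    a2 = ad.tsum(A * A, axis=1, keepdims=True)  # N×1
    b2 = ad.tsum(B * B, axis=1, keepdims=True)  # N'×1
    cross = ad.matmul(A, B.T)
    sq = a2 + b2.T - 2.0 * cross
    if isinstance(sq, ad.Tensor):
        # clamp tiny negatives from cancellation, keep gradient of sqrt finite
        return ad.sqrt(ad.relu(sq) + _SQRT_EPS)
    return np.sqrt(np.maximum(sq, 0.0))


def heterogeneous_block(A, B, same_mask: np.ndarray, tau: float,
                        swap_distance_branches: bool = False):
    """N×N' heterogeneous similarity between code rows of two modalities.

    ``same_mask[i, j]`` flags label agreement.  D² is expanded analytically
    (D² = 1 - e^(-d) or e^(-d)), so no extra square root enters the graph.
    With ``swap_distance_branches`` the two branch assignments are exchanged
    (an experimentation flag; the default follows the printed definition).
    """
    if tau <= 0:
        raise ParameterError(f"heat kernel constant tau must be positive, got {tau}")
    d = _pairwise_euclidean(A, B)
    e = ad.exp(-d)
    same_sq, diff_sq = 1.0 - e, e
    if swap_distance_branches:
        same_sq, diff_sq = diff_sq, same_sq
    mask = same_mask.astype(np.float64)
    d_sq = same_sq * mask + diff_sq * (1.0 - mask)
    return ad.exp(-d_sq / tau)


def homogeneous_block(A):
    """Cosine similarity between all row pairs of one modality's codes."""
    sq_norms = ad.tsum(A * A, axis=1, keepdims=True)
    data = sq_norms.data if isinstance(sq_norms, ad.Tensor) else sq_norms
    if np.any(data <= 0.0):
        raise DegenerateInputError("cosine similarity undefined for all-zero code row")
    normed = A / ad.sqrt(sq_norms)
    return ad.matmul(normed, normed.T)


def assemble_multi_manifold(code_rows: list, same_mask: np.ndarray, tau: float,
                            swap_distance_branches: bool = False):
    """Assemble the MN×MN multi-manifold similarity from per-modality rows.

    ``code_rows`` holds M arrays/Tensors of shape N×K; returns the assembled
    matrix (Tensor if any input is a Tensor).
    """
    m_mod = len(code_rows)
    rows = []
    for m in range(m_mod):
        cols = []
        for n in range(m_mod):
            if m == n:
                cols.append(homogeneous_block(code_rows[m]))
            else:
                cols.append(heterogeneous_block(code_rows[m], code_rows[n], same_mask,
                                                tau, swap_distance_branches))
        rows.append(ad.concatenate(cols, axis=1))
    return ad.concatenate(rows, axis=0)


# ---------------------------------------------------------------------------
# Public matrix operations on the domain types
# ---------------------------------------------------------------------------

def _check_codes_labels(codes: CodeMatrix, labels: LabelSet) -> None:
    if codes.n_samples != labels.n_samples:
        raise DimensionError(
            f"codes have {codes.n_samples} rows but labels have {labels.n_samples}")


def heterogeneous_similarity_matrix(codes_m: CodeMatrix, codes_n: CodeMatrix,
                                    labels: LabelSet, tau: float = 1.0,
                                    swap_distance_branches: bool = False) -> np.ndarray:
    """Heterogeneous similarity S_H between two modalities' codes (strong
    pairing: sample i carries the same label in every modality)."""
    if codes_m.modality_index == codes_n.modality_index:
        raise ParameterError("heterogeneous similarity requires two distinct modalities")
    if codes_m.values.shape != codes_n.values.shape:
        raise DimensionError("code matrices must share N and K across modalities")
    _check_codes_labels(codes_m, labels)
    return heterogeneous_block(codes_m.values, codes_n.values,
                               labels.same_label_matrix(), tau, swap_distance_branches)


def homogeneous_similarity_matrix(codes: CodeMatrix) -> np.ndarray:
    """Within-modality cosine similarity S_I (symmetric, unit diagonal)."""
    return homogeneous_block(codes.values)


def multi_manifold_similarity(codes_per_modality: list[CodeMatrix], labels: LabelSet,
                              tau: float = 1.0,
                              swap_distance_branches: bool = False) -> MultiManifoldSimilarity:
    """Assemble S_M: homogeneous blocks on the diagonal, heterogeneous blocks
    off it, in modality-major order."""
    if not codes_per_modality:
        raise DimensionError("need at least one modality")
    shapes = {c.values.shape for c in codes_per_modality}
    if len(shapes) != 1:
        raise DimensionError(f"all modalities must share N and K, got shapes {shapes}")
    for c in codes_per_modality:
        _check_codes_labels(c, labels)
    mask = labels.same_label_matrix()
    m_mod = len(codes_per_modality)
    blocks = [[None] * m_mod for _ in range(m_mod)]
    for m in range(m_mod):
        for n in range(m_mod):
            if m == n:
                blocks[m][n] = homogeneous_block(codes_per_modality[m].values)
            else:
                blocks[m][n] = heterogeneous_block(
                    codes_per_modality[m].values, codes_per_modality[n].values,
                    mask, tau, swap_distance_branches)
    return MultiManifoldSimilarity(blocks=blocks, tau=tau)
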