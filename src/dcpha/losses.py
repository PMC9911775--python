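"""Training objectives for consistency-preserving hash learning.

Three ingredients make up the total objective:

* **Multi-semantic consistency** ``J1``: every modality's encoder-stage
  prediction y, decoder-stage prediction r and one-hot label ℓ are pulled
  together through the three Euclidean norms ‖y−ℓ‖ + ‖r−ℓ‖ + ‖y−r‖.
* **Multi-manifold similarity preservation** ``J2``: a logistic
  likelihood-style term log(1+e^s) − I·s over every entry s of the
  multi-manifold similarity, with I the same-label indicator.  When
  log(1+e^s) = 2s (s = ln((1+√5)/2)), the term coincides with a Laplacian
  eigenmaps embedding objective, for which
  :func:`laplacian_embedding_loss` is provided as a numerical probe.
* **Quantization regularizer**: an ℓ1 pull of relaxed codes toward valid
  binary values.  The ``literal`` variant measures distance to the all-ones
  vector ‖h−1‖₁ (as the objective prints, including its 2·M·N pair
  multiplicity); the ``magnitude`` variant measures ‖|h|−1‖₁, the common
  quantization loss that treats −1 and +1 symmetrically.

All loss kernels accept relaxed codes either as ``ndarray`` (plain
evaluation) or as autodiff ``Tensor`` (training), and support ``sum``
(as the equations print) or ``mean`` reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import autodiff as ad
from .exceptions import DegenerateInputError, DimensionError, ParameterError
from .similarity import CodeMatrix, LabelSet, assemble_multi_manifold

_NORM_EPS = 1e-12


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PredictionSet:
    """Class predictions of the two attention branches: encoder-stage y and
    decoder-stage r, each M×N×C rows of probabilities."""

    y: np.ndarray
    r: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.float64)
        self.r = np.asarray(self.r, dtype=np.float64)
        if self.y.shape != self.r.shape or self.y.ndim != 3:
            raise DimensionError("y and r must both have shape (M, N, C)")
        for name, p in (("y", self.y), ("r", self.r)):
            if p.size and (p.min() < -1e-9 or p.max() > 1 + 1e-9):
                raise ParameterError(f"{name} entries must lie in [0, 1]")
            if p.size and not np.allclose(p.sum(axis=-1), 1.0, atol=1e-5):
                raise ParameterError(f"each {name} row must sum to 1 (softmax output)")


@dataclass
class LossWeights:
    """Contribution weights α (semantic consistency) and β (manifold
    preservation).  α = 0 gives the DPHA ablation, β = 0 the DCHA one."""

    alpha: float = 0.3
    beta: float = 1.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ParameterError("loss weights must be non-negative")


# ---------------------------------------------------------------------------
# Kernels (ndarray or Tensor input)
# ---------------------------------------------------------------------------

def _row_norms(x, axis: int = -1):
    """Euclidean norm along ``axis``; ε-guarded on the differentiable path."""
    sq = ad.tsum(x * x, axis=axis)
    if isinstance(sq, ad.Tensor):
        return ad.sqrt(sq + _NORM_EPS)
    return np.sqrt(sq)


def semantic_consistency_kernel(y, r, onehot, reduction: str = "sum"):
    """J1 over M×N×C prediction stacks against N×C one-hot labels."""
    lab = onehot.astype(np.float64)[None, :, :]  # broadcast over modalities
    total = ad.tsum(_row_norms(y - lab)) + ad.tsum(_row_norms(r - lab)) \
        + ad.tsum(_row_norms(y - r))
    if reduction == "mean":
        m_mod, n = (y.shape[0], y.shape[1])
        return total / float(m_mod * n)
    return total


def manifold_pair_term(s: float, same_label: bool) -> float:
    """One summand of J2: log(1+e^s) − I·s for a single similarity value."""
    return float(np.log1p(np.exp(s)) - (1.0 if same_label else 0.0) * s)


def manifold_preserving_kernel(code_rows, same_mask: np.ndarray, tau: float = 1.0,
                               reduction: str = "sum",
                               include_self_pairs: bool = True,
                               swap_distance_branches: bool = False):
    """J2 = Σ log(1+e^s) − I·s over every entry of the assembled similarity.

    ``code_rows``: M arrays/Tensors of shape N×K.  ``same_mask``: the N×N
    same-label indicator, tiled M×M to cover the assembled matrix.
    """
    m_mod = len(code_rows)
    n = same_mask.shape[0]
    s = assemble_multi_manifold(code_rows, same_mask, tau, swap_distance_branches)
    big_i = np.tile(same_mask.astype(np.float64), (m_mod, m_mod))
    per_pair = ad.log(1.0 + ad.exp(s)) - s * big_i
    weight = np.ones((m_mod * n, m_mod * n))
    if not include_self_pairs:
        np.fill_diagonal(weight, 0.0)
    total = ad.tsum(per_pair * weight)
    if reduction == "mean":
        return total / float((m_mod * n) ** 2)
    return total


def quantization_kernel(code_rows, variant: str = "literal", reduction: str = "sum",
                        count_multiplicity: bool = True):
    """ℓ1 quantization regularizer over M stacks of N×K relaxed codes.

    With ``count_multiplicity`` the printed pair summation is honored: each
    code's term appears 2·M·N times.  ``variant='magnitude'`` replaces
    ‖h−1‖₁ by ‖|h|−1‖₁.
    """
    if variant not in ("literal", "magnitude"):
        raise ParameterError(f"unknown quantization variant {variant!r}")
    m_mod = len(code_rows)
    n = code_rows[0].shape[0]
    total = 0.0
    for rows in code_rows:
        inner = ad.absolute(rows) if variant == "magnitude" else rows
        total = total + ad.tsum(ad.absolute(inner - 1.0))
    if count_multiplicity:
        total = total * float(2 * m_mod * n)
    if reduction == "mean":
        # average over every scalar summand, bit terms included, so the
        # regularizer's weight does not grow with the code length
        k = code_rows[0].shape[1]
        return total / float(2 * (m_mod * n) ** 2 * k)
    return total


# ---------------------------------------------------------------------------
# Public operations on domain types
# ---------------------------------------------------------------------------

def _code_rows(codes_per_modality: list[CodeMatrix]):
    if not codes_per_modality:
        raise DimensionError("need at least one modality")
    return [c.values for c in codes_per_modality]


def semantic_consistency_loss(preds: PredictionSet, labels: LabelSet,
                              reduction: str = "sum") -> float:
    """Multi-semantic consistency loss J1 (zero iff every prediction equals
    its one-hot label exactly)."""
    m_mod, n, c = preds.y.shape
    if n != labels.n_samples or c != labels.n_classes:
        raise DimensionError(
            f"predictions (N={n}, C={c}) do not match labels "
            f"(N={labels.n_samples}, C={labels.n_classes})")
    return float(semantic_consistency_kernel(preds.y, preds.r, labels.onehot, reduction))


def manifold_preserving_loss(codes_per_modality: list[CodeMatrix], labels: LabelSet,
                             tau: float = 1.0, reduction: str = "sum",
                             include_self_pairs: bool = True,
                             swap_distance_branches: bool = False) -> float:
    """Multi-manifold similarity-preserving loss J2."""
    rows = _code_rows(codes_per_modality)
    for c in codes_per_modality:
        if c.n_samples != labels.n_samples:
            raise DimensionError("codes and labels disagree on N")
    return float(manifold_preserving_kernel(
        rows, labels.same_label_matrix(), tau, reduction,
        include_self_pairs, swap_distance_branches))


def laplacian_embedding_loss(codes_per_modality: list[CodeMatrix],
                             similarity: np.ndarray) -> float:
    """Laplacian eigenmaps objective Σ ½·S_ij·‖H_i − H_j‖² over all ordered
    pairs of row-normalized codes H = h/‖h‖, stacked modality-major."""
    rows = np.concatenate(_code_rows(codes_per_modality), axis=0)
    similarity = np.asarray(similarity, dtype=np.float64)
    if similarity.shape != (rows.shape[0], rows.shape[0]):
        raise DimensionError(
            f"similarity must be {rows.shape[0]}×{rows.shape[0]}, got {similarity.shape}")
    norms = np.linalg.norm(rows, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        raise DegenerateInputError("cannot normalize an all-zero code row")
    h = rows / norms
    sq_dists = np.maximum(2.0 - 2.0 * (h @ h.T), 0.0)  # unit rows
    return float(0.5 * np.sum(similarity * sq_dists))


def quantization_regularizer(codes_per_modality: list[CodeMatrix],
                             variant: str = "literal", reduction: str = "sum",
                             count_multiplicity: bool = True) -> float:
    """ℓ1 quantization regularizer (third term of the total objective)."""
    return float(quantization_kernel(_code_rows(codes_per_modality), variant,
                                     reduction, count_multiplicity))


def total_objective(preds: PredictionSet, codes_per_modality: list[CodeMatrix],
                    labels: LabelSet, tau: float = 1.0,
                    weights: LossWeights | None = None, reduction: str = "sum",
                    include_self_pairs: bool = True,
                    swap_distance_branches: bool = False,
                    quantization_variant: str = "literal",
                    count_multiplicity: bool = True) -> float:
    """Total objective α·J1 + β·J2 + quantization regularizer.

    α = 0 reduces to the DPHA variant, β = 0 to DCHA (each keeps the
    regularizer).  Component terms with zero weight are skipped entirely so
    the ablations dispatch to exactly the reduced objectives.
    """
    weights = weights or LossWeights()
    total = 0.0
    if weights.alpha != 0.0:
        total += weights.alpha * semantic_consistency_loss(preds, labels, reduction)
    if weights.beta != 0.0:
        total += weights.beta * manifold_preserving_loss(
            codes_per_modality, labels, tau, reduction,
            include_self_pairs, swap_distance_branches)
    total += quantization_regularizer(codes_per_modality, quantization_variant,
                                      reduction, count_multiplicity)
    return float(total)


def manifold_preserving_fixed_point() -> float:
    """Numerically solve log(1+e^s) = 2s — the similarity value at which the
    per-pair J2 term matches the Laplacian embedding objective.  The root is
    ln of the golden ratio."""
    return float(brentq(lambda s: np.log1p(np.exp(s)) - 2.0 * s, 1e-9, 10.0,
                        xtol=1e-14, rtol=8.9e-16))
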