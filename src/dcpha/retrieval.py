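"""Cross-modal retrieval evaluation in Hamming space.

Queries from one modality rank the opposite modality's gallery by cosine
similarity of hash codes (for ±1 codes of equal length this ordering is
identical to ascending Hamming distance, since cos = (K − 2·Ham)/K).
Relevance is same-class membership; the headline metric is mean average
precision over *all* returned results, reported for both directions
(e.g. MRI→PET and PET→MRI) together with their arithmetic mean and
precision@k curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ContractError, DataError, DimensionError
from .model import DCPHAModel, binarize, forward_batch
from .similarity import CodeMatrix, LabelSet

logger = logging.getLogger("dcpha")


@dataclass
class RetrievalReport:
    """Per-direction mAP and precision@k plus the two-direction average."""

    tasks: dict = field(default_factory=dict)  # name -> {"map": float, "precision_curve": ndarray}
    average: float = 0.0

    def map_score(self, task: str) -> float:
        return self.tasks[task]["map"]


def _as_code_array(codes, require_binary: bool) -> np.ndarray:
    arr = codes.values if isinstance(codes, CodeMatrix) else np.asarray(codes, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[None, :]
    if require_binary and not np.all(np.isin(arr, (-1.0, 1.0))):
        raise ContractError("retrieval is defined on binarized (±1) codes; "
                            "pass require_binary=False for the relaxed variant")
    return arr


def _labels_array(labels) -> np.ndarray:
    if isinstance(labels, LabelSet):
        return labels.class_index
    return np.asarray(labels, dtype=int)


def _similarity(queries: np.ndarray, gallery: np.ndarray, metric: str) -> np.ndarray:
    """Q×G score matrix; larger is more similar under both metrics."""
    if queries.shape[1] != gallery.shape[1]:
        raise DimensionError("query and gallery codes must share K")
    if metric == "cosine":
        # dot first, normalize after: for ±1 codes the dot is exact, so
        # single-query and batched rankings tie-break identically
        dots = queries @ gallery.T
        qn = np.linalg.norm(queries, axis=1)[:, None]
        gn = np.linalg.norm(gallery, axis=1)[None, :]
        return dots / (qn * gn)
    if metric == "hamming":
        # negative Hamming distance, so bigger = closer
        k = queries.shape[1]
        return -(k - queries @ gallery.T) / 2.0
    raise ContractError(f"unknown metric {metric!r}")


def rank_gallery(query, gallery, metric: str = "cosine",
                 require_binary: bool = True) -> np.ndarray:
    """Gallery indices sorted by decreasing similarity to ``query``; ties
    break by ascending index (stable sort)."""
    q = _as_code_array(query, require_binary)
    g = _as_code_array(gallery, require_binary)
    sims = _similarity(q, g, metric)[0]
    return np.argsort(-sims, kind="stable")


def average_precision(ranked_relevance) -> float:
    """AP of one ranked binary relevance list over all returned results."""
    rel = np.asarray(ranked_relevance, dtype=np.float64)
    if rel.size == 0:
        raise DataError("cannot compute AP of an empty ranking")
    n_rel = rel.sum()
    if n_rel == 0:
        logger.warning("query with no relevant gallery item scores AP = 0")
        return 0.0
    ranks = np.arange(1, rel.size + 1)
    precision_at = np.cumsum(rel) / ranks
    return float((precision_at * rel).sum() / n_rel)


def _ranked_relevance(query_codes, query_labels, gallery_codes, gallery_labels,
                      metric: str, require_binary: bool) -> np.ndarray:
    q = _as_code_array(query_codes, require_binary)
    g = _as_code_array(gallery_codes, require_binary)
    ql = _labels_array(query_labels)
    gl = _labels_array(gallery_labels)
    if q.shape[0] != ql.size or g.shape[0] != gl.size:
        raise DimensionError("codes and labels disagree on sample counts")
    sims = _similarity(q, g, metric)
    order = np.argsort(-sims, axis=1, kind="stable")
    return (gl[order] == ql[:, None]).astype(np.float64)


def mean_average_precision(query_codes, query_labels, gallery_codes, gallery_labels,
                           metric: str = "cosine", require_binary: bool = True,
                           map_at: int | None = None) -> float:
    """Mean over queries of AP, relevance = same class label.  ``map_at``
    truncates rankings at a cutoff; the default uses all returned results."""
    rel = _ranked_relevance(query_codes, query_labels, gallery_codes,
                            gallery_labels, metric, require_binary)
    if map_at is not None:
        rel = rel[:, :map_at]
    ranks = np.arange(1, rel.shape[1] + 1)
    prec = np.cumsum(rel, axis=1) / ranks
    n_rel = rel.sum(axis=1)
    if np.any(n_rel == 0):
        logger.warning("%d queries have no relevant gallery item (AP = 0)",
                       int((n_rel == 0).sum()))
    ap = np.where(n_rel > 0, (prec * rel).sum(axis=1) / np.maximum(n_rel, 1.0), 0.0)
    return float(ap.mean())


def precision_at_k_curve(query_codes, query_labels, gallery_codes, gallery_labels,
                         metric: str = "cosine", require_binary: bool = True) -> np.ndarray:
    """precision@k averaged over queries for k = 1..gallery size."""
    rel = _ranked_relevance(query_codes, query_labels, gallery_codes,
                            gallery_labels, metric, require_binary)
    ranks = np.arange(1, rel.shape[1] + 1)
    return (np.cumsum(rel, axis=1) / ranks).mean(axis=0)


def cross_modal_eval(model: DCPHAModel, test_split, metric: str = "cosine",
                     binarize_codes: bool = True) -> RetrievalReport:
    """Encode the test split, binarize, and evaluate every ordered pair of
    modalities; the report's average is the mean of the directional mAPs."""
    out = forward_batch(model, test_split.samples)
    codes = out.relaxed_codes
    if binarize_codes:
        codes = binarize(codes)
    labels = test_split.labels
    m_mod = codes.shape[0]
    if m_mod < 2:
        raise DataError("cross-modal evaluation needs at least two modalities")
    report = RetrievalReport()
    maps = []
    for mq in range(m_mod):
        for mg in range(m_mod):
            if mq == mg:
                continue
            name = f"{mq}->{mg}"
            score = mean_average_precision(codes[mq], labels, codes[mg], labels,
                                           metric, require_binary=binarize_codes)
            curve = precision_at_k_curve(codes[mq], labels, codes[mg], labels,
                                         metric, require_binary=binarize_codes)
            report.tasks[name] = {"map": score, "precision_curve": curve}
            maps.append(score)
    report.average = float(np.mean(maps))
    return report
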