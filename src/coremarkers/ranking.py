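"""Per-gene ROC-AUC scoring and top-Q selection.

For a single gene the area under the ROC curve equals the Mann-Whitney
probability that a randomly chosen responder expresses the gene higher than
a randomly chosen non-responder, with tied pairs credited 0.5. Genes are
scored by the *oriented* AUC, max(AUC, 1 - AUC), so markers down-regulated
in responders rank symmetrically with up-regulated ones, and sorted by
(oriented AUC descending, gene id ascending) — a total, deterministic order
that makes top-Q sets and their intersections reproducible.

The conventional 0.7 threshold for a "high-quality" biomarker is reported as
an annotation flag on each score; it is never used as a filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .dataset import ExpressionDataset
from .errors import DataError, EmptyClassError
from .response import BinaryLabels

__all__ = [
    "HIGH_QUALITY_AUC",
    "GeneScore",
    "RankedGenes",
    "gene_auc",
    "rank_genes",
    "top_q",
    "TopQAUCSelector",
]

HIGH_QUALITY_AUC = 0.7  # conventional biomarker-quality annotation threshold


@dataclass(frozen=True)
class GeneScore:
    """ROC-AUC score of one gene for the R-vs-NR contrast."""

    gene_id: str
    auc: float
    oriented_auc: float
    direction: str  # up_in_R | down_in_R | flat

    @property
    def high_quality(self) -> bool:
        """Conventional annotation: oriented AUC above 0.7."""
        return self.oriented_auc > HIGH_QUALITY_AUC


@dataclass
class RankedGenes:
    """All gene scores in the deterministic selection order."""

    scores: list[GeneScore]

    @property
    def gene_ids(self) -> list[str]:
        return [s.gene_id for s in self.scores]


def gene_auc(values_r: Sequence[float], values_nr: Sequence[float]) -> float:
    """Mann-Whitney AUC of one gene: P(R > NR) + 0.5 P(R == NR).

    Computed from midranks of the pooled values:
    AUC = (ranksum_R - n_R (n_R + 1) / 2) / (n_R n_NR).
    """
    r = np.asarray(values_r, dtype=float)
    nr = np.asarray(values_nr, dtype=float)
    if r.size == 0 or nr.size == 0:
        raise EmptyClassError("gene_auc requires non-empty R and NR value lists")
    if not (np.isfinite(r).all() and np.isfinite(nr).all()):
        raise DataError("gene_auc requires finite values")
    ranks = rankdata(np.concatenate([r, nr]))
    u = ranks[: r.size].sum() - r.size * (r.size + 1) / 2
    return float(u / (r.size * nr.size))


def auc_numerators(values: np.ndarray, r_mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Mann-Whitney numerator U per row of a genes-by-samples matrix.

    U counts (R, NR) pairs won by R plus half the ties; it is a half-integer,
    exact in floating point, which lets callers orient AUC symmetrically as
    max(U, denom - U) / denom without rounding asymmetry. Returns (U, denom)
    with denom = n_R * n_NR.
    """
    n_r = int(r_mask.sum())
    n_nr = int(values.shape[1] - n_r)
    if n_r == 0 or n_nr == 0:
        raise EmptyClassError("both R and NR classes must be present")
    ranks = rankdata(values, axis=1)
    u = ranks[:, r_mask].sum(axis=1) - n_r * (n_r + 1) / 2
    return u, n_r * n_nr


def auc_per_gene(values: np.ndarray, r_mask: np.ndarray) -> np.ndarray:
    """Vectorized AUC for every row of a genes-by-samples matrix.

    ``r_mask`` flags responder columns. Constant genes come out at exactly
    0.5 (all pairs tie).
    """
    u, denom = auc_numerators(values, r_mask)
    return u / denom


def oriented_from_numerator(u: np.ndarray, denom) -> np.ndarray:
    """Oriented AUC max(U, denom - U) / denom, exactly class-symmetric."""
    return np.maximum(u, denom - u) / denom


def _direction(auc: np.ndarray) -> np.ndarray:
    out = np.where(auc > 0.5, "up_in_R", "down_in_R")
    out[auc == 0.5] = "flat"
    return out


def selection_order(oriented_auc: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices sorting by (oriented AUC desc, gene id asc); total and stable."""
    return np.lexsort((np.asarray(gene_ids, dtype=str), -np.asarray(oriented_auc)))


def _align_labels(dataset: ExpressionDataset, labels: BinaryLabels) -> np.ndarray:
    """Responder mask in dataset column order; ids must match as sets."""
    ds, lb = set(dataset.sample_ids), set(labels.sample_ids)
    if ds != lb:
        diff = sorted(ds.symmetric_difference(lb))
        raise DataError(
            "sample ids of expression matrix and labels differ; "
            f"symmetric difference: {diff[:10]}{'...' if len(diff) > 10 else ''}"
        )
    lab = labels.to_series().reindex(dataset.sample_ids).to_numpy()
    return lab == "R"


def rank_genes(dataset: ExpressionDataset, labels: BinaryLabels) -> RankedGenes:
    """Score every gene by responder-vs-non-responder AUC and sort.

    One :class:`GeneScore` per gene, ordered by (oriented AUC descending,
    gene id ascending).
    """
    r_mask = _align_labels(dataset, labels)
    u, denom = auc_numerators(dataset.values, r_mask)
    auc = u / denom
    oriented = oriented_from_numerator(u, denom)
    direction = _direction(auc)
    order = selection_order(oriented, dataset.gene_ids)
    scores = [
        GeneScore(dataset.gene_ids[i], float(auc[i]), float(oriented[i]), str(direction[i]))
        for i in order
    ]
    return RankedGenes(scores)


def top_q(ranked: RankedGenes, q: int) -> set[str]:
    """The first min(Q, G) gene ids of the deterministic ranking."""
    if q < 1:
        raise DataError(f"Q must be >= 1, got {q}")
    return set(ranked.gene_ids[: min(q, len(ranked.scores))])


class TopQAUCSelector(SelectorMixin, BaseEstimator):
    """Select the top-Q genes by oriented responder-vs-non-responder AUC.

    A scikit-learn feature selector over a samples-by-genes matrix ``X`` and
    binary labels ``y``. The positive (responder) class is the
    lexicographically larger of the two label values (so "R" beats "NR" and
    1 beats 0); orientation makes the selected set independent of that
    choice.

    Parameters
    ----------
    q : int, default 30
        Number of genes to keep.

    Attributes
    ----------
    auc_ : ndarray of shape (n_features,)
        Raw AUC of each gene (positive class on top).
    oriented_auc_ : ndarray of shape (n_features,)
        max(auc_, 1 - auc_), the selection score.
    direction_ : ndarray of str
        up_in_R / down_in_R / flat per gene.
    high_quality_ : ndarray of bool
        Conventional oriented-AUC > 0.7 annotation.
    """

    def __init__(self, q: int = 30):
        self.q = q

    def fit(self, X, y) -> "TopQAUCSelector":
        X = validate_data(self, X, ensure_min_samples=2)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise DataError("X and y have different numbers of samples")
        classes = np.unique(y)
        if classes.size != 2:
            raise EmptyClassError(
                f"need exactly two classes, got {classes.size}: {classes[:5]}"
            )
        if self.q < 1:
            raise DataError(f"q must be >= 1, got {self.q}")
        self.classes_ = classes
        r_mask = y == classes[1]
        u, denom = auc_numerators(X.T, r_mask)
        self.auc_ = u / denom
        self.oriented_auc_ = oriented_from_numerator(u, denom)
        self.direction_ = _direction(self.auc_)
        self.high_quality_ = self.oriented_auc_ > HIGH_QUALITY_AUC
        names = self._tiebreak_names(X.shape[1])
        keep = selection_order(self.oriented_auc_, names)[: min(self.q, X.shape[1])]
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[keep] = True
        self.support_mask_ = mask
        return self

    def _tiebreak_names(self, n_features: int) -> np.ndarray:
        if hasattr(self, "feature_names_in_"):
            return np.asarray(self.feature_names_in_, dtype=str)
        width = max(4, len(str(n_features)))
        return np.array([f"g{i + 1:0{width}d}" for i in range(n_features)])

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_mask_")
        return self.support_mask_
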