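"""Binarization of clinical response annotations and of event-free survival.

Training a binary responder/non-responder classifier requires collapsing the
multi-level clinical response groups found in public cohorts into exactly two
classes. Four named category rules cover the dataset families in the packaged
catalog:

``breast_cr_pr``
    complete + partial response -> R; residual + progressive disease -> NR
    (all breast-cancer cohorts).
``stable_as_responder``
    complete + partial response + stable disease -> R; progressive disease
    -> NR (TCGA cohorts and the tipifarnib AML cohort).
``myeloma_gse9782``
    complete + partial response -> R; no change + progressive disease -> NR.
``myeloma_vgpr``
    complete, near-complete and very good partial response -> R; partial,
    minor and worse -> NR (the remaining myeloma cohorts).

Pediatric TARGET cohorts carry no response categories, only event-free
survival (EFS) times whose distribution is bimodal: a short-survival mode
(relapse/progression) and a long-survival mode. ``fit_survival_split`` fits a
two-component Gaussian mixture to log EFS time and places the responder
threshold at the equal-posterior point between the two modes; samples left of
the threshold are non-responders, samples at or right of it responders.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .errors import DataError, UnimodalSurvivalError

__all__ = [
    "ResponseRule",
    "RESPONSE_RULES",
    "BinaryLabels",
    "SurvivalSeries",
    "SurvivalThreshold",
    "SurvivalBinarizer",
    "canonicalize_category",
    "binarize_response",
    "fit_survival_split",
    "labels_from_survival",
]

_WS = re.compile(r"\s+")


def canonicalize_category(category: str) -> str:
    """Lowercase, trim, and collapse whitespace/hyphen runs to single spaces.

    Public cohorts spell the same group inconsistently ("near-complete",
    "Near complete response"); canonical forms make rule lookup total.
    """
    return _WS.sub(" ", str(category).lower().replace("-", " ")).strip()


@dataclass(frozen=True)
class ResponseRule:
    """A named mapping from clinical response categories to R/NR."""

    rule_id: str
    responder_classes: frozenset[str]
    nonresponder_classes: frozenset[str]

    def __post_init__(self) -> None:
        if self.rule_id != "target_survival":
            if not self.responder_classes or not self.nonresponder_classes:
                raise DataError(f"rule '{self.rule_id}': both class sets must be non-empty")
            overlap = self.responder_classes & self.nonresponder_classes
            if overlap:
                raise DataError(
                    f"rule '{self.rule_id}': categories in both classes: {sorted(overlap)}"
                )


def _rule(rule_id: str, responders: Iterable[str], nonresponders: Iterable[str]) -> ResponseRule:
    return ResponseRule(
        rule_id,
        frozenset(canonicalize_category(c) for c in responders),
        frozenset(canonicalize_category(c) for c in nonresponders),
    )


RESPONSE_RULES: dict[str, ResponseRule] = {
    "breast_cr_pr": _rule(
        "breast_cr_pr",
        ["complete response", "partial response"],
        ["residual disease", "progressive disease"],
    ),
    "stable_as_responder": _rule(
        "stable_as_responder",
        ["complete response", "partial response", "stable disease"],
        ["progressive disease"],
    ),
    "myeloma_gse9782": _rule(
        "myeloma_gse9782",
        ["complete response", "partial response"],
        ["no change", "progressive disease"],
    ),
    "myeloma_vgpr": _rule(
        "myeloma_vgpr",
        [
            "complete",
            "complete response",
            "near complete",
            "near complete response",
            "very good partial",
            "very good partial response",
        ],
        ["partial", "partial response", "minor", "minor response", "worse"],
    ),
    # Sentinel: TARGET cohorts are split by the survival threshold, not by
    # category sets.
    "target_survival": ResponseRule("target_survival", frozenset(), frozenset()),
}


@dataclass
class BinaryLabels:
    """Per-sample responder (R) / non-responder (NR) assignment.

    ``provenance`` records how the labels arose: a rule id, or the survival
    threshold in days.
    """

    sample_ids: np.ndarray
    labels: np.ndarray
    provenance: str | float = "unspecified"

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.labels = np.asarray(self.labels, dtype=str)
        if self.sample_ids.size != self.labels.size:
            raise DataError("sample_ids and labels differ in length")
        if self.sample_ids.size == 0:
            raise DataError("empty label set")
        if np.unique(self.sample_ids).size != self.sample_ids.size:
            raise DataError("duplicate sample ids in labels")
        bad = set(np.unique(self.labels)) - {"R", "NR"}
        if bad:
            raise DataError(f"labels must be 'R' or 'NR', got {sorted(bad)}")

    @property
    def n_responders(self) -> int:
        return int((self.labels == "R").sum())

    @property
    def n_nonresponders(self) -> int:
        return int((self.labels == "NR").sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="response")


@dataclass
class SurvivalSeries:
    """Event-free survival times in days, one per sample.

    ``true_component`` is populated only by the synthetic generator (0 = low
    mode, 1 = high mode) and exists for recovery testing; real cohorts carry
    None.
    """

    sample_ids: np.ndarray
    efs_time: np.ndarray
    true_component: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.efs_time = np.asarray(self.efs_time, dtype=float)
        if self.sample_ids.size != self.efs_time.size:
            raise DataError("sample_ids and efs_time differ in length")
        if np.unique(self.sample_ids).size != self.sample_ids.size:
            raise DataError("duplicate sample ids in survival series")
        if not np.isfinite(self.efs_time).all() or (self.efs_time <= 0).any():
            raise DataError("survival times must be positive and finite")


@dataclass(frozen=True)
class SurvivalThreshold:
    """A fitted responder threshold on event-free survival time.

    ``mode_locations`` are the component medians in days (exp of the log-scale
    means); ``separation`` is |mu2 - mu1| / pooled sigma on the log scale.
    """

    threshold: float
    mode_locations: tuple[float, float]
    separation: float

    def __post_init__(self) -> None:
        low, high = self.mode_locations
        if not (low < self.threshold < high):
            raise DataError(
                f"threshold {self.threshold:.1f} d not between mode locations "
                f"({low:.1f}, {high:.1f})"
            )


class SurvivalBinarizer(BaseEstimator):
    """Two-mode mixture split of event-free survival times.

    Fits a two-component Gaussian mixture to log survival time and derives the
    responder threshold as the equal-posterior point between the component
    means. A split is only declared defensible when (a) the Bayesian
    information criterion prefers two components over one, and (b) the
    component separation |mu2 - mu1| / pooled sigma is at least
    ``min_separation``; otherwise fitting raises
    :class:`~coremarkers.errors.UnimodalSurvivalError`.

    Parameters
    ----------
    min_separation : float, default 1.0
        Minimum separation, in pooled-standard-deviation units on the log
        scale, required to declare bimodality.
    min_samples : int, default 40
        Minimum cohort size; below this a mixture fit is not attempted.
    random_state : int, default 0
        Seed for the fixed random restarts of the EM fit.

    Attributes
    ----------
    threshold_ : float
        Responder threshold in days; ``time >= threshold_`` labels R.
    mode_locations_ : tuple (low, high)
        Component medians in days.
    separation_ : float
        Fitted separation in pooled-sd units.
    weights_, log_means_, log_sigmas_ : ndarray
        Mixture parameters on the log-time scale, low mode first.
    """

    def __init__(self, min_separation: float = 1.0, min_samples: int = 40,
                 random_state: int = 0):
        self.min_separation = min_separation
        self.min_samples = min_samples
        self.random_state = random_state

    def fit(self, times, y=None) -> "SurvivalBinarizer":
        t = np.asarray(times, dtype=float).ravel()
        if t.size < self.min_samples:
            raise DataError(
                f"survival split needs >= {self.min_samples} samples, got {t.size}"
            )
        if not np.isfinite(t).all() or (t <= 0).any():
            raise DataError("survival times must be positive and finite")
        z = np.log(t).reshape(-1, 1)
        if np.ptp(z) == 0:
            raise UnimodalSurvivalError(
                "all survival times identical: no responder split is defensible"
            )
        # 10 EM starts: one at the 25%/75% quantiles of log time, nine random
        # restarts under a fixed seed; best log-likelihood wins.
        q25, q75 = np.quantile(z, [0.25, 0.75])
        fits = [
            GaussianMixture(
                2, means_init=[[q25], [q75]], random_state=self.random_state
            ).fit(z),
            GaussianMixture(
                2, n_init=9, init_params="random_from_data",
                random_state=self.random_state,
            ).fit(z),
        ]
        gm2 = max(fits, key=lambda g: g.score(z))
        gm1 = GaussianMixture(1).fit(z)
        order = np.argsort(gm2.means_.ravel())
        mu = gm2.means_.ravel()[order]
        sigma = np.sqrt(gm2.covariances_.ravel()[order])
        w = gm2.weights_.ravel()[order]
        pooled = float(np.sqrt(w @ sigma**2))
        separation = float((mu[1] - mu[0]) / pooled) if pooled > 0 else 0.0
        if gm1.bic(z) <= gm2.bic(z) or separation < self.min_separation:
            raise UnimodalSurvivalError(
                "unimodal: survival distribution shows no defensible two-mode "
                f"structure (separation {separation:.2f} pooled sd, "
                f"minimum {self.min_separation}); no responder split is possible"
            )
        self.weights_ = w
        self.log_means_ = mu
        self.log_sigmas_ = sigma
        self.separation_ = separation
        self.threshold_ = float(np.exp(self._equal_posterior_point()))
        self.mode_locations_ = (float(np.exp(mu[0])), float(np.exp(mu[1])))
        self.n_features_in_ = 1
        return self

    def _equal_posterior_point(self) -> float:
        """Log-time point between the means with equal component posteriors."""
        w, mu, sg = self.weights_, self.log_means_, self.log_sigmas_

        def logodds(x: float) -> float:
            return (np.log(w[0]) + norm.logpdf(x, mu[0], sg[0])
                    - np.log(w[1]) - norm.logpdf(x, mu[1], sg[1]))

        lo, hi = float(mu[0]), float(mu[1])
        if logodds(lo) > 0 and logodds(hi) < 0:
            return brentq(logodds, lo, hi)
        return 0.5 * (lo + hi)  # pathological weights; midpoint fallback

    def predict(self, times) -> np.ndarray:
        """Label each time: R at or above the threshold, NR below."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "threshold_")
        t = np.asarray(times, dtype=float).ravel()
        return np.where(t >= self.threshold_, "R", "NR")

    def threshold(self) -> SurvivalThreshold:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "threshold_")
        return SurvivalThreshold(self.threshold_, self.mode_locations_, self.separation_)


def _as_categories(raw) -> tuple[np.ndarray, np.ndarray]:
    """Accept a mapping/Series (ids from keys) or a sequence (ids synthesized)."""
    if isinstance(raw, Mapping):
        raw = pd.Series(raw)
    if isinstance(raw, pd.Series):
        return raw.index.to_numpy(dtype=str), raw.to_numpy(dtype=str)
    cats = np.asarray(list(raw), dtype=str)
    width = max(4, len(str(cats.size)))
    ids = np.array([f"s{i + 1:0{width}d}" for i in range(cats.size)])
    return ids, cats


def binarize_response(raw, rule: ResponseRule | str) -> BinaryLabels:
    """Collapse clinical response categories to binary R/NR labels.

    Parameters
    ----------
    raw : sequence, mapping, or pandas Series of category strings
        Per-sample clinical response annotations. A Series or mapping supplies
        sample ids; a plain sequence gets synthetic ids in order.
    rule : ResponseRule or rule id string
        Which category rule to apply. Every category (after canonicalization)
        must belong to exactly one of the rule's class sets.
    """
    if isinstance(rule, str):
        try:
            rule = RESPONSE_RULES[rule]
        except KeyError:
            raise DataError(
                f"unknown response rule '{rule}'; known: {sorted(RESPONSE_RULES)}"
            ) from None
    if rule.rule_id == "target_survival":
        raise DataError(
            "rule 'target_survival' carries no category sets; use "
            "fit_survival_split / labels_from_survival on the EFS times instead"
        )
    sample_ids, cats = _as_categories(raw)
    if cats.size == 0:
        raise DataError("no response categories supplied")
    labels = np.empty(cats.size, dtype="<U2")
    for i, cat in enumerate(cats):
        canon = canonicalize_category(cat)
        if canon in rule.responder_classes:
            labels[i] = "R"
        elif canon in rule.nonresponder_classes:
            labels[i] = "NR"
        else:
            raise DataError(
                f"category '{cat}' is not covered by rule '{rule.rule_id}'"
            )
    return BinaryLabels(sample_ids, labels, provenance=rule.rule_id)


def fit_survival_split(series: SurvivalSeries, min_separation: float = 1.0,
                       min_samples: int = 40) -> SurvivalThreshold:
    """Fit the two-mode threshold on a survival series (see SurvivalBinarizer)."""
    binarizer = SurvivalBinarizer(
        min_separation=min_separation, min_samples=min_samples
    ).fit(series.efs_time)
    return binarizer.threshold()


def labels_from_survival(series: SurvivalSeries,
                         threshold: SurvivalThreshold | float) -> BinaryLabels:
    """Binarize a survival series at a fitted threshold.

    Samples with ``efs_time >= threshold`` become responders (threshold closed
    on the responder side); shorter survival becomes NR.
    """
    thr = threshold.threshold if isinstance(threshold, SurvivalThreshold) else float(threshold)
    tmin, tmax = series.efs_time.min(), series.efs_time.max()
    if not (tmin <= thr <= tmax):
        raise DataError(
            f"threshold {thr:.1f} d outside observed range [{tmin:.1f}, {tmax:.1f}]"
        )
    labels = np.where(series.efs_time >= thr, "R", "NR")
    return BinaryLabels(series.sample_ids, labels, provenance=float(thr))
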