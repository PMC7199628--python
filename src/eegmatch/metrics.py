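"""Statistical distances between spectral feature vectors and their
conversion to bounded similarity scores.

Six distances are provided, each addressable by its conventional
abbreviation:

========  ==============================================  ===========
name      distance d(P, Q)                                range
========  ==============================================  ===========
ED        Euclidean  sqrt(sum (p_k - q_k)^2)              [0, inf)
PCCD      Pearson correlation coefficient                 [-1, 1]
SKLD      symmetric Kullback-Leibler (D(P||Q)+D(Q||P))/2  [0, inf)
HD        Hellinger  sqrt(1 - BC(P, Q))                   [0, 1]
KD        Kolmogorov  max_k |p_k - q_k|                   [0, inf)
BD        Bhattacharyya  -ln BC(P, Q)                     [0, inf]
========  ==============================================  ===========

where BC(P, Q) = sum_k sqrt(p_k q_k) is the Bhattacharyya coefficient.
HD and BD are both monotone transforms of BC:  d_HD^2 = 1 - BC  and
d_BD = -ln(1 - d_HD^2).

ED, HD and KD are proper metrics (they satisfy the triangle inequality);
SKLD and BD are non-metric distances and do not.

Each distance has a similarity conversion such that a larger score always
means more similar: the reciprocal 1/max(d, eps) for ED, SKLD, HD and KD;
the correlation value itself for PCCD; and the Bhattacharyya coefficient
(= exp(-d_BD), bounded in [0, 1] and maximal at identity) for BD.  Raw
scores from a batch of queries are mapped to [0, 1] by min-max
normalization, which preserves the similarity ranking, so the choice of
conversion does not change detection decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "EPS_FLOOR",
    "METRIC_NAMES",
    "MetricId",
    "SimilarityScores",
    "euclidean_distance",
    "pearson_distance",
    "skld",
    "bhattacharyya_coefficient",
    "hellinger_distance",
    "kolmogorov_distance",
    "bhattacharyya_distance",
    "distance",
    "similarity",
    "minmax_normalize",
]

#: guard for reciprocal similarity conversions when the distance is zero
EPS_FLOOR = 1e-12

_PROB_SUM_TOL = 1e-6


def _pair(p, q) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError(f"vectors must be 1-D with equal length, got {p.shape} and {q.shape}")
    if p.size < 1:
        raise ValueError("vectors must be nonempty")
    return p, q


def _check_probability(v: np.ndarray, name: str, strict_positive: bool) -> None:
    if np.any(v < 0):
        raise ValueError(f"{name} has negative entries; not a probability vector")
    if strict_positive and np.any(v == 0):
        raise ValueError(
            f"{name} has zero entries; floor the spectrum first "
            "(spectral.to_probability applies an epsilon floor)"
        )
    if abs(float(v.sum()) - 1.0) > _PROB_SUM_TOL:
        raise ValueError(f"{name} does not sum to 1 (sum={v.sum():.6g})")


def euclidean_distance(p, q) -> float:
    """Euclidean (L2) distance between two equal-length feature vectors."""
    p, q = _pair(p, q)
    return float(np.sqrt(np.sum((p - q) ** 2)))


def pearson_distance(p, q) -> float:
    """Pearson correlation coefficient between two vectors, in [-1, 1].

    Unlike the true distances, larger is *more* similar; it is used
    directly as the similarity score.  Constant vectors have undefined
    correlation and raise.
    """
    p, q = _pair(p, q)
    if p.size < 2:
        raise ValueError("correlation needs at least 2 points")
    dp = p - p.mean()
    dq = q - q.mean()
    sp = float(np.sqrt(np.sum(dp**2)))
    sq = float(np.sqrt(np.sum(dq**2)))
    if sp == 0.0 or sq == 0.0:
        raise ValueError("correlation undefined for a constant vector (zero variance)")
    r = float(np.sum(dp * dq) / (sp * sq))
    return min(1.0, max(-1.0, r))


def skld(p, q) -> float:
    """Symmetric Kullback-Leibler divergence (D(P||Q) + D(Q||P)) / 2.

    Both inputs must be strictly positive probability vectors (natural
    logarithm; zero iff p == q).
    """
    p, q = _pair(p, q)
    _check_probability(p, "p", strict_positive=True)
    _check_probability(q, "q", strict_positive=True)
    log_ratio = np.log(p / q)
    d_pq = float(np.sum(p * log_ratio))
    d_qp = float(-np.sum(q * log_ratio))
    return (d_pq + d_qp) / 2.0


def bhattacharyya_coefficient(p, q) -> float:
    """BC(P, Q) = sum_k sqrt(p_k q_k); overlap of two distributions in [0, 1]."""
    p, q = _pair(p, q)
    _check_probability(p, "p", strict_positive=False)
    _check_probability(q, "q", strict_positive=False)
    bc = float(np.sum(np.sqrt(p * q)))
    return min(bc, 1.0)


def hellinger_distance(p, q) -> float:
    """Hellinger distance sqrt(1 - BC(P, Q)), a bounded metric in [0, 1].

    Computed in the equivalent form ||sqrt(p) - sqrt(q)||_2 / sqrt(2),
    which is exact at p == q (the sqrt(1 - BC) form amplifies the
    rounding of BC near identity).
    """
    p, q = _pair(p, q)
    _check_probability(p, "p", strict_positive=False)
    _check_probability(q, "q", strict_positive=False)
    d = float(np.linalg.norm(np.sqrt(p) - np.sqrt(q)) / np.sqrt(2.0))
    return min(d, 1.0)


def kolmogorov_distance(p, q) -> float:
    """Kolmogorov (L-infinity) distance max_k |p_k - q_k|."""
    p, q = _pair(p, q)
    return float(np.max(np.abs(p - q)))


def bhattacharyya_distance(p, q) -> float:
    """Bhattacharyya distance -ln BC(P, Q); +inf when the supports are disjoint."""
    bc = bhattacharyya_coefficient(p, q)
    if bc == 0.0:
        return float("inf")
    return float(-np.log(bc))


def _reciprocal(d: float) -> float:
    return 1.0 / max(d, EPS_FLOOR)


@dataclass(frozen=True)
class MetricId:
    """A named similarity metric: its distance, its similarity conversion,
    and whether it consumes unit-sum (probability) spectra."""

    name: str
    distance: Callable[[np.ndarray, np.ndarray], float]
    to_similarity: Callable[[np.ndarray, np.ndarray], float]
    requires_probability: bool


_REGISTRY: dict[str, MetricId] = {}


def _register(metric: MetricId) -> MetricId:
    _REGISTRY[metric.name] = metric
    return metric


ED = _register(MetricId(
    "ED", euclidean_distance,
    lambda p, q: _reciprocal(euclidean_distance(p, q)),
    requires_probability=False))
PCCD = _register(MetricId(
    "PCCD", pearson_distance, pearson_distance,
    requires_probability=False))
SKLD = _register(MetricId(
    "SKLD", skld,
    lambda p, q: _reciprocal(skld(p, q)),
    requires_probability=True))
HD = _register(MetricId(
    "HD", hellinger_distance,
    lambda p, q: _reciprocal(hellinger_distance(p, q)),
    requires_probability=True))
KD = _register(MetricId(
    "KD", kolmogorov_distance,
    lambda p, q: _reciprocal(kolmogorov_distance(p, q)),
    requires_probability=True))
BD = _register(MetricId(
    "BD", bhattacharyya_distance, bhattacharyya_coefficient,
    requires_probability=True))

METRIC_NAMES = tuple(_REGISTRY)  # ("ED", "PCCD", "SKLD", "HD", "KD", "BD")


def get_metric(metric: str | MetricId) -> MetricId:
    if isinstance(metric, MetricId):
        return metric
    try:
        return _REGISTRY[metric]
    except KeyError:
        raise KeyError(f"unknown metric {metric!r}; available: {METRIC_NAMES}") from None


def distance(metric: str | MetricId, p, q) -> float:
    """Distance between two feature vectors under the named metric."""
    return get_metric(metric).distance(p, q)


def similarity(metric: str | MetricId, p, q) -> float:
    """Similarity score under the named metric; larger means more similar."""
    return get_metric(metric).to_similarity(p, q)


def minmax_normalize(raw) -> np.ndarray:
    """Map a batch of raw similarity scores onto [0, 1].

    ``(s - min) / (max - min)``; an all-equal batch (normalization
    undefined) maps to 0.5 everywhere so downstream thresholding stays
    total.  Infinite raw scores (identical-template sentinels) are treated
    as the batch maximum.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size < 2:
        raise ValueError("need at least 2 scores to normalize")
    finite = raw[np.isfinite(raw)]
    if finite.size == 0:
        return np.full(raw.shape, 0.5)
    hi = float(finite.max())
    lo = float(finite.min())
    capped = np.clip(raw, lo, hi)
    if hi == lo:
        return np.full(raw.shape, 0.5)
    return (capped - lo) / (hi - lo)


@dataclass
class SimilarityScores:
    """Raw and [0,1]-normalized similarity scores for a batch of queries."""

    query_ids: list[str]
    raw: np.ndarray
    normalized: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        n = len(self.query_ids)
        if self.raw.shape != (n,) or self.normalized.shape != (n,):
            raise ValueError("query_ids, raw and normalized must have equal length")
        if np.any(self.normalized < 0) or np.any(self.normalized > 1):
            raise ValueError("normalized scores must lie in [0, 1]")

    @classmethod
    def from_raw(cls, query_ids: Sequence[str], raw, metric: str) -> "SimilarityScores":
        raw = np.asarray(raw, dtype=float)
        return cls(list(query_ids), raw, minmax_normalize(raw), metric)
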