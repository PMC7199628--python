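"""Template matching, the threshold decision rule, and threshold fitting.

A query segment's spectrum is compared against a set of normal-template
spectra with one of the similarity metrics; the per-template scores are
aggregated (nearest template ``max`` by default, worst-case ``min``
optionally) into a single similarity S.  After batch min-max
normalization the decision rule is a one-sided threshold test:

    H0 (normal):   S > lambda
    HA (abnormal): S <= lambda

The boundary S == lambda is assigned to the abnormal class.  The
threshold is fitted by an exhaustive sweep over a [0, 1] grid, keeping
the value that maximizes accuracy on labeled calibration scores (ties
broken toward the smallest lambda).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import MetricId, get_metric, minmax_normalize, similarity
from .spectral import SpectrumFeature

__all__ = [
    "TemplateSet",
    "DetectorModel",
    "ThresholdResult",
    "score_query",
    "score_batch",
    "classify",
    "optimize_threshold",
    "calibrate_detector",
    "apply_model",
]


@dataclass
class TemplateSet:
    """Feature vectors of the normal reference (template) segments."""

    features: np.ndarray  # (M, K)
    source_ids: list[str]
    freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        if self.features.shape[0] < 1:
            raise ValueError("template set must contain at least one template")
        if len(self.source_ids) != self.features.shape[0]:
            raise ValueError("source_ids must match the number of template rows")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("template features must be finite")
        if self.freqs is not None:
            self.freqs = np.asarray(self.freqs, dtype=float)

    @classmethod
    def from_spectra(cls, spectra: Sequence[SpectrumFeature],
                     ids: Sequence[str]) -> "TemplateSet":
        mat = np.vstack([s.values for s in spectra])
        return cls(features=mat, source_ids=list(ids), freqs=spectra[0].freqs)

    @property
    def count(self) -> int:
        return int(self.features.shape[0])


def _query_values(query) -> np.ndarray:
    if isinstance(query, SpectrumFeature):
        return query.values
    return np.asarray(query, dtype=float)


def score_query(query, templates: TemplateSet, metric: str | MetricId,
                aggregation: str = "max") -> float:
    """Aggregate similarity of one query against every template.

    ``max`` implements nearest-template matching (default); ``min``
    scores a query by its least similar template.
    """
    if aggregation not in ("max", "min"):
        raise ValueError(f"aggregation must be 'max' or 'min', got {aggregation!r}")
    q = _query_values(query)
    if q.size != templates.features.shape[1]:
        raise ValueError(
            f"query has {q.size} bins but templates have {templates.features.shape[1]}"
        )
    metric = get_metric(metric)
    sims = [similarity(metric, q, t) for t in templates.features]
    return max(sims) if aggregation == "max" else min(sims)


def score_batch(queries: Sequence, templates: TemplateSet, metric: str | MetricId,
                aggregation: str = "max") -> np.ndarray:
    """Raw aggregated similarity score for each query in a batch."""
    return np.array([score_query(q, templates, metric, aggregation) for q in queries])


def classify(s_normalized: float, lam: float) -> str:
    """Threshold test: abnormal iff S <= lambda (boundary is abnormal)."""
    if not 0.0 <= s_normalized <= 1.0:
        raise ValueError(f"normalized similarity {s_normalized} outside [0, 1]")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"threshold {lam} outside [0, 1]")
    return "abnormal" if s_normalized <= lam else "normal"


@dataclass
class ThresholdResult:
    """Outcome of the threshold sweep: the optimum and the full curve."""

    lambda0: float
    grid: np.ndarray
    accuracies: np.ndarray

    @property
    def best_accuracy(self) -> float:
        return float(self.accuracies.max())


def optimize_threshold(scores, labels: Sequence[str],
                       grid_step: float = 0.01) -> ThresholdResult:
    """Exhaustive sweep of lambda over {0, grid_step, ..., 1}.

    Returns the lambda maximizing accuracy on the given normalized scores
    together with the accuracy-vs-lambda curve.  Ties are broken by the
    midpoint of the longest contiguous run of maximal grid points (the
    maximal-margin threshold), which transfers better to held-out data
    than either end of the optimal plateau.  Requires both classes to be
    present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not 0.0 < grid_step <= 1.0:
        raise ValueError("grid_step must be in (0, 1]")
    present = set(labels.tolist())
    if not {"normal", "abnormal"} <= present:
        raise ValueError(
            f"threshold optimization needs both classes, got only {sorted(present)}"
        )
    n_steps = int(round(1.0 / grid_step))
    grid = np.linspace(0.0, 1.0, n_steps + 1)
    is_abnormal = labels == "abnormal"
    # decision: abnormal iff score <= lambda
    correct = [
        np.mean((scores <= lam) == is_abnormal) for lam in grid
    ]
    accuracies = np.asarray(correct, dtype=float)
    lambda0 = float(grid[_plateau_midpoint(accuracies)])
    return ThresholdResult(lambda0=lambda0, grid=grid, accuracies=accuracies)


def _plateau_midpoint(accuracies: np.ndarray) -> int:
    """Index of the midpoint of the longest contiguous run of maxima
    (first such run on ties)."""
    best = accuracies.max()
    is_max = np.concatenate([[False], accuracies == best, [False]])
    edges = np.flatnonzero(np.diff(is_max.astype(int)))
    starts, ends = edges[::2], edges[1::2]  # half-open [start, end) runs
    lengths = ends - starts
    k = int(np.argmax(lengths))
    return int(starts[k] + (lengths[k] - 1) // 2)


@dataclass
class DetectorModel:
    """A calibrated template-matching detector.

    ``normalization_bounds`` are the (min, max) raw scores observed on
    the calibration batch; at deployment a single query has no batch, so
    its raw score is normalized with these stored bounds and clamped to
    [0, 1] before the threshold test.
    """

    templates: TemplateSet
    metric: str
    aggregation: str = "max"
    lam: float | None = None
    normalization_bounds: tuple[float, float] | None = None
    feature_config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        get_metric(self.metric)
        if self.aggregation not in ("max", "min"):
            raise ValueError("aggregation must be 'max' or 'min'")
        if self.lam is not None and not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.normalization_bounds is not None:
            lo, hi = self.normalization_bounds
            if not lo < hi:
                raise ValueError("normalization bounds must satisfy min < max")

    @property
    def calibrated(self) -> bool:
        return self.lam is not None and self.normalization_bounds is not None

    def save(self, path: str | Path) -> None:
        """Serialize to JSON with the template matrix as a CSV sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        sidecar = path.with_suffix(".templates.csv")
        frame = pd.DataFrame(self.templates.features.T,
                             columns=self.templates.source_ids)
        if self.templates.freqs is not None:
            frame.insert(0, "freq", self.templates.freqs)
        frame.to_csv(sidecar, index=False)
        doc = {
            "metric": self.metric,
            "aggregation": self.aggregation,
            "lambda": self.lam,
            "normalization_bounds": list(self.normalization_bounds)
            if self.normalization_bounds else None,
            "feature_config": self.feature_config,
            "templates_csv": sidecar.name,
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "DetectorModel":
        path = Path(path)
        doc = json.loads(path.read_text())
        frame = pd.read_csv(path.parent / doc["templates_csv"])
        freqs = None
        if "freq" in frame.columns:
            freqs = frame.pop("freq").to_numpy()
        templates = TemplateSet(features=frame.to_numpy().T,
                                source_ids=list(frame.columns), freqs=freqs)
        bounds = doc.get("normalization_bounds")
        return cls(
            templates=templates,
            metric=doc["metric"],
            aggregation=doc.get("aggregation", "max"),
            lam=doc.get("lambda"),
            normalization_bounds=tuple(bounds) if bounds else None,
            feature_config=doc.get("feature_config", {}),
        )


def calibrate_detector(
    templates: TemplateSet,
    calibration_features: Sequence,
    labels: Sequence[str],
    metric: str | MetricId,
    aggregation: str = "max",
    grid_step: float = 0.01,
    feature_config: dict | None = None,
) -> tuple[DetectorModel, ThresholdResult]:
    """Fit the threshold and normalization bounds on a labeled batch."""
    metric = get_metric(metric)
    raw = score_batch(calibration_features, templates, metric, aggregation)
    finite = raw[np.isfinite(raw)]
    if finite.size < 2 or float(finite.min()) == float(finite.max()):
        raise ValueError("calibration scores are degenerate (all equal); "
                         "cannot fix normalization bounds")
    bounds = (float(finite.min()), float(finite.max()))
    normalized = minmax_normalize(raw)
    result = optimize_threshold(normalized, labels, grid_step)
    model = DetectorModel(
        templates=templates, metric=metric.name, aggregation=aggregation,
        lam=result.lambda0, normalization_bounds=bounds,
        feature_config=dict(feature_config or {}),
    )
    return model, result


def apply_model(model: DetectorModel, queries: Sequence) -> list[str]:
    """Decide normal/abnormal for each query with a calibrated model.

    Raw scores are normalized with the stored calibration bounds and
    clamped to [0, 1] before thresholding, so a batch decision equals the
    one-by-one decision for every query.
    """
    if not model.calibrated:
        raise ValueError("model is not calibrated (missing lambda or bounds)")
    lo, hi = model.normalization_bounds
    decisions = []
    for q in queries:
        raw = score_query(q, model.templates, model.metric, model.aggregation)
        s = float(np.clip((raw - lo) / (hi - lo), 0.0, 1.0))
        decisions.append(classify(s, model.lam))
    return decisions
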