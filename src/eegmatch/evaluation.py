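"""Evaluation machinery: the AOPO separability indicator, accuracy, metric
ranking, and the cross-validated multi-repetition benchmarking protocol.

AOPO ("abscissa of point O") summarizes class separation with a single
half-integer.  Normal-query similarities are sorted ascending, abnormal
ones descending, and the two curves plotted against rank index 1..n; the
abscissa of their crossing point is the first index i where the ascending
normal curve meets or exceeds the descending abnormal curve, reported at
the midpoint i - 0.5.  Curves that never cross score n + 0.5.  A smaller
AOPO means the two classes' similarity distributions pull apart sooner —
better separation.

The benchmarking protocol mirrors a two-group cross-validation design:
a fixed template set of "most stable" normal segments, two disjoint test
groups each holding equal numbers of normal and abnormal segments, the
decision threshold fitted on one group and evaluated on the other (and
vice versa, averaged), the whole procedure repeated with reshuffled group
assignments and averaged into per-metric means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .detector import TemplateSet, optimize_threshold, score_batch
from .metrics import METRIC_NAMES, get_metric, minmax_normalize
from .signal_model import Dataset
from .spectral import (DEFAULT_BAND, DEFAULT_EPSILON, WelchConfig,
                       extract_feature)

__all__ = [
    "aopo",
    "accuracy",
    "rank_metrics",
    "format_ranking",
    "EvaluationReport",
    "select_templates",
    "run_protocol",
]


def aopo(normal_scores, abnormal_scores) -> float:
    """Abscissa of the crossing point of the sorted similarity curves.

    Returns a half-integer in {0.5, 1.5, ..., n + 0.5}; smaller is better
    separation.  Both score lists must be nonempty and of equal length n.
    """
    a = np.sort(np.asarray(normal_scores, dtype=float))          # ascending
    b = np.sort(np.asarray(abnormal_scores, dtype=float))[::-1]  # descending
    if a.size == 0 or b.size == 0:
        raise ValueError("both score lists must be nonempty")
    if a.size != b.size:
        raise ValueError(f"score lists must have equal length, got {a.size} and {b.size}")
    crossings = np.flatnonzero(a >= b)
    if crossings.size == 0:
        return a.size + 0.5
    return float(crossings[0] + 1) - 0.5


def accuracy(predictions: Sequence[str], labels: Sequence[str]) -> float:
    """Fraction of segments whose predicted label equals the true label."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape or predictions.size == 0:
        raise ValueError("predictions and labels must be nonempty and equal length")
    return float(np.mean(predictions == labels))


def rank_metrics(per_metric: pd.DataFrame, tol: float = 1e-9) -> list[list[str]]:
    """Order metrics by mean accuracy (descending), breaking ties by lower
    mean AOPO; metrics tied on both are grouped together ("equal").

    ``per_metric`` must be indexed by metric name with columns
    ``mean_accuracy`` and ``mean_aopo``.
    """
    items = sorted(
        per_metric.index,
        key=lambda m: (-per_metric.loc[m, "mean_accuracy"],
                       per_metric.loc[m, "mean_aopo"], m),
    )
    groups: list[list[str]] = []
    for m in items:
        if groups:
            head = groups[-1][0]
            same_acc = abs(per_metric.loc[m, "mean_accuracy"]
                           - per_metric.loc[head, "mean_accuracy"]) <= tol
            same_aopo = abs(per_metric.loc[m, "mean_aopo"]
                            - per_metric.loc[head, "mean_aopo"]) <= tol
            if same_acc and same_aopo:
                groups[-1].append(m)
                continue
        groups.append([m])
    return groups


def format_ranking(groups: list[list[str]]) -> str:
    """Render ranked groups as e.g. ``"HD > BD > KD = SKLD > ED"``."""
    return " > ".join(" = ".join(g) for g in groups)


@dataclass
class EvaluationReport:
    """Results of one protocol run.

    Attributes
    ----------
    repetitions : DataFrame
        One row per (repetition, metric) with AOPO, cross-validated
        accuracy, the fitted thresholds and the per-group breakdowns.
    per_metric : DataFrame
        Per-metric means over repetitions, indexed by metric name.
    ranking : list of lists
        Metrics ordered best-first; inner lists hold ties.
    config : dict
        The resolved protocol parameters (including the seed).
    """

    repetitions: pd.DataFrame
    per_metric: pd.DataFrame
    ranking: list[list[str]]
    config: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write ``repetitions.csv`` and ``summary.json`` under *out_dir*."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rep_path = out_dir / "repetitions.csv"
        self.repetitions.to_csv(rep_path, index=False)
        summary = {
            "config": self.config,
            "per_metric": {
                m: {c: float(self.per_metric.loc[m, c]) for c in self.per_metric.columns}
                for m in self.per_metric.index
            },
            "ranking": self.ranking,
            "ranking_text": format_ranking(self.ranking),
        }
        sum_path = out_dir / "summary.json"
        sum_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        return {"repetitions": rep_path, "summary": sum_path}


def select_templates(normal_ids: list[str], features: dict[str, np.ndarray],
                     n_templates: int) -> list[str]:
    """Pick the *n_templates* most stable normal segments.

    Stability is proxied by spectral typicality: segments are ranked by
    the Euclidean distance of their unit-sum spectrum to the normal-pool
    centroid spectrum, and the closest are taken (ids break ties, so the
    choice is deterministic).
    """
    if n_templates > len(normal_ids):
        raise ValueError(
            f"requested {n_templates} templates from only {len(normal_ids)} normals"
        )
    centroid = np.mean([features[i] for i in normal_ids], axis=0)
    ranked = sorted(normal_ids,
                    key=lambda i: (float(np.linalg.norm(features[i] - centroid)), i))
    return ranked[:n_templates]


def run_protocol(
    dataset: Dataset,
    metrics: Sequence[str] = METRIC_NAMES,
    feature_name: str = "dft-welch",
    n_templates: int = 30,
    group_size: int = 30,
    n_repetitions: int = 20,
    seed: int = 0,
    aggregation: str = "max",
    grid_step: float = 0.01,
    welch: WelchConfig | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    epsilon: float = DEFAULT_EPSILON,
) -> EvaluationReport:
    """Run the full cross-validated benchmarking protocol.

    Per repetition: the test pool (``group_size`` normal + ``group_size``
    abnormal segments) is reshuffled into two groups of ``group_size``
    segments each (half normal, half abnormal); for every metric the
    threshold is fitted on group 1 and evaluated on group 2 and vice
    versa, the two accuracies averaged; AOPO is computed on each group
    and averaged.  Features, raw similarities and the joint min-max
    normalization over the whole test pool are computed once — they do
    not depend on the group split.

    Repetition r reshuffles with an independent generator seeded
    ``seed + r``.
    """
    if group_size % 2 != 0:
        raise ValueError("group_size must be even (equal normal/abnormal halves)")
    half = group_size // 2
    metrics = [get_metric(m).name for m in metrics]

    normals = dataset.with_label("normal")
    abnormals = dataset.with_label("abnormal")
    need_normal = n_templates + group_size
    if len(normals) < need_normal or len(abnormals) < group_size:
        raise ValueError(
            f"insufficient segments: need {need_normal} normal and "
            f"{group_size} abnormal, found {len(normals)} and {len(abnormals)}"
        )

    # features once per segment
    feat_kwargs = dict(name=feature_name, welch=welch, band=band, epsilon=epsilon)
    features = {s.id: extract_feature(s, **feat_kwargs).values
                for s in [*normals, *abnormals]}

    template_ids = select_templates([s.id for s in normals], features, n_templates)
    templates = TemplateSet(
        features=np.vstack([features[i] for i in template_ids]),
        source_ids=template_ids,
    )

    # deterministic test pool: the remaining normals closest to the pool
    # centroid, and the first abnormals in id order
    remaining = [s.id for s in normals if s.id not in set(template_ids)]
    norm_test = select_templates(remaining, features, group_size)
    abn_test = sorted(s.id for s in abnormals)[:group_size]
    test_ids = [*norm_test, *abn_test]
    test_labels = np.array(["normal"] * group_size + ["abnormal"] * group_size)

    # raw scores and joint normalization over the whole test pool (Eq 16
    # style: one batch of all test segments) — independent of the split
    normalized = {}
    for m in metrics:
        raw = score_batch([features[i] for i in test_ids], templates, m, aggregation)
        normalized[m] = minmax_normalize(raw)

    norm_idx = np.arange(group_size)              # positions of normals
    abn_idx = np.arange(group_size, 2 * group_size)

    records = []
    for rep in range(n_repetitions):
        rng = np.random.default_rng(seed + rep)
        pn = rng.permutation(group_size)
        pa = rng.permutation(group_size)
        g1 = np.concatenate([norm_idx[pn[:half]], abn_idx[pa[:half]]])
        g2 = np.concatenate([norm_idx[pn[half:]], abn_idx[pa[half:]]])
        for m in metrics:
            s = normalized[m]
            row = {"repetition": rep, "metric": m}
            accs, lams, aops = [], [], []
            for train, test, tag in ((g1, g2, 1), (g2, g1, 2)):
                fit = optimize_threshold(s[train], test_labels[train], grid_step)
                preds = np.where(s[test] <= fit.lambda0, "abnormal", "normal")
                acc = accuracy(preds, test_labels[test])
                grp_norm = s[train][test_labels[train] == "normal"]
                grp_abn = s[train][test_labels[train] == "abnormal"]
                grp_aopo = aopo(grp_norm, grp_abn)
                row[f"lambda_group{tag}"] = fit.lambda0
                row[f"accuracy_group{tag}"] = acc
                row[f"aopo_group{tag}"] = grp_aopo
                accs.append(acc)
                lams.append(fit.lambda0)
                aops.append(grp_aopo)
            row["accuracy"] = float(np.mean(accs))
            row["aopo"] = float(np.mean(aops))
            row["lambda0"] = lams[0]  # threshold fitted on group 1
            records.append(row)

    repetitions = pd.DataFrame.from_records(records)
    per_metric = (
        repetitions.groupby("metric")[["accuracy", "aopo", "lambda0"]]
        .mean()
        .rename(columns={"accuracy": "mean_accuracy", "aopo": "mean_aopo",
                         "lambda0": "mean_lambda0"})
        .loc[metrics]
    )
    ranking = rank_metrics(per_metric)
    config = {
        "metrics": list(metrics),
        "feature": feature_name,
        "n_templates": n_templates,
        "group_size": group_size,
        "n_repetitions": n_repetitions,
        "seed": seed,
        "aggregation": aggregation,
        "grid_step": grid_step,
        "band": list(band),
        "epsilon": epsilon,
        "welch": (welch or WelchConfig(fs=dataset.fs)).to_dict(),
        "template_ids": template_ids,
    }
    return EvaluationReport(repetitions=repetitions, per_metric=per_metric,
                            ranking=ranking, config=config)
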