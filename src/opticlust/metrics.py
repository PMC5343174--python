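"""Pairwise confusion matrix and clustering-quality metrics.

Clustering quality is judged over all n(n-1)/2 unordered sequence pairs:
a close pair (distance <= cutoff) co-clustered in one OTU is a true
positive, a far pair kept apart is a true negative, a far pair
co-clustered is a false positive, and a close pair split across OTUs is a
false negative.  The Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

balances all four counts and is the default optimization and assessment
metric; the registry below also exposes sensitivity, specificity,
accuracy, F1, PPV, NPV, FDR, the sums TP+TN and FP+FN, and the raw counts
so any of them can drive the optimizer.

Zero-denominator conventions (degenerate but reachable states):

* MCC with FP = FN = 0 is 1.0 — the clustering makes no errors, so e.g.
  an all-singleton partition of a graph with no close pairs is perfect.
  Otherwise a zero marginal factor yields 0.0.
* A ratio metric with an empty denominator returns its optimum under its
  direction (sensitivity with TP+FN = 0 -> 1, FDR with TP+FP = 0 -> 0, ...),
  so degenerate seedings are not artificially penalized.

All counts are exact Python integers; MCC is evaluated in floating point
from exact integer products (the denominator is split into four square
roots so totals beyond 2**53 pairs do not overflow).
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import IO, TYPE_CHECKING, Callable, Sequence

from .errors import RosterMismatchError
from .pair_io import ClosePairGraph, Partition

if TYPE_CHECKING:  # pragma: no cover
    from .optimizer import ClusterResult

__all__ = [
    "ConfusionMatrix",
    "MetricSpec",
    "METRIC_DIRECTIONS",
    "mcc",
    "metric_value",
    "resolve_metric",
    "evaluate_partition",
    "stability_report",
    "StabilityReport",
    "write_sensspec",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Pairwise TP/TN/FP/FN counts for a (partition, graph) pair."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for fld in ("tp", "tn", "fp", "fn"):
            v = getattr(self, fld)
            if v < 0:
                raise ValueError(f"{fld} must be >= 0, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _mcc_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    if fp == 0 and fn == 0:
        return 1.0
    for factor in (tp + fp, tp + fn, tn + fp, tn + fn):
        if factor == 0:
            return 0.0
    num = tp * tn - fp * fn
    den = (
        math.sqrt(tp + fp) * math.sqrt(tp + fn) * math.sqrt(tn + fp) * math.sqrt(tn + fn)
    )
    return num / den


def _ratio(num: int, den: int, empty: float) -> float:
    return num / den if den else empty


def _sensitivity(tp, tn, fp, fn):
    return _ratio(tp, tp + fn, 1.0)


def _specificity(tp, tn, fp, fn):
    return _ratio(tn, tn + fp, 1.0)


def _ppv(tp, tn, fp, fn):
    return _ratio(tp, tp + fp, 1.0)


def _npv(tp, tn, fp, fn):
    return _ratio(tn, tn + fn, 1.0)


def _fdr(tp, tn, fp, fn):
    return _ratio(fp, tp + fp, 0.0)


def _accuracy(tp, tn, fp, fn):
    return _ratio(tp + tn, tp + tn + fp + fn, 1.0)


def _f1(tp, tn, fp, fn):
    return _ratio(2 * tp, 2 * tp + fp + fn, 1.0)


_REGISTRY: dict[str, tuple[str, Callable[[int, int, int, int], float]]] = {
    "mcc": ("maximize", _mcc_counts),
    "sensitivity": ("maximize", _sensitivity),
    "specificity": ("maximize", _specificity),
    "accuracy": ("maximize", _accuracy),
    "f1": ("maximize", _f1),
    "ppv": ("maximize", _ppv),
    "npv": ("maximize", _npv),
    "fdr": ("minimize", _fdr),
    "tptn": ("maximize", lambda tp, tn, fp, fn: float(tp + tn)),
    "fpfn": ("minimize", lambda tp, tn, fp, fn: float(fp + fn)),
    "tp": ("maximize", lambda tp, tn, fp, fn: float(tp)),
    "tn": ("maximize", lambda tp, tn, fp, fn: float(tn)),
    "fp": ("minimize", lambda tp, tn, fp, fn: float(fp)),
    "fn": ("minimize", lambda tp, tn, fp, fn: float(fn)),
}

#: fixed optimization direction of every registered metric
METRIC_DIRECTIONS: dict[str, str] = {name: d for name, (d, _) in _REGISTRY.items()}


@dataclass(frozen=True)
class MetricSpec:
    """A named optimization target with its fixed direction."""

    name: str
    direction: str

    def __post_init__(self) -> None:
        if self.name not in _REGISTRY:
            raise KeyError(f"unknown metric {self.name!r}; known: {sorted(_REGISTRY)}")
        if self.direction != METRIC_DIRECTIONS[self.name]:
            raise ValueError(
                f"metric {self.name!r} is always {METRIC_DIRECTIONS[self.name]}d"
            )

    @property
    def fn(self) -> Callable[[int, int, int, int], float]:
        return _REGISTRY[self.name][1]

    def value(self, cm: ConfusionMatrix) -> float:
        return self.fn(cm.tp, cm.tn, cm.fp, cm.fn)

    def is_improvement(self, new: float, old: float) -> bool:
        """Strictly better under this metric's direction."""
        return new > old if self.direction == "maximize" else new < old


def resolve_metric(spec: str | MetricSpec) -> MetricSpec:
    if isinstance(spec, MetricSpec):
        return spec
    if spec not in _REGISTRY:
        raise KeyError(f"unknown metric {spec!r}; known: {sorted(_REGISTRY)}")
    return MetricSpec(name=spec, direction=METRIC_DIRECTIONS[spec])


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient of a confusion matrix, in [-1, 1]."""
    return _mcc_counts(cm.tp, cm.tn, cm.fp, cm.fn)


def metric_value(spec: str | MetricSpec, cm: ConfusionMatrix) -> float:
    """Evaluate a registered metric on a confusion matrix."""
    return resolve_metric(spec).value(cm)


def evaluate_partition(partition: Partition, graph: ClosePairGraph) -> ConfusionMatrix:
    """Post-hoc confusion matrix of an arbitrary partition against a graph.

    TP is counted over the stored close pairs; FP is derived from the number
    of within-OTU pairs, so the cost is O(close pairs + n), never O(n^2).
    """
    proster = partition.roster()
    groster = set(graph.names)
    if proster != groster:
        missing = sorted(groster - proster)[:3]
        extra = sorted(proster - groster)[:3]
        raise RosterMismatchError(
            f"partition and graph rosters differ (graph-only={missing}, partition-only={extra})"
        )
    assign = partition.assignment()
    tp = sum(1 for a, b in graph.iter_close_pairs() if assign[a] == assign[b])
    within = sum(len(otu) * (len(otu) - 1) // 2 for otu in partition.otus)
    fp = within - tp
    fn = graph.total_close - tp
    tn = graph.total_pairs - within - fn
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass(frozen=True)
class StabilityReport:
    """Replicate-to-replicate spread of the optimized metric and OTU count.

    %CV is 100 times the ratio of the sample (n-1) standard deviation to the
    mean.
    """

    n: int
    metric_mean: float
    metric_sd: float
    metric_cv_percent: float
    otu_count_mean: float
    otu_count_sd: float
    otu_count_cv_percent: float


def _cv_percent(sd: float, mean: float) -> float:
    if mean == 0:
        return 0.0 if sd == 0 else math.inf
    return 100.0 * sd / mean


def stability_report(results: Sequence["ClusterResult"]) -> StabilityReport:
    """Summarize replicate clusterings of the same graph.

    Requires at least two results; uses each result's final metric value and
    OTU count.
    """
    if len(results) < 2:
        raise ValueError("stability report requires at least 2 replicate results")
    finals = [r.trace[-1] for r in results]
    otus = [float(r.partition.otu_count) for r in results]
    m_mean = statistics.fmean(finals)
    m_sd = statistics.stdev(finals)
    o_mean = statistics.fmean(otus)
    o_sd = statistics.stdev(otus)
    return StabilityReport(
        n=len(results),
        metric_mean=m_mean,
        metric_sd=m_sd,
        metric_cv_percent=_cv_percent(m_sd, m_mean),
        otu_count_mean=o_mean,
        otu_count_sd=o_sd,
        otu_count_cv_percent=_cv_percent(o_sd, o_mean),
    )


SENSSPEC_COLUMNS = (
    "label",
    "cutoff",
    "tp",
    "tn",
    "fp",
    "fn",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "fdr",
    "accuracy",
    "mcc",
    "f1",
)


def sensspec_row(label: str, cutoff: float, cm: ConfusionMatrix) -> dict[str, object]:
    row: dict[str, object] = {
        "label": label,
        "cutoff": cutoff,
        "tp": cm.tp,
        "tn": cm.tn,
        "fp": cm.fp,
        "fn": cm.fn,
    }
    for name in ("sensitivity", "specificity", "ppv", "npv", "fdr", "accuracy", "mcc", "f1"):
        row[name] = metric_value(name, cm)
    return row


def write_sensspec(
    stream: IO[str],
    label: str,
    cutoff: float,
    cm: ConfusionMatrix,
    extra: dict[str, object] | None = None,
    header: bool = True,
) -> None:
    """Write one sens.spec-style evaluation record as TSV."""
    row = sensspec_row(label, cutoff, cm)
    if extra:
        row.update(extra)
    cols = list(SENSSPEC_COLUMNS) + [k for k in (extra or {}) if k not in SENSSPEC_COLUMNS]
    if header:
        stream.write("\t".join(cols) + "\n")

    def fmt(v: object) -> str:
        if isinstance(v, float):
            return f"{v:.6f}"
        return str(v)

    stream.write("\t".join(fmt(row[c]) for c in cols) + "\n")
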