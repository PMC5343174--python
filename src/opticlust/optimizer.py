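"""Metric-directed local search that assigns sequences to OTUs.

The optimizer is seeded either with every sequence in its own OTU (the
default) or with all sequences in a single OTU.  Each iteration interrogates
every sequence, in a shuffled order fixed once per run, and recomputes the
optimization metric for the cases where the sequence stays in its current
OTU, moves to a new OTU, or moves into any OTU that already holds at least
one of its close neighbors.  The best-scoring placement is committed
immediately.  Iteration stops when the metric changes by less than a delta
(default 0.0001; delta 0 demands exact stabilization, "full convergence")
or when a maximum number of iterations (default 100) is reached.

Only OTUs holding a close neighbor of the interrogated sequence are scored
(besides "stay" and "new"): moving a sequence into a neighbor-free OTU of
size m adds m false positives and no true positives relative to the new-OTU
option, which strictly dominates it under every registered maximize metric
and never beats it under the minimize ones, so restricting the candidate
set cannot change the chosen move.  This is what lets the optimizer track
only the sparse close-pair graph rather than all n^2 distances.

The confusion matrix is maintained incrementally: removing a sequence with
c close neighbors inside its OTU of size m subtracts c true positives and
m-1 within-OTU pairs; inserting it into a candidate OTU adds that OTU's
neighbor count and size.  FN and TN follow from the fixed totals
(fn = total_close - tp, tn = total_pairs - within - fn).

Ties are broken deterministically: prefer the current OTU, then the new-OTU
option, then the first candidate in an enumeration ordered by decreasing
OTU size with the lexicographically smallest member as tiebreaker.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Iterable

from .metrics import ConfusionMatrix, MetricSpec, evaluate_partition, resolve_metric
from .pair_io import ClosePairGraph, Partition

__all__ = [
    "OptimizerConfig",
    "ClusterResult",
    "seed_partition",
    "best_move",
    "cluster",
    "cluster_replicates",
]

SEED_MODES = ("singletons", "one_otu")
STOP_REASONS = ("delta_reached", "fully_converged", "max_iterations")


@dataclass(frozen=True)
class OptimizerConfig:
    """Knobs of a clustering run.

    delta is the convergence threshold on the per-iteration metric change;
    0 means iterate until the metric is exactly unchanged.  shuffle_seed
    fixes the sequence interrogation order.
    """

    metric: str | MetricSpec = "mcc"
    seed_mode: str = "singletons"
    delta: float = 0.0001
    max_iterations: int = 100
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if self.seed_mode not in SEED_MODES:
            raise ValueError(f"seed_mode must be one of {SEED_MODES}, got {self.seed_mode!r}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if self.max_iterations < 1:
            raise ValueError(f"max_iterations must be >= 1, got {self.max_iterations}")
        resolve_metric(self.metric)


@dataclass
class ClusterResult:
    """Final partition plus the per-iteration metric trace.

    trace[0] is the metric of the seeding state; trace[i] the value after
    iteration i.  otu_trace parallels trace with OTU counts.
    """

    partition: Partition
    trace: list[float]
    otu_trace: list[int]
    confusion: ConfusionMatrix
    converged: bool
    reason: str
    config: OptimizerConfig


def seed_partition(graph: ClosePairGraph, mode: str = "singletons") -> Partition:
    """Initial partition: n singleton OTUs, or one OTU holding all n sequences."""
    if not graph.names:
        raise ValueError("cannot seed a partition from an empty roster")
    if mode not in SEED_MODES:
        raise ValueError(f"mode must be one of {SEED_MODES}, got {mode!r}")
    label = format(graph.cutoff, "g")
    if mode == "singletons":
        return Partition(otus=[{nm} for nm in graph.names], label=label)
    return Partition(otus=[set(graph.names)], label=label)


class _OptState:
    """Mutable partition state with an incrementally maintained confusion matrix."""

    __slots__ = ("graph", "assign", "members", "tp", "within", "_next_id")

    def __init__(self, graph: ClosePairGraph, partition: Partition):
        self.graph = graph
        self.assign: dict[str, int] = {}
        self.members: dict[int, set[str]] = {}
        for i, otu in enumerate(partition.otus):
            self.members[i] = set(otu)
            for nm in otu:
                self.assign[nm] = i
        self._next_id = len(partition.otus)
        self.within = sum(m * (m - 1) // 2 for m in (len(o) for o in self.members.values()))
        tp = 0
        for a, b in graph.iter_close_pairs():
            if self.assign[a] == self.assign[b]:
                tp += 1
        self.tp = tp

    def confusion(self) -> ConfusionMatrix:
        fn = self.graph.total_close - self.tp
        fp = self.within - self.tp
        tn = self.graph.total_pairs - self.within - fn
        return ConfusionMatrix(tp=self.tp, tn=tn, fp=fp, fn=fn)

    def _score(self, metric: MetricSpec, tp: int, within: int) -> float:
        fn = self.graph.total_close - tp
        fp = within - tp
        tn = self.graph.total_pairs - within - fn
        return metric.fn(tp, tn, fp, fn)

    def propose(self, seq: str, metric: MetricSpec) -> tuple[str, int | None, int, int, float]:
        """Best placement for seq: ('stay'|'new'|'move', otu_id, tp', within', score)."""
        cur = self.assign[seq]
        counts: dict[int, int] = {}
        for nb in self.graph.neighbors[seq]:
            oid = self.assign[nb]
            counts[oid] = counts.get(oid, 0) + 1
        c_cur = counts.pop(cur, 0)
        m_cur = len(self.members[cur])
        tp_base = self.tp - c_cur
        within_base = self.within - (m_cur - 1)

        best: tuple[str, int | None, int, int, float] = (
            "stay",
            cur,
            self.tp,
            self.within,
            self._score(metric, self.tp, self.within),
        )
        s_new = self._score(metric, tp_base, within_base)
        if metric.is_improvement(s_new, best[4]):
            best = ("new", None, tp_base, within_base, s_new)
        # deterministic enumeration: size desc, then smallest member
        order = sorted(counts, key=lambda oid: (-len(self.members[oid]), min(self.members[oid])))
        for oid in order:
            m = len(self.members[oid])
            tp_c = tp_base + counts[oid]
            within_c = within_base + m
            s = self._score(metric, tp_c, within_c)
            if metric.is_improvement(s, best[4]):
                best = ("move", oid, tp_c, within_c, s)
        return best

    def apply(self, seq: str, move: tuple[str, int | None, int, int, float]) -> bool:
        kind, oid, tp_new, within_new, _ = move
        if kind == "stay":
            return False
        cur = self.assign[seq]
        self.members[cur].discard(seq)
        if not self.members[cur]:
            del self.members[cur]
        if kind == "new":
            oid = self._next_id
            self._next_id += 1
            self.members[oid] = set()
        assert oid is not None
        self.members[oid].add(seq)
        self.assign[seq] = oid
        self.tp = tp_new
        self.within = within_new
        return True

    def to_partition(self, label: str) -> Partition:
        return Partition(otus=[set(m) for m in self.members.values()], label=label)


def best_move(
    seq: str,
    partition: Partition,
    graph: ClosePairGraph,
    metric: str | MetricSpec = "mcc",
    cm: ConfusionMatrix | None = None,
) -> tuple[frozenset[str] | str, ConfusionMatrix, float]:
    """Score the candidate placements of one sequence and return the best.

    Returns ``(target, confusion_after, score)`` where target is the member
    set of the chosen OTU (the current one when the sequence stays, excluding
    the sequence itself for a move) or the string ``"new"`` for a fresh
    singleton OTU.  A supplied ``cm`` is checked against the partition.
    """
    spec = resolve_metric(metric)
    state = _OptState(graph, partition)
    if cm is not None and cm != state.confusion():
        raise ValueError("supplied confusion matrix is inconsistent with the partition")
    kind, oid, tp_new, within_new, score = state.propose(seq, spec)
    fn = graph.total_close - tp_new
    fp = within_new - tp_new
    tn = graph.total_pairs - within_new - fn
    cm_after = ConfusionMatrix(tp=tp_new, tn=tn, fp=fp, fn=fn)
    if kind == "stay":
        target: frozenset[str] | str = frozenset(state.members[state.assign[seq]])
    elif kind == "new":
        target = "new"
    else:
        assert oid is not None
        target = frozenset(state.members[oid])
    return target, cm_after, score


def cluster(
    graph: ClosePairGraph,
    config: OptimizerConfig | None = None,
    *,
    validate_every_move: bool = False,
) -> ClusterResult:
    """Run the optimizer to convergence on a close-pair graph.

    ``validate_every_move`` recomputes the confusion matrix from scratch after
    every committed move and raises if it disagrees with the incremental
    bookkeeping; used by the test harness.
    """
    if not graph.names:
        raise ValueError("cannot cluster an empty graph")
    config = config or OptimizerConfig()
    spec = resolve_metric(config.metric)
    label = format(graph.cutoff, "g")

    state = _OptState(graph, seed_partition(graph, config.seed_mode))
    order = sorted(graph.names)
    random.Random(config.shuffle_seed).shuffle(order)

    trace = [spec.value(state.confusion())]
    otu_trace = [len(state.members)]
    converged = False
    reason = "max_iterations"
    for _ in range(config.max_iterations):
        for seq in order:
            move = state.propose(seq, spec)
            if state.apply(seq, move) and validate_every_move:
                full = evaluate_partition(state.to_partition(label), graph)
                if full != state.confusion():
                    raise RuntimeError(
                        f"incremental confusion matrix diverged: {state.confusion()} vs {full}"
                    )
        trace.append(spec.value(state.confusion()))
        otu_trace.append(len(state.members))
        change = abs(trace[-1] - trace[-2])
        if change == 0.0:
            converged = True
            reason = "fully_converged"
            break
        if config.delta > 0 and change < config.delta:
            converged = True
            reason = "delta_reached"
            break

    partition = state.to_partition(label)
    return ClusterResult(
        partition=partition,
        trace=trace,
        otu_trace=otu_trace,
        confusion=state.confusion(),
        converged=converged,
        reason=reason,
        config=config,
    )


def cluster_replicates(
    graph: ClosePairGraph,
    config: OptimizerConfig | None = None,
    n_reps: int = 10,
    *,
    validate_every_move: bool = False,
) -> list[ClusterResult]:
    """Cluster with n_reps shuffled interrogation orders (seeds seed, seed+1, ...).

    The replicate results feed :func:`opticlust.metrics.stability_report`.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    config = config or OptimizerConfig()
    out = []
    for i in range(n_reps):
        cfg = replace(config, shuffle_seed=config.shuffle_seed + i)
        out.append(cluster(graph, cfg, validate_every_move=validate_every_move))
    return out
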