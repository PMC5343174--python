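"""Independent oracles used by the tests: brute-force confusion counting,
exhaustive set-partition enumeration, and random instance generators.

These deliberately avoid the package's incremental bookkeeping so they can
stand as independent cross-checks.
"""

from __future__ import annotations

import math
import random

from opticlust.pair_io import ClosePairGraph, Partition


def random_graph(rng: random.Random, n: int, p: float, cutoff: float = 0.03) -> ClosePairGraph:
    """Erdos-Renyi close-pair graph on n named vertices."""
    names = [f"s{i:03d}" for i in range(n)]
    neighbors: dict[str, set[str]] = {nm: set() for nm in names}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                neighbors[names[i]].add(names[j])
                neighbors[names[j]].add(names[i])
    return ClosePairGraph(names=names, neighbors=neighbors, cutoff=cutoff)


def random_partition(rng: random.Random, names: list[str]) -> Partition:
    """Random partition via independent block assignment."""
    k = rng.randint(1, len(names))
    otus: dict[int, set[str]] = {}
    for nm in names:
        otus.setdefault(rng.randrange(k), set()).add(nm)
    return Partition(otus=[s for s in otus.values() if s], label="0.03")


def brute_force_confusion(partition: Partition, graph: ClosePairGraph) -> tuple[int, int, int, int]:
    """(tp, tn, fp, fn) by a naive double loop over every unordered pair."""
    assign = {}
    for i, otu in enumerate(partition.otus):
        for nm in otu:
            assign[nm] = i
    names = graph.names
    tp = tn = fp = fn = 0
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            close = b in graph.neighbors[a]
            together = assign[a] == assign[b]
            if close and together:
                tp += 1
            elif close:
                fn += 1
            elif together:
                fp += 1
            else:
                tn += 1
    return tp, tn, fp, fn


def mcc_reference(tp: int, tn: int, fp: int, fn: int) -> float:
    """MCC evaluated straight off the formula: exact integer numerator and
    marginal product, one floating square root at the end."""
    if fp == 0 and fn == 0:
        return 1.0
    prod = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if prod == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(prod)


def set_partitions(items: list[str]):
    """Every set partition of the items (Bell(n) of them)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {first}] + part[i + 1 :]
        yield part + [{first}]


def exhaustive_best_mcc(graph: ClosePairGraph) -> float:
    """Maximal MCC over all set partitions of the roster (tiny n only)."""
    close = set(graph.iter_close_pairs())
    total = graph.total_pairs
    tc = len(close)
    best = -2.0
    for part in set_partitions(list(graph.names)):
        assign = {}
        for i, block in enumerate(part):
            for nm in block:
                assign[nm] = i
        tp = sum(1 for a, b in close if assign[a] == assign[b])
        within = sum(len(b) * (len(b) - 1) // 2 for b in part)
        fp = within - tp
        fn = tc - tp
        tn = total - within - fn
        best = max(best, mcc_reference(tp, tn, fp, fn))
    return best
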