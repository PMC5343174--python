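"""Taxonomy-based cluster splitting.

A divide-and-conquer heuristic: classify sequences (upstream, e.g. with a
naive Bayesian classifier), group them by their taxonomic label at a chosen
rank, cluster each taxon independently, and merge the per-taxon OTU lists.
Close pairs whose members fall in different taxa can never be co-clustered,
so each one is a forced false negative of the merged partition; the merged
confusion matrix is always evaluated against the full close-pair graph so
this degradation is visible.

Taxonomy is consumed as a TSV of ``name<TAB>lineage`` with semicolon-delimited
ranks (kingdom through genus) and optional bootstrap confidences in
parentheses, which are stripped.  Sequences unclassified at the split rank
are grouped under their deepest classified label as an
"<label>_unclassified" pseudo-taxon.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, replace
from typing import IO, Iterable, Mapping, NamedTuple

from .errors import DataFormatError
from .metrics import ConfusionMatrix, evaluate_partition
from .optimizer import ClusterResult, OptimizerConfig, cluster
from .pair_io import ClosePairGraph, Partition

__all__ = [
    "RANKS",
    "TaxonomyMap",
    "read_taxonomy",
    "write_taxonomy",
    "SplitGraphs",
    "SplitResult",
    "split_roster",
    "split_cluster",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

_BOOTSTRAP = re.compile(r"\([^()]*\)")


def _is_unclassified(label: str) -> bool:
    low = label.lower()
    return low == "unclassified" or low.endswith("_unclassified")


@dataclass
class TaxonomyMap:
    """Sequence name -> ordered lineage labels (kingdom ... genus)."""

    assignments: dict[str, tuple[str, ...]]

    def taxon_at(self, name: str, rank: str) -> str:
        """Effective taxon label of a sequence at a rank.

        Lineages shallower than the rank, or carrying an "unclassified"
        sentinel at it, inherit the deepest classified label above.
        """
        if rank not in RANKS:
            raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
        depth = RANKS.index(rank)
        levels = self.assignments[name]
        deepest: str | None = None
        effective = "unclassified"
        for d in range(depth + 1):
            label = levels[d] if d < len(levels) else ""
            if label and not _is_unclassified(label):
                deepest = label
                effective = label
            else:
                effective = f"{deepest}_unclassified" if deepest else "unclassified"
        return effective

    def covers(self, names: Iterable[str]) -> list[str]:
        """Names missing from the taxonomy (empty when fully covered)."""
        return [nm for nm in names if nm not in self.assignments]


def read_taxonomy(stream: IO[str]) -> TaxonomyMap:
    """Read a classifier-style taxonomy TSV, stripping bootstrap values."""
    assignments: dict[str, tuple[str, ...]] = {}
    for lineno, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split(None, 1)
        if len(tokens) != 2:
            raise DataFormatError("taxonomy line must be 'name<TAB>lineage'", lineno)
        name, lineage = tokens
        if name in assignments:
            raise DataFormatError(f"duplicate taxonomy entry for {name!r}", lineno)
        lineage = _BOOTSTRAP.sub("", lineage)
        labels = tuple(lab.strip() for lab in lineage.split(";") if lab.strip())
        if not labels:
            raise DataFormatError(f"empty lineage for {name!r}", lineno)
        assignments[name] = labels
    if not assignments:
        raise DataFormatError("no taxonomy records found")
    return TaxonomyMap(assignments=assignments)


def write_taxonomy(taxonomy: TaxonomyMap, stream: IO[str]) -> None:
    for name in taxonomy.assignments:
        stream.write(f"{name}\t{';'.join(taxonomy.assignments[name])};\n")


class SplitGraphs(NamedTuple):
    subgraphs: dict[str, ClosePairGraph]
    cross_pairs: list[tuple[str, str]]


@dataclass
class SplitResult:
    """Merged partition from per-taxon clustering, scored against the full graph."""

    partition: Partition
    per_taxon: dict[str, ClusterResult]
    confusion: ConfusionMatrix
    cross_pairs: list[tuple[str, str]]

    @property
    def forced_fn(self) -> int:
        """Close pairs split across taxa — guaranteed false negatives."""
        return len(self.cross_pairs)


def split_roster(graph: ClosePairGraph, taxonomy: TaxonomyMap, rank: str) -> SplitGraphs:
    """Partition a close-pair graph by taxon at a rank.

    Each sub-graph keeps only within-taxon close pairs; cross-taxon close
    pairs are returned separately (they become forced false negatives of any
    merged partition).  The sub-rosters partition the full roster.
    """
    missing = taxonomy.covers(graph.names)
    if missing:
        raise DataFormatError(f"sequences missing from taxonomy: {missing[:5]}")
    taxon_of = {nm: taxonomy.taxon_at(nm, rank) for nm in graph.names}
    rosters: dict[str, list[str]] = {}
    for nm in graph.names:
        rosters.setdefault(taxon_of[nm], []).append(nm)
    cross: list[tuple[str, str]] = []
    subgraphs: dict[str, ClosePairGraph] = {}
    for taxon, names in rosters.items():
        subgraphs[taxon] = ClosePairGraph(
            names=names,
            neighbors={nm: {b for b in graph.neighbors[nm] if taxon_of[b] == taxon} for nm in names},
            cutoff=graph.cutoff,
        )
    for a, b in graph.iter_close_pairs():
        if taxon_of[a] != taxon_of[b]:
            cross.append((a, b))
    return SplitGraphs(subgraphs=subgraphs, cross_pairs=cross)


def _taxon_seed(base_seed: int, taxon: str) -> int:
    # stable per-taxon seed so results are independent of taxon processing order
    return (base_seed + zlib.crc32(taxon.encode("utf-8"))) % (2**31)


def split_cluster(
    graph: ClosePairGraph,
    taxonomy: TaxonomyMap,
    rank: str,
    config: OptimizerConfig | None = None,
) -> SplitResult:
    """Cluster each taxon independently and merge the OTU lists.

    The merged partition is evaluated against the FULL graph, so cross-taxon
    close pairs count as false negatives.  With a single taxon (e.g. a
    one-kingdom taxonomy split at kingdom rank) this reduces exactly to plain
    clustering with the same seed.
    """
    config = config or OptimizerConfig()
    subgraphs, cross = split_roster(graph, taxonomy, rank)
    per_taxon: dict[str, ClusterResult] = {}
    otus: list[set[str]] = []
    single_taxon = len(subgraphs) == 1
    for taxon in sorted(subgraphs):
        # a single taxon reproduces plain clustering bit-for-bit (same seed)
        seed = config.shuffle_seed if single_taxon else _taxon_seed(config.shuffle_seed, taxon)
        result = cluster(subgraphs[taxon], replace(config, shuffle_seed=seed))
        per_taxon[taxon] = result
        otus.extend(set(o) for o in result.partition.otus)
    merged = Partition(otus=otus, label=format(graph.cutoff, "g"))
    confusion = evaluate_partition(merged, graph)
    return SplitResult(partition=merged, per_taxon=per_taxon, confusion=confusion, cross_pairs=cross)
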