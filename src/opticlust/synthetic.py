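"""Synthetic fixtures: planted partitions, abundance profiles, taxonomies.

The planted-partition generator emits full pairwise distance records for a
known ground-truth clustering: within-cluster pairs draw distances at or
below the cutoff, between-cluster pairs above it, and an optional noise rate
flips the close/far status of individual pairs by redrawing from the
opposite range.  Distances (not just the boolean relation) are emitted so
fixtures exercise the real file-reading path, including the inclusive
cutoff boundary.

Abundance generators mimic mock-community profiles: an even profile gives
every sequence the same read count (default 100); a staggered profile draws
i.i.d. uniform integer counts (default 1..200).

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field
from typing import Sequence

from .pair_io import (
    ClosePairGraph,
    DistanceRecord,
    Partition,
    read_column_distances,
    write_column_distances,
)
from .taxsplit import RANKS, TaxonomyMap

__all__ = [
    "PlantedSpec",
    "AbundanceProfile",
    "generate_planted",
    "planted_graph",
    "generate_abundance",
    "generate_taxonomy",
]


@dataclass(frozen=True)
class PlantedSpec:
    """Recipe for a planted-partition distance instance."""

    cluster_sizes: tuple[int, ...]
    within_range: tuple[float, float] = (0.005, 0.03)
    between_range: tuple[float, float] = (0.05, 0.25)
    noise_rate: float = 0.0
    cutoff: float = 0.03
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cluster_sizes", tuple(self.cluster_sizes))
        if not self.cluster_sizes or any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster_sizes must be positive integers")
        lo, hi = self.within_range
        if not (0.0 <= lo <= hi <= self.cutoff):
            raise ValueError(f"within_range {self.within_range} must lie inside [0, cutoff]")
        lo, hi = self.between_range
        if not (self.cutoff < lo <= hi <= 1.0):
            raise ValueError(f"between_range {self.between_range} must lie inside (cutoff, 1]")
        if not (0.0 <= self.noise_rate < 0.5):
            raise ValueError(f"noise_rate must be in [0, 0.5), got {self.noise_rate}")

    @property
    def n(self) -> int:
        return sum(self.cluster_sizes)


def _names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"seq{i + 1:0{width}d}" for i in range(n)]


def generate_planted(spec: PlantedSpec) -> tuple[list[DistanceRecord], Partition]:
    """Generate all-pairs distance records plus the ground-truth partition."""
    rng = random.Random(spec.rng_seed)
    names = _names(spec.n)
    membership: list[int] = []
    for ci, size in enumerate(spec.cluster_sizes):
        membership.extend([ci] * size)
    records: list[DistanceRecord] = []
    for i in range(spec.n):
        for j in range(i + 1, spec.n):
            same = membership[i] == membership[j]
            if spec.noise_rate > 0 and rng.random() < spec.noise_rate:
                same = not same
            rng_range = spec.within_range if same else spec.between_range
            d = rng.uniform(*rng_range)
            records.append(DistanceRecord(names[i], names[j], d))
    otus: list[set[str]] = [set() for _ in spec.cluster_sizes]
    for nm, ci in zip(names, membership):
        otus[ci].add(nm)
    truth = Partition(otus=otus, label=format(spec.cutoff, "g"))
    return records, truth


def planted_graph(spec: PlantedSpec) -> tuple[ClosePairGraph, Partition]:
    """Generate a planted instance and load it through the column-file reader.

    Round-tripping through the text format guarantees the graph seen by the
    optimizer is byte-identical to one read from disk.
    """
    records, truth = generate_planted(spec)
    buf = io.StringIO()
    write_column_distances(records, buf)
    buf.seek(0)
    names = sorted(truth.roster())
    graph = read_column_distances(buf, spec.cutoff, roster=names)
    return graph, truth


@dataclass(frozen=True)
class AbundanceProfile:
    """Even or staggered read-count profile for a mock community."""

    mode: str = "even"
    n_taxa: int = 0
    even_depth: int = 100
    staggered_range: tuple[int, int] = (1, 200)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("even", "staggered"):
            raise ValueError(f"mode must be 'even' or 'staggered', got {self.mode!r}")
        if self.n_taxa < 0:
            raise ValueError("n_taxa must be >= 0")
        if self.even_depth < 1:
            raise ValueError("even_depth must be >= 1")
        lo, hi = self.staggered_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid staggered_range {self.staggered_range}")


def generate_abundance(
    profile: AbundanceProfile, names: Sequence[str] | None = None
) -> dict[str, int]:
    """Read counts per sequence; compatible with the name-count roster format."""
    if names is None:
        names = _names(profile.n_taxa)
    if profile.mode == "even":
        return {nm: profile.even_depth for nm in names}
    rng = random.Random(profile.rng_seed)
    lo, hi = profile.staggered_range
    return {nm: rng.randint(lo, hi) for nm in names}


def generate_taxonomy(
    truth: Partition,
    k_genera: int,
    cross_rate: float = 0.0,
    rng_seed: int = 0,
) -> TaxonomyMap:
    """Taxonomy fixture: whole truth OTUs share a genus, plus misclassification.

    Each ground-truth OTU (in canonical order) is assigned wholly to one of
    ``k_genera`` six-rank lineages, round-robin.  Each sequence is then
    independently reassigned to a uniformly chosen *different* genus with
    probability ``cross_rate``, emulating classifier error — the mechanism
    that turns within-OTU close pairs into forced false negatives when
    clustering is split by taxon.
    """
    if k_genera < 1:
        raise ValueError("k_genera must be >= 1")
    if not (0.0 <= cross_rate <= 1.0):
        raise ValueError(f"cross_rate must be in [0, 1], got {cross_rate}")
    lineages = [
        ("Bacteria", f"Phylum{g:02d}", f"Class{g:02d}", f"Order{g:02d}", f"Family{g:02d}", f"Genus{g:02d}")
        for g in range(k_genera)
    ]
    rng = random.Random(rng_seed)
    assignments: dict[str, tuple[str, ...]] = {}
    for i, block in enumerate(truth.canonical()):
        g = i % k_genera
        for nm in block:
            gi = g
            if k_genera > 1 and cross_rate > 0 and rng.random() < cross_rate:
                gi = rng.randrange(k_genera - 1)
                if gi >= g:
                    gi += 1
            assignments[nm] = lineages[gi]
    return TaxonomyMap(assignments=assignments)
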