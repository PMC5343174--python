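"""Readers and writers for pairwise-distance inputs and OTU assignments.

Distance inputs come either as column ("triplet") files with one
``nameA nameB distance`` record per line, or as square / lower-triangle
PHYLIP distance matrices.  Only the boolean close/far relation at the
chosen cutoff is retained after loading: the clustering algorithm never
consults the numeric distances again, so the in-memory representation is
a sparse adjacency over sequence names (:class:`ClosePairGraph`).

The cutoff boundary is inclusive: a pair at exactly the cutoff distance
is a close pair.

OTU assignments are read and written in the mothur list dialect: a single
line holding the distance label, the OTU count, and one comma-joined
member list per OTU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

from .errors import DataFormatError

__all__ = [
    "DistanceRecord",
    "ClosePairGraph",
    "Partition",
    "read_column_distances",
    "read_phylip_distances",
    "write_column_distances",
    "read_list",
    "write_list",
    "read_roster",
]

#: tolerance for declaring a square distance matrix asymmetric
SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class DistanceRecord:
    """One pairwise dissimilarity between two distinct sequences."""

    name_a: str
    name_b: str
    distance: float


@dataclass
class ClosePairGraph:
    """Sparse symmetric adjacency holding exactly the pairs at or below the cutoff.

    Attributes
    ----------
    names:
        Ordered roster of the n unique sequence identifiers.  Sequences with
        no close pair are isolated vertices but still count toward
        ``total_pairs``.
    neighbors:
        For each name, the set of names whose distance to it is <= cutoff.
    cutoff:
        The dissimilarity threshold defining "close".
    """

    names: list[str]
    neighbors: dict[str, set[str]]
    cutoff: float

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def total_pairs(self) -> int:
        """Number of unordered sequence pairs, n(n-1)/2."""
        n = len(self.names)
        return n * (n - 1) // 2

    @property
    def total_close(self) -> int:
        """Number of stored close pairs."""
        return sum(len(s) for s in self.neighbors.values()) // 2

    def iter_close_pairs(self) -> Iterator[tuple[str, str]]:
        """Yield each unordered close pair once, smaller name first."""
        for a in self.names:
            for b in self.neighbors[a]:
                if a < b:
                    yield a, b

    def validate(self) -> None:
        """Check symmetry, absence of self-edges and roster closure."""
        roster = set(self.names)
        if len(roster) != len(self.names):
            raise ValueError("duplicate names in roster")
        if set(self.neighbors) != roster:
            raise ValueError("neighbor map keys differ from roster")
        for a, nbrs in self.neighbors.items():
            if a in nbrs:
                raise ValueError(f"self-edge at {a!r}")
            for b in nbrs:
                if b not in roster:
                    raise ValueError(f"neighbor {b!r} not in roster")
                if a not in self.neighbors[b]:
                    raise ValueError(f"asymmetric edge {a!r}-{b!r}")


@dataclass
class Partition:
    """Assignment of every sequence to exactly one OTU."""

    otus: list[set[str]]
    label: str = "0.03"

    def validate(self, roster: Iterable[str] | None = None) -> None:
        seen: set[str] = set()
        for otu in self.otus:
            if not otu:
                raise ValueError("empty OTU retained in partition")
            dup = seen & otu
            if dup:
                raise ValueError(f"sequence in more than one OTU: {sorted(dup)[:3]}")
            seen |= otu
        if roster is not None and seen != set(roster):
            missing = set(roster) - seen
            extra = seen - set(roster)
            raise ValueError(f"partition/roster mismatch (missing={sorted(missing)[:3]}, extra={sorted(extra)[:3]})")

    def roster(self) -> set[str]:
        out: set[str] = set()
        for otu in self.otus:
            out |= otu
        return out

    def assignment(self) -> dict[str, int]:
        """Map each sequence to the index of its OTU (validates disjointness)."""
        assign: dict[str, int] = {}
        for i, otu in enumerate(self.otus):
            for name in otu:
                if name in assign:
                    raise ValueError(f"sequence {name!r} in more than one OTU")
                assign[name] = i
        return assign

    def canonical(self) -> list[list[str]]:
        """OTUs as sorted member lists, ordered by decreasing size then first member."""
        blocks = [sorted(otu) for otu in self.otus if otu]
        blocks.sort(key=lambda b: (-len(b), b[0]))
        return blocks

    @property
    def otu_count(self) -> int:
        return len(self.otus)


def _build_graph(names: list[str], pair_dist: dict[tuple[str, str], float], cutoff: float) -> ClosePairGraph:
    neighbors: dict[str, set[str]] = {nm: set() for nm in names}
    for (a, b), d in pair_dist.items():
        if d <= cutoff:
            neighbors[a].add(b)
            neighbors[b].add(a)
    return ClosePairGraph(names=names, neighbors=neighbors, cutoff=cutoff)


def read_column_distances(
    stream: IO[str],
    cutoff: float,
    roster: Sequence[str] | None = None,
) -> ClosePairGraph:
    """Read a column distance file into a :class:`ClosePairGraph`.

    Every name seen in the file joins the roster even when its distances all
    exceed the cutoff; an optional ``roster`` adds isolated vertices for
    sequences that appear in no pair at all (e.g. singleton reads in a
    names/count file).

    Duplicate records for the same unordered pair are collapsed when their
    distances agree and rejected otherwise.
    """
    names: list[str] = []
    seen: set[str] = set()

    def add(nm: str) -> None:
        if nm not in seen:
            seen.add(nm)
            names.append(nm)

    pair_dist: dict[tuple[str, str], float] = {}
    for lineno, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 3:
            raise DataFormatError(
                f"expected 3 whitespace-separated fields, found {len(tokens)}", lineno
            )
        a, b, dtok = tokens
        try:
            d = float(dtok)
        except ValueError:
            raise DataFormatError(f"distance {dtok!r} is not a number", lineno) from None
        if not 0.0 <= d <= 1.0:
            raise DataFormatError(f"distance {d} outside [0, 1]", lineno)
        if a == b:
            raise DataFormatError(f"self-pair for sequence {a!r}", lineno)
        key = (a, b) if a < b else (b, a)
        if key in pair_dist:
            if pair_dist[key] != d:
                raise DataFormatError(
                    f"conflicting duplicate distances for pair {key[0]} {key[1]}: "
                    f"{pair_dist[key]} vs {d}",
                    lineno,
                )
        else:
            pair_dist[key] = d
        add(a)
        add(b)

    if roster is not None:
        roster = list(roster)
        if len(set(roster)) != len(roster):
            dup = sorted({nm for nm in roster if roster.count(nm) > 1})
            raise DataFormatError(f"roster name collision: {dup[:3]}")
        for nm in roster:
            add(nm)

    return _build_graph(names, pair_dist, cutoff)


def read_phylip_distances(stream: IO[str], cutoff: float) -> ClosePairGraph:
    """Read a square or lower-triangle PHYLIP distance matrix.

    The layout is auto-detected from the row lengths.  All n names enter the
    roster regardless of the cutoff.  A square matrix must be symmetric to
    within ``SYMMETRY_TOL``.
    """
    lines = [ln.strip() for ln in stream if ln.strip()]
    if not lines:
        raise DataFormatError("empty distance matrix stream")
    head = lines[0].split()
    try:
        n = int(head[0])
    except ValueError:
        raise DataFormatError(f"first line must be the sequence count, got {lines[0]!r}", 1) from None
    rows = [ln.split() for ln in lines[1:]]
    if len(rows) != n:
        raise DataFormatError(f"declared {n} sequences but found {len(rows)} matrix rows")

    if n > 0 and all(len(r) == n + 1 for r in rows):
        square = True
    elif all(len(r) == i + 1 for i, r in enumerate(rows)):
        square = False
    else:
        raise DataFormatError("row lengths match neither a square nor a lower-triangle layout")

    names = [r[0] for r in rows]
    if len(set(names)) != n:
        raise DataFormatError("duplicate sequence names in matrix")

    def cell(tok: str, i: int, j: int) -> float:
        try:
            d = float(tok)
        except ValueError:
            raise DataFormatError(f"non-numeric cell {tok!r} at row {i + 1}, column {j + 1}") from None
        if not 0.0 <= d <= 1.0:
            raise DataFormatError(f"distance {d} outside [0, 1] at row {i + 1}, column {j + 1}")
        return d

    pair_dist: dict[tuple[str, str], float] = {}
    if square:
        mat = [[cell(tok, i, j) for j, tok in enumerate(r[1:])] for i, r in enumerate(rows)]
        for i in range(n):
            for j in range(i + 1, n):
                if abs(mat[i][j] - mat[j][i]) > SYMMETRY_TOL:
                    raise DataFormatError(
                        f"asymmetric matrix: d({names[i]},{names[j]})={mat[i][j]} "
                        f"but d({names[j]},{names[i]})={mat[j][i]}"
                    )
                key = (names[i], names[j]) if names[i] < names[j] else (names[j], names[i])
                pair_dist[key] = mat[i][j]
    else:
        for i, r in enumerate(rows):
            for j, tok in enumerate(r[1:]):
                d = cell(tok, i, j)
                a, b = names[i], names[j]
                key = (a, b) if a < b else (b, a)
                pair_dist[key] = d

    return _build_graph(names, pair_dist, cutoff)


def write_column_distances(records: Iterable[DistanceRecord], stream: IO[str]) -> None:
    """Write distance records as a column file (round-trip exact via ``repr``)."""
    for rec in records:
        stream.write(f"{rec.name_a}\t{rec.name_b}\t{rec.distance!r}\n")


def write_list(partition: Partition, stream: IO[str]) -> None:
    """Write a partition as a one-line mothur-style list record.

    OTUs are ordered by decreasing size (ties broken by the lexicographically
    smallest member) and members within an OTU are sorted, so output is
    deterministic and diff-able.
    """
    partition.validate()
    blocks = partition.canonical()
    fields = [partition.label, str(len(blocks))] + [",".join(b) for b in blocks]
    stream.write("\t".join(fields) + "\n")


def read_list(stream: IO[str]) -> Partition:
    """Read a one-line mothur-style list record back into a :class:`Partition`."""
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise DataFormatError("list record needs at least a label and an OTU count", lineno)
        label = fields[0]
        try:
            declared = int(fields[1])
        except ValueError:
            raise DataFormatError(f"OTU count {fields[1]!r} is not an integer", lineno) from None
        otus: list[set[str]] = []
        seen: set[str] = set()
        for block in fields[2:]:
            members = [m for m in block.split(",") if m]
            if not members:
                raise DataFormatError("empty OTU in list record", lineno)
            otu = set(members)
            if len(otu) != len(members):
                raise DataFormatError(f"duplicate member within an OTU: {block!r}", lineno)
            dup = seen & otu
            if dup:
                raise DataFormatError(f"sequence {sorted(dup)[0]!r} appears in more than one OTU", lineno)
            seen |= otu
            otus.append(otu)
        if declared != len(otus):
            raise DataFormatError(f"declared {declared} OTUs but parsed {len(otus)}", lineno)
        return Partition(otus=otus, label=label)
    raise DataFormatError("no list record found in stream")


def read_roster(stream: IO[str]) -> tuple[list[str], dict[str, int] | None]:
    """Read a sequence roster: one name per line, or a name-count TSV.

    Counts, when present, are carried through to reporting only; they never
    affect clustering.
    """
    names: list[str] = []
    counts: dict[str, int] = {}
    widths: set[int] = set()
    for lineno, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) not in (1, 2):
            raise DataFormatError(f"roster line must have 1 or 2 fields, found {len(tokens)}", lineno)
        widths.add(len(tokens))
        if len(widths) > 1:
            raise DataFormatError("roster mixes plain-name and name-count lines", lineno)
        nm = tokens[0]
        if nm in counts or (len(widths) == 1 and 1 in widths and nm in names):
            raise DataFormatError(f"roster name collision: {nm!r}", lineno)
        names.append(nm)
        if len(tokens) == 2:
            try:
                c = int(tokens[1])
            except ValueError:
                raise DataFormatError(f"count {tokens[1]!r} is not an integer", lineno) from None
            if c < 1:
                raise DataFormatError(f"count must be >= 1, got {c}", lineno)
            counts[nm] = c
    if len(names) != len(set(names)):
        dup = sorted({nm for nm in names if names.count(nm) > 1})
        raise DataFormatError(f"roster name collision: {dup[:3]}")
    return names, (counts if counts else None)
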