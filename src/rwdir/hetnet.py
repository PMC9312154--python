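"""Three-type heterogeneous RNA network: data model and plain-text I/O.

The network mixes three vertex classes (mRNA, miRNA, lncRNA) and the six
edge classes formed by pairing them.  Vertices are kept in a canonical
order — all mRNAs first, then miRNAs, then lncRNAs, each class sorted
lexicographically by id — so the adjacency matrix has a fixed 3x3 block
layout that the transition-matrix code relies on.

Edges are undirected, unweighted and simple: the adjacency matrix H is
symmetric 0/1 with a zero diagonal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RNAType",
    "Label",
    "FormatError",
    "IntegrityError",
    "HeteroNetwork",
    "BlockAdjacency",
    "LabelAssignment",
    "read_edge_list",
    "read_labels",
    "build_adjacency",
    "degree",
    "write_edge_list",
    "write_labels",
]


class RNAType(str, Enum):
    """The three vertex classes, in canonical block order."""

    MRNA = "mRNA"
    MIRNA = "miRNA"
    LNCRNA = "lncRNA"

    @classmethod
    def parse(cls, token: str) -> "RNAType":
        t = token.strip().lower()
        for member in cls:
            if member.value.lower() == t:
                return member
        raise FormatError(f"unknown RNA type token: {token!r}")


#: canonical ordering of the three classes (mRNA block first, lncRNA last)
TYPE_ORDER: tuple[RNAType, ...] = (RNAType.MRNA, RNAType.MIRNA, RNAType.LNCRNA)


class Label(str, Enum):
    """Per-vertex disease label: related / irrelevant / unlabeled."""

    RELATED = "related"
    IRRELEVANT = "irrelevant"
    UNLABELED = "unlabeled"

    @classmethod
    def parse(cls, token: str) -> "Label":
        t = token.strip().lower()
        for member in cls:
            if member.value == t:
                return member
        raise FormatError(f"unknown label token: {token!r}")


class FormatError(ValueError):
    """Malformed input file (bad token, wrong column count)."""


class IntegrityError(ValueError):
    """Input is well-formed but internally inconsistent."""


@dataclass(frozen=True)
class HeteroNetwork:
    """Typed vertex set plus an undirected simple edge set.

    ``vertices`` is in canonical order; ``edges`` holds id pairs that are
    themselves stored in canonical-index order.
    """

    vertices: tuple[tuple[str, RNAType], ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [v for v, _ in self.vertices]
        if len(set(ids)) != len(ids):
            raise IntegrityError("duplicate vertex ids")
        idset = set(ids)
        for u, v in self.edges:
            if u == v:
                raise IntegrityError(f"self-loop on {u!r}")
            if u not in idset or v not in idset:
                raise IntegrityError(f"edge ({u!r}, {v!r}) references undeclared vertex")

    # -- construction -------------------------------------------------

    @classmethod
    def from_members(
        cls,
        types: Mapping[str, RNAType],
        edges: Iterable[tuple[str, str]],
    ) -> "HeteroNetwork":
        """Build the canonical-order network from an id->type map and edge pairs.

        Duplicate edges (in either orientation) collapse; each stored pair is
        ordered by canonical vertex index.
        """
        ordered = sorted(types.items(), key=lambda kv: (TYPE_ORDER.index(kv[1]), kv[0]))
        index = {vid: i for i, (vid, _) in enumerate(ordered)}
        canon: set[tuple[str, str]] = set()
        for u, v in edges:
            if u not in index or v not in index:
                raise IntegrityError(f"edge ({u!r}, {v!r}) references undeclared vertex")
            if u == v:
                raise IntegrityError(f"self-loop on {u!r}")
            canon.add((u, v) if index[u] < index[v] else (v, u))
        return cls(vertices=tuple(ordered), edges=frozenset(canon))

    # -- basic queries -------------------------------------------------

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(v for v, _ in self.vertices)

    @property
    def index(self) -> dict[str, int]:
        return {vid: i for i, (vid, _) in enumerate(self.vertices)}

    def type_counts(self) -> dict[RNAType, int]:
        counts = {t: 0 for t in TYPE_ORDER}
        for _, t in self.vertices:
            counts[t] += 1
        return counts

    @property
    def s(self) -> int:
        """Number of mRNA vertices."""
        return self.type_counts()[RNAType.MRNA]

    @property
    def m(self) -> int:
        """Number of miRNA vertices."""
        return self.type_counts()[RNAType.MIRNA]

    @property
    def n(self) -> int:
        """Number of lncRNA vertices."""
        return self.type_counts()[RNAType.LNCRNA]

    @property
    def h(self) -> int:
        """Total vertex count (s + m + n)."""
        return len(self.vertices)

    def degree(self, vid: str) -> int:
        if vid not in self.index:
            raise KeyError(f"unknown vertex: {vid!r}")
        return sum(1 for u, v in self.edges if vid in (u, v))


@dataclass(frozen=True)
class BlockAdjacency:
    """Symmetric 0/1 adjacency in canonical order plus block edge counts.

    ``block_counts`` is keyed by unordered type pairs; diagonal blocks count
    undirected edges once (upper triangle).
    """

    H: np.ndarray
    type_slices: dict[RNAType, slice]
    block_counts: dict[frozenset, int] = field(default_factory=dict)

    def count(self, a: RNAType, b: RNAType) -> int:
        return self.block_counts[frozenset((a, b))]

    @property
    def h(self) -> int:
        return self.H.shape[0]

    def degrees(self) -> np.ndarray:
        return np.asarray(self.H.sum(axis=1)).ravel()


@dataclass
class LabelAssignment:
    """Raw vertex-id -> label map as read from a label file.

    Vertices missing from the map resolve to ``unlabeled``; ids unknown to a
    network are warned about and ignored at resolution time.
    """

    labels: dict[str, Label]

    def resolve(self, net: HeteroNetwork) -> list[Label]:
        """Per-vertex labels in the network's canonical order."""
        known = set(net.ids)
        extra = sorted(set(self.labels) - known)
        if extra:
            warnings.warn(
                f"{len(extra)} labeled id(s) not in the network, ignored: "
                + ", ".join(extra[:5]) + ("..." if len(extra) > 5 else ""),
                stacklevel=2,
            )
        missing = [vid for vid in net.ids if vid not in self.labels]
        if missing:
            logger.info("%d network vertex(es) default to unlabeled", len(missing))
        return [self.labels.get(vid, Label.UNLABELED) for vid in net.ids]

    def count(self, label: Label) -> int:
        return sum(1 for v in self.labels.values() if v is label)


# ---------------------------------------------------------------------------
# I/O — tab-separated dialect
# ---------------------------------------------------------------------------


def _parse_vertex_table(path: str | Path) -> dict[str, RNAType]:
    types: dict[str, RNAType] = {}
    for lineno, row in _tsv_rows(path):
        if len(row) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
        vid, tok = row
        t = RNAType.parse(tok)
        if vid in types and types[vid] is not t:
            raise IntegrityError(
                f"{path}:{lineno}: vertex {vid!r} declared both "
                f"{types[vid].value} and {t.value}"
            )
        types[vid] = t
    return types


def _tsv_rows(path: str | Path):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_edge_list(
    path: str | Path,
    vertices: str | Path | None = None,
) -> HeteroNetwork:
    """Read an edge-list TSV into a :class:`HeteroNetwork`.

    Each row is ``source_id <TAB> source_type <TAB> target_id <TAB>
    target_type`` with an optional fifth weight column, which is discarded
    with a warning (the adjacency is binary).  An optional companion vertex
    table (``id <TAB> type``) declares vertices — including isolated ones —
    ahead of the edges; rows may then omit nothing, but any type declared in
    both places must agree.
    """
    types: dict[str, RNAType] = {}
    if vertices is not None:
        types = _parse_vertex_table(vertices)
    edges: list[tuple[str, str]] = []
    saw_weight = False
    for lineno, row in _tsv_rows(path):
        if len(row) not in (4, 5):
            raise FormatError(f"{path}:{lineno}: expected 4 or 5 columns, got {len(row)}")
        if len(row) == 5:
            saw_weight = True
        sid, stok, tid, ttok = row[:4]
        for vid, tok in ((sid, stok), (tid, ttok)):
            t = RNAType.parse(tok)
            if vid in types and types[vid] is not t:
                raise IntegrityError(
                    f"{path}:{lineno}: vertex {vid!r} declared both "
                    f"{types[vid].value} and {t.value}"
                )
            types[vid] = t
        edges.append((sid, tid))
    if saw_weight:
        warnings.warn(
            "edge weights present in input were discarded (adjacency is binary)",
            stacklevel=2,
        )
    return HeteroNetwork.from_members(types, edges)


def read_labels(path: str | Path) -> LabelAssignment:
    """Read a two-column ``id <TAB> label`` TSV; tokens match case-insensitively."""
    labels: dict[str, Label] = {}
    for lineno, row in _tsv_rows(path):
        if len(row) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
        vid, tok = row
        labels[vid] = Label.parse(tok)
    return LabelAssignment(labels)


def write_edge_list(net: HeteroNetwork, path: str | Path) -> None:
    """Emit the edge-list TSV dialect read by :func:`read_edge_list`.

    Isolated vertices are preserved by a companion vertex table written next
    to the edge file only when needed — here we instead emit a header-free
    four-column file plus, for isolated vertices, a ``<path>.vertices.tsv``
    side file.
    """
    path = Path(path)
    index = net.index
    typemap = dict(net.vertices)
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(net.edges, key=lambda e: (index[e[0]], index[e[1]])):
            fh.write(f"{u}\t{typemap[u].value}\t{v}\t{typemap[v].value}\n")
    touched = {x for e in net.edges for x in e}
    isolated = [(vid, t) for vid, t in net.vertices if vid not in touched]
    if isolated:
        with open(path.with_suffix(path.suffix + ".vertices.tsv"), "w", encoding="utf-8") as fh:
            for vid, t in net.vertices:
                fh.write(f"{vid}\t{t.value}\n")


def write_labels(assignment: LabelAssignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for vid in sorted(assignment.labels):
            fh.write(f"{vid}\t{assignment.labels[vid].value}\n")


# ---------------------------------------------------------------------------
# Adjacency
# ---------------------------------------------------------------------------


def build_adjacency(net: HeteroNetwork) -> BlockAdjacency:
    """Dense symmetric 0/1 adjacency H plus the six block edge counts."""
    h = net.h
    H = np.zeros((h, h), dtype=np.int8)
    index = net.index
    for u, v in net.edges:
        i, j = index[u], index[v]
        H[i, j] = 1
        H[j, i] = 1

    counts = net.type_counts()
    slices: dict[RNAType, slice] = {}
    start = 0
    for t in TYPE_ORDER:
        slices[t] = slice(start, start + counts[t])
        start += counts[t]

    block_counts: dict[frozenset, int] = {}
    for ai, a in enumerate(TYPE_ORDER):
        for b in TYPE_ORDER[ai:]:
            block = H[slices[a], slices[b]]
            if a is b:
                c = int(np.triu(block, k=1).sum())
            else:
                c = int(block.sum())
            block_counts[frozenset((a, b))] = c
    return BlockAdjacency(H=H, type_slices=slices, block_counts=block_counts)


def degree(net: HeteroNetwork, vid: str) -> int:
    """Number of incident edges of ``vid`` across all vertex classes."""
    return net.degree(vid)
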