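"""Parsing and assembly of the chemical-enzyme heterogeneous network.

Interaction evidence comes as STITCH/STRING-dialect links files: tab-separated
rows of (node1, node2, combined confidence score), where the score is an
integer between 1 and 999 that integrates several evidence channels. Three
such files -- chemical-chemical (CCI), chemical-protein (CPI) and
protein-protein (PPI) interactions -- are combined into one undirected,
weighted heterogeneous network whose nodes are chemicals and enzymes and
whose edge weights are the confidence scores rescaled into (0, 1).

Node identifiers are opaque strings; a node's kind (chemical vs enzyme) is
assigned purely from the supplied roster files, never inferred from the id
syntax. All matrix views of the network use the canonical node order:
chemicals sorted lexicographically, then enzymes sorted lexicographically.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

CHEMICAL = "chemical"
ENZYME = "enzyme"

SCORE_MIN = 1
SCORE_MAX = 999

_DIALECTS = ("cci", "cpi", "ppi")


class EdgeListParseError(ValueError):
    """A links file row that cannot be interpreted; names the line number."""


@dataclass(frozen=True)
class EdgeRecord:
    """One interaction row: two node ids and the raw 1-999 confidence score."""

    source: str
    target: str
    raw_score: int


def refine_score(raw_score: int) -> float:
    """Rescale a 1-999 confidence score to an edge weight in (0, 1).

    The combined score is divided by 1000, so 999 -> 0.999 and 1 -> 0.001.
    """
    if raw_score != int(raw_score):
        raise ValueError(f"confidence score must be an integer, got {raw_score!r}")
    raw_score = int(raw_score)
    if not SCORE_MIN <= raw_score <= SCORE_MAX:
        raise ValueError(
            f"confidence score {raw_score} outside the valid range "
            f"[{SCORE_MIN}, {SCORE_MAX}]"
        )
    return raw_score / 1000.0


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def read_edge_list(path: str | Path, dialect: str) -> list[EdgeRecord]:
    """Read a STITCH/STRING-dialect links file into edge records.

    The file is tab-separated with three columns (node1, node2, score), an
    optional single header line, and may be gzip-compressed (detected from
    the magic bytes, not the file name). For ``dialect="cpi"`` the chemical
    column is the source and the protein column the target; the other two
    dialects are symmetric.

    Rows with an out-of-range score or the wrong column count raise
    :class:`EdgeListParseError` naming the line. Self-loop rows are skipped
    with a warning. An empty file yields an empty list.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    records: list[EdgeRecord] = []
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            source, target, score_text = fields
            try:
                score = int(score_text)
            except ValueError:
                if lineno == 1:  # single header line allowed
                    continue
                raise EdgeListParseError(
                    f"{path}: line {lineno}: non-integer score {score_text!r}"
                ) from None
            if not SCORE_MIN <= score <= SCORE_MAX:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: score {score} outside "
                    f"[{SCORE_MIN}, {SCORE_MAX}]"
                )
            if source == target:
                warnings.warn(
                    f"{path}: line {lineno}: self-loop on {source!r} skipped",
                    stacklevel=2,
                )
                continue
            records.append(EdgeRecord(source, target, score))
    return records


@dataclass
class HeteroNetwork:
    """Undirected weighted network over chemical and enzyme nodes.

    Wraps a :class:`networkx.Graph` whose nodes carry a ``kind`` attribute
    and whose edges carry a ``weight`` in (0, 1]. Edges are stored once and
    queried symmetrically; there are no self-loops or duplicates.
    """

    graph: nx.Graph
    subnetwork_edge_counts: dict[str, int] = field(default_factory=dict)

    @property
    def chemicals(self) -> list[str]:
        return sorted(
            n for n, k in self.graph.nodes(data="kind") if k == CHEMICAL
        )

    @property
    def enzymes(self) -> list[str]:
        return sorted(n for n, k in self.graph.nodes(data="kind") if k == ENZYME)

    @property
    def nodes(self) -> list[str]:
        """Canonical node order: sorted chemicals, then sorted enzymes."""
        return self.chemicals + self.enzymes

    @property
    def kinds(self) -> list[str]:
        return [self.graph.nodes[n]["kind"] for n in self.nodes]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def kind(self, node: str) -> str:
        return self.graph.nodes[node]["kind"]

    def weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def adjacency_matrix(self) -> np.ndarray:
        """Dense symmetric weighted adjacency in canonical node order."""
        order = self.nodes
        return nx.to_numpy_array(self.graph, nodelist=order, weight="weight")

    def copy(self) -> "HeteroNetwork":
        return HeteroNetwork(self.graph.copy(), dict(self.subnetwork_edge_counts))


def _kind_pair(net: HeteroNetwork, u: str, v: str) -> str:
    ku, kv = net.kind(u), net.kind(v)
    return f"{ku}-{kv}" if (ku, kv) <= (kv, ku) else f"{kv}-{ku}"


def build_hetero_network(
    cci: Iterable[EdgeRecord],
    cpi: Iterable[EdgeRecord],
    ppi: Iterable[EdgeRecord],
    chemical_ids: Iterable[str],
    enzyme_ids: Iterable[str],
) -> HeteroNetwork:
    """Combine the three interaction layers into one heterogeneous network.

    Nodes are exactly the union of the two rosters (kind tagged from the
    roster an id appears in); edges whose endpoints fall outside the rosters
    are dropped with a logged count. Duplicate rows for the same unordered
    pair (including A-B vs B-A) resolve to the maximum refined score --
    deterministic and order independent, keeping the strongest evidence.
    """
    chemical_ids = set(chemical_ids)
    enzyme_ids = set(enzyme_ids)
    overlap = chemical_ids & enzyme_ids
    if overlap:
        raise ValueError(
            f"{len(overlap)} ids present in both rosters, e.g. {sorted(overlap)[:3]}"
        )

    def _valid(dialect: str, rec: EdgeRecord) -> bool:
        if dialect == "cci":
            return rec.source in chemical_ids and rec.target in chemical_ids
        if dialect == "ppi":
            return rec.source in enzyme_ids and rec.target in enzyme_ids
        return rec.source in chemical_ids and rec.target in enzyme_ids

    graph = nx.Graph()
    graph.add_nodes_from((c, {"kind": CHEMICAL}) for c in chemical_ids)
    graph.add_nodes_from((e, {"kind": ENZYME}) for e in enzyme_ids)

    counts: dict[str, int] = {}
    for dialect, records in (("cci", cci), ("cpi", cpi), ("ppi", ppi)):
        best: dict[tuple[str, str], float] = {}
        dropped = 0
        for rec in records:
            if not _valid(dialect, rec):
                dropped += 1
                continue
            pair = (rec.source, rec.target)
            if pair[0] > pair[1]:
                pair = (pair[1], pair[0])
            w = refine_score(rec.raw_score)
            if w > best.get(pair, 0.0):
                best[pair] = w
        if dropped:
            logger.info("%s: dropped %d edges with endpoints off-roster", dialect, dropped)
        counts[dialect] = len(best)
        for (u, v), w in best.items():
            graph.add_edge(u, v, weight=w)
    return HeteroNetwork(graph, counts)


def drop_isolated(network: HeteroNetwork) -> tuple[HeteroNetwork, list[str]]:
    """Remove degree-zero nodes; returns the pruned network and the removed
    ids sorted lexicographically. Idempotent."""
    removed = sorted(n for n in network.graph.nodes if network.graph.degree(n) == 0)
    pruned = network.graph.copy()
    pruned.remove_nodes_from(removed)
    return HeteroNetwork(pruned, dict(network.subnetwork_edge_counts)), removed


def write_edge_list(network: HeteroNetwork, path: str | Path) -> None:
    """Write the canonical edge-list TSV: source, target, kind_pair, weight
    (6 decimals), one row per undirected edge, endpoints in canonical order."""
    order = {n: i for i, n in enumerate(network.nodes)}
    rows = []
    for u, v, w in network.graph.edges(data="weight"):
        if order[u] > order[v]:
            u, v = v, u
        rows.append((order[u], order[v], u, v, w))
    rows.sort()
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("source\ttarget\tkind_pair\tweight\n")
        for _, _, u, v, w in rows:
            fh.write(f"{u}\t{v}\t{_kind_pair(network, u, v)}\t{w:.6f}\n")


def read_canonical_edge_list(path: str | Path) -> HeteroNetwork:
    """Read a network written by :func:`write_edge_list` back into memory."""
    graph = nx.Graph()
    counts: dict[str, int] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("source\t"):
            raise EdgeListParseError(f"{path}: missing canonical header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected 4 columns, got {len(fields)}"
                )
            u, v, kind_pair, weight = fields
            ku, kv = kind_pair.split("-")
            graph.add_node(u, kind=ku)
            graph.add_node(v, kind=kv)
            graph.add_edge(u, v, weight=float(weight))
            key = {"chemical-chemical": "cci", "chemical-enzyme": "cpi",
                   "enzyme-enzyme": "ppi"}[kind_pair]
            counts[key] = counts.get(key, 0) + 1
    return HeteroNetwork(graph, counts)


def read_roster(path: str | Path) -> list[str]:
    """Read a roster file: one node id per line, blank lines ignored."""
    with open(path, "rt", encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def read_label_table(
    path: str | Path, vocabulary: Sequence[str] | None = None
) -> tuple[list[str], np.ndarray, list[str]]:
    """Read a node-to-label-set TSV (node id, semicolon-separated labels).

    Returns (node ids in file order, binary label matrix, label vocabulary).
    The vocabulary is the sorted set of labels seen unless one is supplied,
    in which case unknown labels raise a :class:`ValueError`.
    """
    entries: list[tuple[str, list[str]]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            node, labels = fields
            entries.append((node, [l for l in labels.split(";") if l]))
    if vocabulary is None:
        vocabulary = sorted({l for _, labels in entries for l in labels})
    vocab = list(vocabulary)
    index = {l: j for j, l in enumerate(vocab)}
    Y = np.zeros((len(entries), len(vocab)), dtype=np.int8)
    for i, (_, labels) in enumerate(entries):
        for l in labels:
            if l not in index:
                raise ValueError(f"{path}: unknown label {l!r} for node {entries[i][0]!r}")
            Y[i, index[l]] = 1
    return [node for node, _ in entries], Y, vocab


def write_removed_report(removed: Sequence[str], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("node\n")
        for node in removed:
            fh.write(f"{node}\n")
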