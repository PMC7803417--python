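"""Seeded synthetic heterogeneous networks with label-correlated wiring.

The generator emulates the structure of the real chemical-enzyme data --
two node kinds, multilabel pathway-type membership, weighted edges in
(0, 1] -- with a label-conditioned planted-partition design: a pair of
nodes sharing at least one label is connected with probability ``p_intra``,
any other pair with probability ``p_inter`` <= ``p_intra``, regardless of
kind, so cross-kind edges carry the same label signal as within-kind edges.
Shared-label edges draw their weight from a higher-mean law than
non-shared edges. Weights are quantized to 3 decimals so they round-trip
the 1-999 integer confidence-score dialect exactly.

Every quantity is a pure function of the configuration (bit-reproducible
given the seed). Fixtures can be exported in the links-file dialect that
:mod:`hetpath.net_builder` parses, exercising the whole pipeline from flat
files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple

import networkx as nx
import numpy as np

from .net_builder import CHEMICAL, ENZYME, HeteroNetwork


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings: node counts per kind, label-vocabulary size m,
    per-node label-count cap, the planted edge probabilities (p_intra for
    label-sharing pairs, p_inter otherwise) and the two uniform weight laws
    in (0, 1], all driven by one seed."""

    n_chem: int = 120
    n_enz: int = 60
    m: int = 5
    max_labels_per_node: int = 2
    p_intra: float = 0.25
    p_inter: float = 0.02
    w_shared: tuple[float, float] = (0.5, 0.999)
    w_other: tuple[float, float] = (0.001, 0.5)
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_inter <= self.p_intra <= 1.0:
            raise ValueError("need 0 <= p_inter <= p_intra <= 1")
        if self.m < 2:
            raise ValueError("need at least 2 labels")
        if self.max_labels_per_node < 1:
            raise ValueError("max_labels_per_node must be >= 1")
        if self.n_chem < 1 or self.n_enz < 1:
            raise ValueError("need at least one node of each kind")


class Benchmark(NamedTuple):
    network: HeteroNetwork
    labels: np.ndarray
    kinds: np.ndarray
    node_ids: list[str]
    label_names: list[str]
    config: SynthConfig


PRESETS: dict[str, SynthConfig] = {
    # p_intra/p_inter gap shrinks from easy to hard (weaker planted signal)
    "easy": SynthConfig(p_intra=0.25, p_inter=0.02),
    "medium": SynthConfig(p_intra=0.15, p_inter=0.04),
    "hard": SynthConfig(p_intra=0.08, p_inter=0.05),
}


def _node_ids(cfg: SynthConfig) -> tuple[list[str], np.ndarray]:
    ids = [f"c{i:04d}" for i in range(cfg.n_chem)] + [
        f"e{i:04d}" for i in range(cfg.n_enz)
    ]
    kinds = np.array([CHEMICAL] * cfg.n_chem + [ENZYME] * cfg.n_enz)
    return ids, kinds


def generate_labels(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Assign each node 1..max_labels_per_node labels: the count uniform,
    then that many labels uniform without replacement. Returns the binary
    label matrix (canonical node order) and the per-node kinds."""
    rng = np.random.default_rng(cfg.seed)
    _, kinds = _node_ids(cfg)
    n = cfg.n_chem + cfg.n_enz
    Y = np.zeros((n, cfg.m), dtype=np.int8)
    counts = rng.integers(1, cfg.max_labels_per_node + 1, size=n)
    for i in range(n):
        Y[i, rng.choice(cfg.m, size=counts[i], replace=False)] = 1
    return Y, kinds


def _quantize(w: np.ndarray | float) -> np.ndarray | float:
    """Snap to the 3-decimal grid of the 1-999 score dialect."""
    return np.clip(np.round(np.asarray(w) * 1000.0) / 1000.0, 0.001, 0.999)


def generate_network(
    labels: np.ndarray, kinds: np.ndarray, cfg: SynthConfig
) -> HeteroNetwork:
    """Plant label-correlated edges over all node pairs.

    Each unordered pair (within or across kinds) receives an edge with
    probability p_intra if the nodes share a label, p_inter otherwise;
    shared-label edges draw from the higher-mean weight law. Nodes left
    isolated are rewired to one random shared-label partner (or any other
    node if none shares a label), so pruning removes nothing.
    """
    if cfg.p_intra == 0.0 and cfg.p_inter == 0.0:
        raise ValueError("p_intra = p_inter = 0 cannot produce a connected fixture")
    rng = np.random.default_rng(cfg.seed + 1)
    ids, _ = _node_ids(cfg)
    n = len(ids)
    Y = np.asarray(labels)
    shared = (Y @ Y.T) > 0
    prob = np.where(shared, cfg.p_intra, cfg.p_inter)
    draw = rng.random((n, n)) < prob
    graph = nx.Graph()
    for node, kind in zip(ids, kinds):
        graph.add_node(node, kind=kind)
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu[draw[iu, ju]], ju[draw[iu, ju]]):
        lo, hi = cfg.w_shared if shared[i, j] else cfg.w_other
        graph.add_edge(ids[i], ids[j], weight=float(_quantize(rng.uniform(lo, hi))))
    for i in range(n):
        if graph.degree(ids[i]) > 0:
            continue
        partners = np.flatnonzero(shared[i])
        partners = partners[partners != i]
        if partners.size == 0:
            partners = np.array([j for j in range(n) if j != i])
        j = int(rng.choice(partners))
        lo, hi = cfg.w_shared if shared[i, j] else cfg.w_other
        graph.add_edge(ids[i], ids[j], weight=float(_quantize(rng.uniform(lo, hi))))
    counts = {"cci": 0, "cpi": 0, "ppi": 0}
    for u, v in graph.edges:
        ku, kv = graph.nodes[u]["kind"], graph.nodes[v]["kind"]
        if ku == kv:
            counts["cci" if ku == CHEMICAL else "ppi"] += 1
        else:
            counts["cpi"] += 1
    return HeteroNetwork(graph, counts)


def make_benchmark(difficulty: str = "easy", seed: int | None = None) -> Benchmark:
    """Build a preset fixture; ``seed`` overrides the preset's seed."""
    if difficulty not in PRESETS:
        raise ValueError(
            f"unknown difficulty {difficulty!r}; expected one of {sorted(PRESETS)}"
        )
    cfg = PRESETS[difficulty]
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    Y, kinds = generate_labels(cfg)
    network = generate_network(Y, kinds, cfg)
    ids, _ = _node_ids(cfg)
    label_names = [f"type{j:02d}" for j in range(cfg.m)]
    return Benchmark(network, Y, kinds, ids, label_names, cfg)


def export_fixture(benchmark: Benchmark, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture in the exact input dialects of net_builder:
    cci/cpi/ppi links TSVs (integer scores = weight x 1000), one-id-per-line
    rosters, and the node-to-label-set table. Returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = benchmark.network
    paths = {name: outdir / f"{name}.tsv" for name in ("cci", "cpi", "ppi")}
    handles = {name: open(path, "wt", encoding="utf-8") for name, path in paths.items()}
    try:
        for name in handles:
            handles[name].write("node1\tnode2\tscore\n")
        for u, v, w in sorted(net.graph.edges(data="weight")):
            ku, kv = net.kind(u), net.kind(v)
            score = int(round(w * 1000))
            if ku == kv:
                name = "cci" if ku == CHEMICAL else "ppi"
                handles[name].write(f"{u}\t{v}\t{score}\n")
            else:
                chem, enz = (u, v) if ku == CHEMICAL else (v, u)
                handles["cpi"].write(f"{chem}\t{enz}\t{score}\n")
    finally:
        for fh in handles.values():
            fh.close()
    paths["chemicals"] = outdir / "chemicals.txt"
    paths["enzymes"] = outdir / "enzymes.txt"
    paths["chemicals"].write_text("\n".join(net.chemicals) + "\n")
    paths["enzymes"].write_text("\n".join(net.enzymes) + "\n")
    paths["labels"] = outdir / "labels.tsv"
    with open(paths["labels"], "wt", encoding="utf-8") as fh:
        for node, row in zip(benchmark.node_ids, benchmark.labels):
            names = ";".join(
                benchmark.label_names[j] for j in np.flatnonzero(row)
            )
            fh.write(f"{node}\t{names}\n")
    return paths
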