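"""Heterogeneous lncRNA-disease network and metagraph-guided random walks.

The global network stacks the fused similarity blocks and the association
matrix into U = [[SL, A], [A^T, SD]].  Walkable edges are typed:

* ``LL`` / ``DD`` -- each node's top-k most similar same-type neighbours
  (self excluded, strictly positive similarity), symmetrised by union;
* ``LD`` / ``DL`` -- exactly the known associations (and their transposes).

A *metagraph* is a small acyclic schema over node types with a source and a
target of the same type; its recursive unrolling (restart at the target)
constrains which edge types a walk may follow.  Each step samples in two
stages, both uniform: first an edge type among the schema-legal types that
have at least one realisation at the current node, then a neighbour of that
type.  The walk terminates when no legal edge type remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .similarity import AssociationMatrix, SimilarityMatrix

__all__ = [
    "HeterogeneousNetwork",
    "MetaGraph",
    "WalkCorpus",
    "build_network",
    "legal_edge_types",
    "transition_distribution",
    "walk_step",
    "generate_corpus",
    "default_metagraph",
]

LNC = "lncRNA"
DIS = "disease"
_EDGE_TYPE = {(LNC, LNC): "LL", (LNC, DIS): "LD", (DIS, LNC): "DL", (DIS, DIS): "DD"}


@dataclass
class HeterogeneousNetwork:
    """Typed node table, per-node typed adjacency, and the dense matrix U."""

    node_ids: list[str]
    node_types: list[str]
    neighbors: list[dict[str, np.ndarray]]  # node index -> edge type -> sorted neighbour indices
    U: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        if len(self.node_types) != n or len(self.neighbors) != n:
            raise ValueError("node table and adjacency sizes disagree")
        if self.U.shape != (n, n):
            raise ValueError("U must be (nl+nd) x (nl+nd)")
        self._index = {v: i for i, v in enumerate(self.node_ids)}

    def index(self, node_id: str) -> int:
        return self._index[node_id]

    def typed_neighbors(self, v: int, edge_type: str) -> np.ndarray:
        return self.neighbors[v].get(edge_type, _EMPTY)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


_EMPTY = np.empty(0, dtype=np.int64)


@dataclass(frozen=True)
class MetaGraph:
    """Walk schema: typed nodes, directed edges, source and target.

    ``nodes`` maps schema node name -> node type; ``edges`` is a list of
    (src, dst) schema node pairs.  The schema must be acyclic and source and
    target must share a type (the walk restarts the schema at the target).
    """

    nodes: dict[str, str]
    edges: tuple[tuple[str, str], ...]
    source: str
    target: str

    def __post_init__(self) -> None:
        for name, t in self.nodes.items():
            if t not in (LNC, DIS):
                raise ValueError(f"schema node {name!r} has unknown type {t!r}")
        for s, d in self.edges:
            if s not in self.nodes or d not in self.nodes:
                raise ValueError(f"schema edge ({s}, {d}) references unknown node")
        if self.source not in self.nodes or self.target not in self.nodes:
            raise ValueError("source/target must be schema nodes")
        if self.nodes[self.source] != self.nodes[self.target]:
            raise ValueError("source and target must have the same node type")
        g = nx.DiGraph(list(self.edges))
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("metagraph must be acyclic")
        out: dict[str, list[tuple[str, str]]] = {n: [] for n in self.nodes}
        for s, d in self.edges:
            out[s].append((_EDGE_TYPE[(self.nodes[s], self.nodes[d])], d))
        object.__setattr__(self, "_out", out)

    def position(self, state: str) -> str:
        """Effective schema position: the target wraps around to the source."""
        return self.source if state == self.target else state

    def out_edges(self, state: str) -> list[tuple[str, str]]:
        """(edge_type, destination schema node) pairs leaving a position."""
        return self._out[self.position(state)]

    def to_text(self) -> str:
        lines = [f"node {n} {t}" for n, t in self.nodes.items()]
        lines += [f"edge {s} {d}" for s, d in self.edges]
        lines += [f"source {self.source}", f"target {self.target}"]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "MetaGraph":
        nodes: dict[str, str] = {}
        edges: list[tuple[str, str]] = []
        source = target = None
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if parts[0] == "node" and len(parts) == 3:
                nodes[parts[1]] = parts[2]
            elif parts[0] == "edge" and len(parts) == 3:
                edges.append((parts[1], parts[2]))
            elif parts[0] == "source" and len(parts) == 2:
                source = parts[1]
            elif parts[0] == "target" and len(parts) == 2:
                target = parts[1]
            else:
                raise ValueError(f"unparseable schema line: {raw!r}")
        if source is None or target is None:
            raise ValueError("schema must declare a source and a target")
        return cls(nodes, tuple(edges), source, target)


def default_metagraph() -> MetaGraph:
    """The default diamond schema: union of the L-D-L and L-D-D-L metapaths.

    L1 -> D1, D1 -> L2, D1 -> D2, D2 -> L2 with source L1 and target L2.
    The branch at D1 makes this a genuine metagraph rather than a metapath.
    """
    return MetaGraph(
        nodes={"L1": LNC, "D1": DIS, "L2": LNC, "D2": DIS},
        edges=(("L1", "D1"), ("D1", "L2"), ("D1", "D2"), ("D2", "L2")),
        source="L1",
        target="L2",
    )


@dataclass
class WalkCorpus:
    """Node-id sequences generated by metagraph-guided walks."""

    walks: list[list[str]]
    length_cap: int
    starts: list[str] = field(default_factory=list)
    seed: int | None = None

    def to_text(self) -> str:
        return "\n".join(" ".join(w) for w in self.walks) + "\n"

    @classmethod
    def from_text(cls, text: str, length_cap: int = 0) -> "WalkCorpus":
        walks = [line.split() for line in text.splitlines() if line.strip()]
        cap = length_cap or max((len(w) for w in walks), default=0)
        return cls(walks, cap, [w[0] for w in walks])


def _top_k_edges(S: np.ndarray, top_k: int) -> list[np.ndarray]:
    """Per-node top-k positive-similarity neighbours, symmetrised by union."""
    n = S.shape[0]
    chosen: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        row = S[i].copy()
        row[i] = -np.inf
        # stable, deterministic: sort by (-similarity, index)
        order = np.lexsort((np.arange(n), -row))
        picked = [j for j in order[:top_k] if row[j] > 0.0]
        for j in picked:
            chosen[i].add(j)
            chosen[j].add(i)
    return [np.array(sorted(c), dtype=np.int64) for c in chosen]


def build_network(SL: SimilarityMatrix, SD: SimilarityMatrix,
                  A: AssociationMatrix, top_k: int = 10) -> HeterogeneousNetwork:
    """Assemble U = [[SL, A], [A^T, SD]] and the typed walkable edge sets."""
    if top_k < 1:
        raise ValueError("top_k must be at least 1")
    nl, nd = A.nl, A.nd
    if SL.values.shape != (nl, nl) or SL.ids != A.lncrna_ids:
        raise ValueError("SL does not match the association matrix lncRNAs")
    if SD.values.shape != (nd, nd) or SD.ids != A.disease_ids:
        raise ValueError("SD does not match the association matrix diseases")
    Af = A.values.astype(float)
    U = np.block([[SL.values, Af], [Af.T, SD.values]])
    node_ids = list(A.lncrna_ids) + list(A.disease_ids)
    node_types = [LNC] * nl + [DIS] * nd
    ll = _top_k_edges(SL.values, top_k)
    dd = _top_k_edges(SD.values, top_k)
    neighbors: list[dict[str, np.ndarray]] = []
    for m in range(nl):
        entry: dict[str, np.ndarray] = {}
        if ll[m].size:
            entry["LL"] = ll[m]
        ld = np.nonzero(A.values[m])[0] + nl
        if ld.size:
            entry["LD"] = ld.astype(np.int64)
        neighbors.append(entry)
    for j in range(nd):
        entry = {}
        if dd[j].size:
            entry["DD"] = dd[j] + nl
        dl = np.nonzero(A.values[:, j])[0]
        if dl.size:
            entry["DL"] = dl.astype(np.int64)
        neighbors.append(entry)
    return HeterogeneousNetwork(node_ids, node_types, neighbors, U)


def legal_edge_types(state: str, v: int, G: HeterogeneousNetwork,
                     mg: MetaGraph) -> dict[str, list[str]]:
    """Schema-legal edge types with at least one realisation at node ``v``.

    Returns edge type -> destination schema nodes.  The size of the returned
    mapping is the NUM factor of the two-stage transition probability.
    """
    pos = mg.position(state)
    if mg.nodes[pos] != G.node_types[v]:
        raise ValueError(
            f"node {G.node_ids[v]!r} of type {G.node_types[v]} cannot occupy "
            f"schema position {pos!r} of type {mg.nodes[pos]}")
    legal: dict[str, list[str]] = {}
    for etype, dest in mg.out_edges(state):
        if G.typed_neighbors(v, etype).size:
            legal.setdefault(etype, []).append(dest)
    return legal


def transition_distribution(v: int, state: str, G: HeterogeneousNetwork,
                            mg: MetaGraph) -> dict[int, float]:
    """Per-neighbour next-step probabilities: 1/NUM times 1/(type degree)."""
    legal = legal_edge_types(state, v, G, mg)
    if not legal:
        return {}
    num = len(legal)
    probs: dict[int, float] = {}
    for etype in legal:
        nbrs = G.typed_neighbors(v, etype)
        p = 1.0 / (num * nbrs.size)
        for u in nbrs:
            probs[int(u)] = probs.get(int(u), 0.0) + p
    return probs


def walk_step(v: int, state: str, G: HeterogeneousNetwork, mg: MetaGraph,
              rng: np.random.Generator) -> tuple[int, str] | None:
    """One two-stage uniform step; ``None`` when the walk terminates."""
    legal = legal_edge_types(state, v, G, mg)
    if not legal:
        return None
    etypes = sorted(legal)
    etype = etypes[rng.integers(len(etypes))]
    dests = legal[etype]
    dest = dests[rng.integers(len(dests))] if len(dests) > 1 else dests[0]
    nbrs = G.typed_neighbors(v, etype)
    v_next = int(nbrs[rng.integers(nbrs.size)])
    return v_next, dest


def generate_corpus(G: HeterogeneousNetwork, mg: MetaGraph,
                    walks_per_node: int = 10, length: int = 80,
                    seed: int = 0) -> WalkCorpus:
    """Launch ``walks_per_node`` capped-length walks from every source-type node."""
    if walks_per_node < 1:
        raise ValueError("walks_per_node must be at least 1")
    if length < 2:
        raise ValueError("walk length cap must be at least 2")
    src_type = mg.nodes[mg.source]
    starts = [i for i, t in enumerate(G.node_types) if t == src_type]
    if not starts:
        raise ValueError(f"network has no node of source type {src_type!r}")
    rng = np.random.default_rng(seed)
    walks: list[list[str]] = []
    origins: list[str] = []
    for v0 in starts:
        for _ in range(walks_per_node):
            seq = [v0]
            state = mg.source
            while len(seq) < length:
                step = walk_step(seq[-1], state, G, mg, rng)
                if step is None:
                    break
                v, state = step
                seq.append(v)
            walks.append([G.node_ids[i] for i in seq])
            origins.append(G.node_ids[v0])
    return WalkCorpus(walks, length, origins, seed)
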