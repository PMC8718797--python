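"""Similarity matrices for the lncRNA-disease heterogeneous network.

Four similarity notions feed the network:

* **SSD** -- disease semantic similarity from a disease-ontology DAG.  Each
  disease contributes 1 to itself, and every ancestor contributes
  ``delta ** (hop distance)`` (with ``delta`` in (0, 1), default 0.5, and the
  max taken over descending paths).  Two diseases are similar in proportion
  to the contribution mass of their shared ancestors.
* **FSL** -- lncRNA functional similarity: two lncRNAs are similar if the
  disease sets they are associated with are semantically similar (best-match
  average of SSD across the two sets).
* **GSL / GSD** -- Gaussian interaction-profile (GIP) kernel similarity of
  lncRNAs (rows of the association matrix) and diseases (columns), with the
  kernel bandwidth normalised by the mean squared profile norm.
* **SL / SD** -- the fused networks: the semantic/functional value where it
  is non-zero, the GIP value where it is zero.

All outputs are symmetric matrices in [0, 1]; SSD, GSL, GSD, SL and SD carry
a unit diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AssociationMatrix",
    "DiseaseDAGSet",
    "SimilarityMatrix",
    "compute_contributions",
    "semantic_value",
    "disease_semantic_similarity",
    "lncrna_functional_similarity",
    "gip_bandwidth",
    "gip_similarity",
    "fuse",
]

_UNIT_DIAG_ROLES = frozenset({"SSD", "GSL", "GSD", "SL", "SD"})
_ROLES = frozenset({"FSL", "SSD", "GSL", "GSD", "SL", "SD"})
_SYM_TOL = 1e-10


@dataclass
class AssociationMatrix:
    """Binary lncRNA x disease incidence matrix with ordered labels.

    ``values[m, j] == 1`` iff lncRNA ``lncrna_ids[m]`` is associated with
    disease ``disease_ids[j]``.
    """

    values: np.ndarray
    lncrna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        vals = np.unique(self.values)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        self.lncrna_ids = [str(x) for x in self.lncrna_ids]
        self.disease_ids = [str(x) for x in self.disease_ids]
        nl, nd = self.values.shape
        if len(self.lncrna_ids) != nl or len(self.disease_ids) != nd:
            raise ValueError("label lists must match matrix dimensions")
        if len(set(self.lncrna_ids)) != nl or len(set(self.disease_ids)) != nd:
            raise ValueError("row/column labels must be unique")
        if (self.values.sum(axis=1) == 0).any():
            warnings.warn("association matrix has lncRNAs with no known disease",
                          stacklevel=2)
        if (self.values.sum(axis=0) == 0).any():
            warnings.warn("association matrix has diseases with no known lncRNA",
                          stacklevel=2)

    @property
    def nl(self) -> int:
        return self.values.shape[0]

    @property
    def nd(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_pairs(cls, pairs, lncrna_ids=None, disease_ids=None) -> "AssociationMatrix":
        """Build from an iterable of (lncRNA_id, disease_id), deduplicated.

        Label order defaults to first appearance; explicit orderings may be
        supplied (ids absent from ``pairs`` then become all-zero rows/cols).
        """
        pairs = [(str(l), str(d)) for l, d in pairs]
        seen = dict.fromkeys(pairs)  # dedupe, keep order
        if lncrna_ids is None:
            lncrna_ids = list(dict.fromkeys(l for l, _ in seen))
        if disease_ids is None:
            disease_ids = list(dict.fromkeys(d for _, d in seen))
        li = {l: i for i, l in enumerate(lncrna_ids)}
        di = {d: j for j, d in enumerate(disease_ids)}
        A = np.zeros((len(lncrna_ids), len(disease_ids)), dtype=np.int8)
        for l, d in seen:
            A[li[l], di[d]] = 1
        return cls(A, list(lncrna_ids), list(disease_ids))

    @classmethod
    def from_tsv(cls, path) -> "AssociationMatrix":
        """Read a two-column TSV edge list (``lncRNA_id<TAB>disease_id``).

        A header line is tolerated: if the first row reappears nowhere as an
        id pair and looks like column names, pandas' sniffing is skipped in
        favour of treating every line as data; duplicates are removed.
        """
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two tab-separated columns")
        first = tuple(df.iloc[0, :2])
        if first in {("lncRNA_id", "disease_id"), ("lncrna_id", "disease_id"),
                     ("lncRNA", "disease")}:
            df = df.iloc[1:]
        return cls.from_pairs(df.iloc[:, :2].itertuples(index=False, name=None))

    def pairs(self) -> list[tuple[str, str]]:
        rows, cols = np.nonzero(self.values)
        return [(self.lncrna_ids[m], self.disease_ids[j]) for m, j in zip(rows, cols)]


@dataclass
class DiseaseDAGSet:
    """Per-disease ancestor DAGs extracted from one global ontology graph.

    The ontology is stored as a directed graph with child -> parent edges.
    ``Z(i)`` (the disease plus all its ancestors) is the closure reachable
    from the disease along those edges.  Diseases absent from the edge list
    get the trivial one-node DAG.
    """

    graph: nx.DiGraph
    diseases: list[str]
    _closures: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.diseases = [str(d) for d in self.diseases]
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology graph contains a cycle")

    @classmethod
    def from_edges(cls, edges, diseases) -> "DiseaseDAGSet":
        g = nx.DiGraph()
        g.add_nodes_from(str(d) for d in diseases)
        g.add_edges_from((str(c), str(p)) for c, p in edges)
        return cls(g, list(diseases))

    @classmethod
    def from_tsv(cls, path, diseases) -> "DiseaseDAGSet":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two tab-separated columns")
        first = tuple(df.iloc[0, :2])
        if first in {("child_id", "parent_id"), ("child", "parent")}:
            df = df.iloc[1:]
        return cls.from_edges(df.iloc[:, :2].itertuples(index=False, name=None),
                              diseases)

    def closure(self, disease: str) -> set[str]:
        """Node set Z(i): the disease and all its ancestors."""
        disease = str(disease)
        if disease not in self.diseases:
            raise KeyError(f"no DAG for disease {disease!r}")
        if disease not in self._closures:
            if disease in self.graph:
                z = {disease} | nx.descendants(self.graph, disease)
            else:
                z = {disease}
            self._closures[disease] = z
        return self._closures[disease]

    def dag(self, disease: str) -> nx.DiGraph:
        """The child->parent DAG induced on Z(i)."""
        z = self.closure(disease)
        sub = self.graph.subgraph(z).copy() if z - {disease} else nx.DiGraph()
        sub.add_node(str(disease))
        return sub


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] with a role tag."""

    values: np.ndarray
    ids: list[str]
    role: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = [str(x) for x in self.ids]
        n = len(self.ids)
        if self.role not in _ROLES:
            raise ValueError(f"unknown similarity role {self.role!r}")
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match id list")
        if not np.isfinite(self.values).all():
            raise ValueError("similarity entries must be finite")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > _SYM_TOL:
            raise ValueError(f"matrix not symmetric (max asymmetry {asym:g})")
        # guard against negative-zero and tiny float overshoot
        self.values = np.clip(self.values, 0.0, 1.0) if (
            self.values.min() >= -_SYM_TOL and self.values.max() <= 1.0 + _SYM_TOL
        ) else self.values
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("similarity entries must lie in [0, 1]")
        if self.role in _UNIT_DIAG_ROLES and n and not np.allclose(
                np.diag(self.values), 1.0, atol=_SYM_TOL):
            raise ValueError(f"{self.role} requires a unit diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def compute_contributions(dags: DiseaseDAGSet, disease: str, delta: float = 0.5) -> dict[str, float]:
    """Contribution C_i(u) of every node u in Z(i) to disease i's semantics.

    The disease itself contributes 1; each ancestor contributes ``delta``
    times the largest contribution among its children (the nodes one hop
    closer to the disease), i.e. ``delta ** (shortest hop distance)``.
    Evaluated by dynamic programming in topological order outward from the
    disease.
    """
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must lie strictly between 0 and 1")
    disease = str(disease)
    z = dags.closure(disease)
    sub = dags.graph.subgraph(z)
    contrib: dict[str, float] = {disease: 1.0}
    if len(z) == 1:
        return contrib
    # child -> parent edges: topological order lists children before parents
    for u in nx.topological_sort(sub):
        if u == disease:
            continue
        preds = [c for c in sub.predecessors(u) if c in contrib]
        if not preds:  # unreachable from the disease; not part of Z by construction
            continue
        contrib[u] = delta * max(contrib[c] for c in preds)
    return contrib


def semantic_value(cmap: dict[str, float]) -> float:
    """Semantic value C(i): the sum of all ancestor contributions (>= 1)."""
    if not cmap:
        raise ValueError("contribution map is empty")
    return float(sum(cmap.values()))


def disease_semantic_similarity(dags: DiseaseDAGSet, delta: float = 0.5,
                                diseases: list[str] | None = None) -> SimilarityMatrix:
    """Semantic similarity SSD over shared ontology ancestors.

    SSD(i, j) = sum over u in Z(i) & Z(j) of (C_i(u) + C_j(u)) divided by
    (C(i) + C(j)); 1 on the diagonal, 0 for diseases with disjoint DAGs.
    """
    if diseases is None:
        diseases = list(dags.diseases)
    missing = [d for d in diseases if str(d) not in dags.diseases]
    if missing:
        raise KeyError(f"missing DAG for disease(s): {', '.join(map(str, missing))}")
    cmaps = [compute_contributions(dags, d, delta) for d in diseases]
    cvals = [semantic_value(c) for c in cmaps]
    n = len(diseases)
    ssd = np.eye(n)
    for i in range(n):
        zi = cmaps[i]
        for j in range(i + 1, n):
            zj = cmaps[j]
            shared = zi.keys() & zj.keys()
            if shared:
                num = sum(zi[u] + zj[u] for u in shared)
                ssd[i, j] = ssd[j, i] = num / (cvals[i] + cvals[j])
    return SimilarityMatrix(ssd, [str(d) for d in diseases], "SSD")


def lncrna_functional_similarity(A: AssociationMatrix, SSD: SimilarityMatrix) -> SimilarityMatrix:
    """Functional similarity FSL via best-match averaging of SSD.

    For lncRNAs with disease sets DL1 (size x) and DL2 (size y):
    FSL = (sum over d in DL2 of max SSD(d, DL1)
           + sum over d in DL1 of max SSD(d, DL2)) / (x + y).

    lncRNAs with no known disease get 0 off-diagonal (the fused network
    falls back to the GIP kernel there) and 0 on the diagonal, so fusion
    supplies the self-similarity.
    """
    if SSD.role != "SSD":
        raise ValueError("expected an SSD similarity matrix")
    idx = {d: j for j, d in enumerate(SSD.ids)}
    missing = [d for d in A.disease_ids if d not in idx]
    if missing:
        raise KeyError(f"SSD does not cover disease(s): {', '.join(missing)}")
    cols = np.array([idx[d] for d in A.disease_ids])
    S = SSD.values[np.ix_(cols, cols)]
    sets = [np.nonzero(A.values[m])[0] for m in range(A.nl)]
    empty = [m for m in range(A.nl) if sets[m].size == 0]
    if empty:
        warnings.warn(
            f"{len(empty)} lncRNA(s) have no associated disease; their "
            "functional similarity is 0 and fusion falls back to the GIP kernel",
            stacklevel=2)
    n = A.nl
    fsl = np.zeros((n, n))
    for m in range(n):
        dl1 = sets[m]
        if dl1.size == 0:
            continue
        fsl[m, m] = 1.0
        for k in range(m + 1, n):
            dl2 = sets[k]
            if dl2.size == 0:
                continue
            sub = S[np.ix_(dl1, dl2)]
            val = (sub.max(axis=0).sum() + sub.max(axis=1).sum()) / (dl1.size + dl2.size)
            fsl[m, k] = fsl[k, m] = min(val, 1.0)
    return SimilarityMatrix(fsl, A.lncrna_ids, "FSL")


def gip_bandwidth(profiles: np.ndarray, base_bandwidth: float = 1.0) -> float:
    """GIP kernel bandwidth: base bandwidth over the mean squared row norm."""
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] == 0:
        raise ValueError("need at least one profile row")
    if base_bandwidth <= 0:
        raise ValueError("base bandwidth must be positive")
    mean_sq = float((profiles ** 2).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise ValueError("all interaction profiles are zero; bandwidth undefined")
    return float(base_bandwidth) / mean_sq


def gip_similarity(A: AssociationMatrix, axis: str = "lncRNA",
                   base_bandwidth: float = 1.0) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel similarity (GSL or GSD).

    ``exp(-bandwidth * ||profile_a - profile_b||^2)`` over rows of A for
    ``axis='lncRNA'`` and over columns for ``axis='disease'``.
    """
    if axis == "lncRNA":
        profiles, ids, role = A.values.astype(float), A.lncrna_ids, "GSL"
    elif axis == "disease":
        profiles, ids, role = A.values.T.astype(float), A.disease_ids, "GSD"
    else:
        raise ValueError("axis must be 'lncRNA' or 'disease'")
    bw = gip_bandwidth(profiles, base_bandwidth)
    norms = (profiles ** 2).sum(axis=1)
    d2 = norms[:, None] + norms[None, :] - 2.0 * profiles @ profiles.T
    np.clip(d2, 0.0, None, out=d2)
    d2 = 0.5 * (d2 + d2.T)  # exact symmetry against float noise
    sim = np.exp(-bw * d2)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(sim, ids, role)


def fuse(primary: SimilarityMatrix, fallback: SimilarityMatrix,
         role: str | None = None) -> SimilarityMatrix:
    """Fused similarity: the primary value where non-zero, else the fallback.

    The zero test is structural (exact comparison with 0), since primary
    entries are 0 precisely when no semantic overlap exists.
    """
    if primary.ids != fallback.ids:
        raise ValueError("cannot fuse matrices with different id orderings")
    if role is None:
        role = {"FSL": "SL", "SSD": "SD"}.get(primary.role, "SL")
    out = np.where(primary.values != 0.0, primary.values, fallback.values)
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(out, primary.ids, role)
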