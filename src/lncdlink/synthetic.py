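"""Synthetic planted-block worlds for end-to-end testing without downloads.

The generator emulates the statistical structure the pipeline exploits:
lncRNAs and diseases belong to latent communities, associations are dense
within a community (``p_in``) and sparse across (``p_out``), and the disease
ontology forest is biased so that diseases of the same community share
ancestors (giving the semantic similarity its block structure).  A fraction
of the sampled associations is held out before anything else sees the
matrix, providing recoverable ground truth for ranking experiments.

Default sizes mirror the smallest real catalogue release this kind of
pipeline is run on (112 lncRNAs x 150 diseases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import AssociationMatrix, DiseaseDAGSet

__all__ = ["PlantedWorld", "generate"]


@dataclass
class PlantedWorld:
    """Parameters of the planted-community bipartite world.

    nl, nd: numbers of lncRNAs and diseases.
    n_communities: latent block count B (nodes assigned round-robin).
    p_in / p_out: association probability within / across communities.
    holdout_fraction: share of sampled associations removed as ground truth.
    ancestor forest: every disease gets 0-3 parents among its community's
    internal ontology terms (80% of draws stay in-community), depth <= 4.
    """

    nl: int = 112
    nd: int = 150
    n_communities: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    holdout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if self.nl < 2 * self.n_communities or self.nd < 2 * self.n_communities:
            raise ValueError("need at least two lncRNAs and diseases per community")
        if not 0.0 <= self.holdout_fraction < 1.0:
            raise ValueError("holdout fraction must lie in [0, 1)")


def _ancestor_forest(world: PlantedWorld, disease_ids, dis_comm,
                     rng: np.random.Generator):
    """Child->parent edges of a community-biased ontology forest (depth <= 4).

    Per community: one root, two mid-level terms under the root, three
    low-level terms each under a mid-level term.  Diseases attach to 0-3
    low/mid terms, drawn from their own community with probability 0.8.
    """
    B = world.n_communities
    edges: list[tuple[str, str]] = []
    attach_pool: list[list[str]] = []
    for b in range(B):
        root = f"term_{b}_root"
        mids = [f"term_{b}_mid{i}" for i in range(2)]
        lows = [f"term_{b}_low{i}" for i in range(3)]
        for m in mids:
            edges.append((m, root))
        for i, low in enumerate(lows):
            edges.append((low, mids[i % 2]))
        attach_pool.append(mids + lows)
    for j, d in enumerate(disease_ids):
        k = int(rng.integers(0, 4))  # 0-3 direct ancestors
        parents: set[str] = set()
        for _ in range(k):
            b = dis_comm[j] if rng.random() < 0.8 else int(rng.integers(0, B))
            pool = attach_pool[b]
            parents.add(pool[int(rng.integers(0, len(pool)))])
        for p in sorted(parents):
            edges.append((d, p))
    return edges


def generate(world: PlantedWorld):
    """Sample one world.

    Returns ``(A, dags, held_out)`` where ``A`` is the association matrix
    *after* holdout removal, ``dags`` the disease ancestor DAG set, and
    ``held_out`` the list of removed (lncRNA id, disease id) true positives.
    Deterministic given the world seed; if sampling leaves no positive
    association the seed is incremented and the draw repeated (at most 10
    times).
    """
    lnc_ids = [f"l{m}" for m in range(world.nl)]
    dis_ids = [f"d{j}" for j in range(world.nd)]
    B = world.n_communities
    lnc_comm = np.arange(world.nl) % B
    dis_comm = np.arange(world.nd) % B

    for attempt in range(10):
        seed = world.seed + attempt
        rng = np.random.default_rng(seed)
        same = lnc_comm[:, None] == dis_comm[None, :]
        prob = np.where(same, world.p_in, world.p_out)
        A_full = (rng.random((world.nl, world.nd)) < prob).astype(np.int8)
        ones = np.argwhere(A_full == 1)
        n_hold = int(np.floor(world.holdout_fraction * len(ones)))
        if len(ones) - n_hold < 1:
            continue
        hold_idx = rng.choice(len(ones), size=n_hold, replace=False)
        held_out = [(lnc_ids[m], dis_ids[j]) for m, j in ones[np.sort(hold_idx)]]
        A_vals = A_full.copy()
        for m, j in ones[hold_idx]:
            A_vals[m, j] = 0
        if A_vals.sum() < 1:
            continue
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # isolated rows/cols are expected here
            A = AssociationMatrix(A_vals, lnc_ids, dis_ids)
        edges = _ancestor_forest(world, dis_ids, dis_comm, rng)
        dags = DiseaseDAGSet.from_edges(edges, dis_ids)
        return A, dags, held_out
    raise RuntimeError("could not sample a world with at least one positive")
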