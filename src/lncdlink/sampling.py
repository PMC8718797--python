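"""Balanced negative-sample selection by K-means over pair feature vectors.

Known associations vastly outnumber unknown pairs' true negatives, so the
training set is balanced by clustering every *unknown* lncRNA-disease pair
and drawing negatives across clusters.  Each pair (l_m, d_j) is described by
the four-block concatenation

    [ SL row m | A column j | A row m | SD row j ]

of length 2(nl + nd).  Lloyd's algorithm (random centers chosen from the
points, assign, recompute means, repeat until assignments stabilise) groups
the unknown pairs into k clusters; negatives are then drawn from each
cluster with a quota proportional to cluster size (largest-remainder
rounding) and uniformly without replacement within a cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .similarity import AssociationMatrix, SimilarityMatrix

__all__ = [
    "KMeansModel",
    "LabeledPairSet",
    "unknown_pairs",
    "build_pair_features",
    "kmeans",
    "select_negatives",
    "assemble_training_set",
]


@dataclass
class KMeansModel:
    """Fitted Lloyd clustering: centroids, assignments and diagnostics."""

    centroids: np.ndarray
    labels: np.ndarray
    inertia: float
    n_iter: int
    converged: bool
    history: list = field(default_factory=list)  # objective after each assignment

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class LabeledPairSet:
    """(lncRNA id, disease id, label) triples with per-negative provenance."""

    frame: pd.DataFrame  # columns: lncRNA, disease, label, cluster

    def __post_init__(self) -> None:
        required = {"lncRNA", "disease", "label"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"pair set frame needs columns {sorted(required)}")
        if "cluster" not in self.frame.columns:
            self.frame = self.frame.assign(cluster=-1)
        dup = self.frame.duplicated(subset=["lncRNA", "disease"])
        if dup.any():
            raise ValueError("duplicate pairs in labeled set")
        if not self.frame["label"].isin([0, 1]).all():
            raise ValueError("labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.frame["lncRNA"], self.frame["disease"]))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LabeledPairSet":
        return cls(pd.read_csv(path, sep="\t", dtype={"lncRNA": str, "disease": str}))


def unknown_pairs(A: AssociationMatrix) -> list[tuple[int, int]]:
    """All (lncRNA index, disease index) pairs with no known association."""
    rows, cols = np.nonzero(A.values == 0)
    return list(zip(rows.tolist(), cols.tolist()))


def build_pair_features(SL: SimilarityMatrix, SD: SimilarityMatrix,
                        A: AssociationMatrix, pairs) -> np.ndarray:
    """Four-block pair feature matrix, one row of length 2(nl+nd) per pair."""
    nl, nd = A.nl, A.nd
    if SL.values.shape != (nl, nl) or SD.values.shape != (nd, nd):
        raise ValueError("similarity matrices do not match the association matrix")
    pairs = list(pairs)
    m_idx = np.array([p[0] for p in pairs], dtype=int)
    j_idx = np.array([p[1] for p in pairs], dtype=int)
    if pairs and (m_idx.min() < 0 or m_idx.max() >= nl or j_idx.min() < 0 or j_idx.max() >= nd):
        raise IndexError("pair index out of range")
    Af = A.values.astype(float)
    return np.hstack([
        SL.values[m_idx],   # block 1: lncRNA similarity row   (len nl)
        Af[:, j_idx].T,     # block 2: A column of the disease (len nl)
        Af[m_idx, :],       # block 3: A row of the lncRNA     (len nd)
        SD.values[j_idx],   # block 4: disease similarity row  (len nd)
    ])


def _lloyd(points: np.ndarray, init_idx: np.ndarray, max_iter: int):
    """One Lloyd run from given initial centers; returns (model fields)."""
    n = points.shape[0]
    centroids = points[init_idx].copy()
    norms = (points ** 2).sum(axis=1)
    labels = np.full(n, -1, dtype=np.int64)
    converged = False
    it = 0
    history: list[float] = []
    for it in range(1, max_iter + 1):
        d2 = norms[:, None] - 2.0 * points @ centroids.T + (centroids ** 2).sum(axis=1)
        new_labels = np.argmin(d2, axis=1)
        history.append(float(np.maximum(d2[np.arange(n), new_labels], 0.0).sum()))
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
        for c in range(centroids.shape[0]):
            members = labels == c
            if members.any():
                centroids[c] = points[members].mean(axis=0)
            else:
                # deterministic repair: re-seed from the point farthest
                # from its current centroid
                dist_own = d2[np.arange(n), labels]
                far = int(np.argmax(dist_own))
                centroids[c] = points[far]
                labels[far] = c
    d2 = norms[:, None] - 2.0 * points @ centroids.T + (centroids ** 2).sum(axis=1)
    labels = np.argmin(d2, axis=1)
    inertia = float(np.maximum(d2[np.arange(n), labels], 0.0).sum())
    return centroids, labels, inertia, it, converged, history


def kmeans(points: np.ndarray, k: int, seed: int = 0, max_iter: int = 300,
           restarts: int = 10) -> KMeansModel:
    """Lloyd's K-means with best-of-restarts, deterministic for a given seed.

    Initial centers are drawn (without replacement) from the points.  Empty
    clusters are repaired by re-seeding from the point farthest from its
    centroid.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array")
    n = points.shape[0]
    if k < 1:
        raise ValueError("k must be at least 1")
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        init_idx = rng.choice(n, size=k, replace=False)
        centroids, labels, inertia, n_iter, converged, history = _lloyd(
            points, init_idx, max_iter)
        if best is None or inertia < best.inertia - 1e-12:
            best = KMeansModel(centroids, labels, inertia, n_iter, converged, history)
    return best


def _largest_remainder_quotas(sizes: np.ndarray, n_needed: int) -> np.ndarray:
    """Proportional quotas summing exactly to n_needed, capped by cluster size."""
    sizes = np.asarray(sizes, dtype=int)
    total = int(sizes.sum())
    if n_needed > total:
        raise ValueError(f"cannot draw {n_needed} negatives from {total} pairs")
    exact = n_needed * sizes / total
    quotas = np.floor(exact).astype(int)
    remainder = n_needed - int(quotas.sum())
    # distribute leftovers by descending fractional part, ties to lower id
    frac_order = np.lexsort((np.arange(sizes.size), -(exact - quotas)))
    for c in frac_order:
        if remainder == 0:
            break
        if quotas[c] < sizes[c]:
            quotas[c] += 1
            remainder -= 1
    # cap at cluster size and push overflow to clusters with room
    while True:
        over = quotas - sizes
        excess = int(over[over > 0].sum())
        if excess == 0:
            break
        quotas = np.minimum(quotas, sizes)
        room = np.nonzero(quotas < sizes)[0]
        for c in room:
            if excess == 0:
                break
            take = min(excess, sizes[c] - quotas[c])
            quotas[c] += take
            excess -= take
    return quotas


def select_negatives(model: KMeansModel, pairs, n_needed: int, seed: int = 0,
                     pair_ids=None, allocation: str = "proportional") -> pd.DataFrame:
    """Draw ``n_needed`` negatives across clusters.

    ``pairs`` are the clustered unknown pairs, aligned with ``model.labels``.
    ``pair_ids`` optionally maps index pairs to (lncRNA id, disease id).
    ``allocation`` is 'proportional' (largest-remainder, the default) or
    'equal' (same quota per cluster, remainder to the largest clusters).
    """
    pairs = list(pairs)
    if len(pairs) != model.labels.size:
        raise ValueError("pairs and cluster assignment sizes disagree")
    if n_needed > len(pairs):
        raise ValueError(f"requested {n_needed} negatives but only {len(pairs)} available")
    sizes = model.cluster_sizes()
    if allocation == "proportional":
        quotas = _largest_remainder_quotas(sizes, n_needed)
    elif allocation == "equal":
        base = np.minimum(np.full(model.k, n_needed // model.k), sizes)
        quotas = base
        short = n_needed - int(quotas.sum())
        order = np.lexsort((np.arange(model.k), -sizes))
        for c in order:
            if short == 0:
                break
            take = min(short, sizes[c] - quotas[c])
            quotas[c] += take
            short -= take
    else:
        raise ValueError("allocation must be 'proportional' or 'equal'")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(model.k):
        if quotas[c] == 0:
            continue
        members = np.nonzero(model.labels == c)[0]
        picked = rng.choice(members, size=int(quotas[c]), replace=False)
        for p in np.sort(picked):
            m, j = pairs[p]
            lid, did = pair_ids(m, j) if pair_ids else (str(m), str(j))
            rows.append({"lncRNA": lid, "disease": did, "label": 0, "cluster": int(c)})
    return pd.DataFrame(rows, columns=["lncRNA", "disease", "label", "cluster"])


def assemble_training_set(A: AssociationMatrix, negatives: pd.DataFrame) -> LabeledPairSet:
    """All known associations (label 1) plus the selected negatives (label 0)."""
    pos_pairs = A.pairs()
    if not pos_pairs:
        raise ValueError("association matrix has no positive pair")
    pos = pd.DataFrame(
        [{"lncRNA": l, "disease": d, "label": 1, "cluster": -1} for l, d in pos_pairs])
    pos_set = set(pos_pairs)
    neg_pairs = set(zip(negatives["lncRNA"], negatives["disease"]))
    overlap = pos_set & neg_pairs
    if overlap:
        raise ValueError(f"negatives overlap known positives: {sorted(overlap)[:5]}")
    if len(negatives) != len(pos):
        raise ValueError(
            f"training set must be balanced: {len(pos)} positives vs "
            f"{len(negatives)} negatives")
    frame = pd.concat([pos, negatives], ignore_index=True)
    return LabeledPairSet(frame)
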