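"""The three clustering algorithms and the nine-approach grid runner.

The grid crosses three data variants (Bray-Curtis on log abundance, Sorensen
on presence/absence, Euclidean on log-chord abundance) with three algorithms
(Ward hierarchical, K-means, PAM).  K-means needs coordinates; the log-chord
variant supplies them directly, while the two matrix-only variants are bridged
through classical principal-coordinates analysis (all positive axes kept).

PAM is the classic BUILD + SWAP algorithm on the dissimilarity matrix and is
fully deterministic; Ward follows the ward.D2 convention (squared
dissimilarities in the Lance-Williams update).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

from .community import (AbundanceTable, AnalysisConfig, log_chord_transform,
                        log_transform, to_presence_absence)
from .dissimilarity import DissimilarityMatrix, bray_curtis, euclidean, sorensen

__all__ = [
    "ApproachSpec",
    "Partition",
    "Embedding",
    "ward_hierarchical",
    "pam",
    "pcoa_embed",
    "kmeans",
    "run_approach",
    "run_grid",
    "ALL_APPROACHES",
    "linkage_to_newick",
]

DATA_VARIANTS = ("log_bray", "sorensen", "log_chord")
ALGORITHMS = ("ward_hier", "kmeans", "pam")


@dataclass(frozen=True)
class ApproachSpec:
    """One cell of the 3 dissimilarities × 3 algorithms grid."""

    data_variant: str
    algorithm: str

    def __post_init__(self) -> None:
        if self.data_variant not in DATA_VARIANTS:
            raise ValueError(f"unknown data_variant {self.data_variant!r}")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    def __str__(self) -> str:
        return f"{self.data_variant}:{self.algorithm}"

    @classmethod
    def parse(cls, s: str) -> "ApproachSpec":
        variant, _, algo = s.partition(":")
        return cls(variant, algo)


ALL_APPROACHES: tuple[ApproachSpec, ...] = tuple(
    ApproachSpec(v, a) for v in DATA_VARIANTS for a in ALGORITHMS
)


@dataclass(frozen=True)
class Partition:
    """Assignment of every sample to one of K clusters, labels 1..K."""

    sample_ids: tuple[str, ...]
    labels: np.ndarray
    k: int
    approach: ApproachSpec | None = None
    seed: int | None = None
    medoids: tuple[str, ...] | None = None
    linkage: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if len(labels) != len(self.sample_ids):
            raise ValueError("labels and sample_ids length mismatch")
        present = np.unique(labels)
        if labels.size and (labels.min() < 1 or labels.max() > self.k):
            raise ValueError("labels must lie in 1..k")
        if len(present) != self.k:
            raise ValueError(f"partition has {len(present)} non-empty clusters, expected k={self.k}")
        labels.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([self.labels[pos[s]] for s in sample_ids], dtype=int)

    def cluster_sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": list(self.sample_ids),
                             "cluster": self.labels.astype(int)})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, approach: ApproachSpec | None = None) -> "Partition":
        df = pd.read_csv(path)
        labels = df["cluster"].to_numpy(dtype=int)
        return cls(tuple(df["sample_id"].astype(str)), labels,
                   k=int(len(np.unique(labels))), approach=approach)


def _relabel_canonical(raw: np.ndarray) -> tuple[np.ndarray, int]:
    """Map arbitrary labels to 1..K in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, v in enumerate(raw):
        if v not in mapping:
            mapping[v] = len(mapping) + 1
        out[i] = mapping[v]
    return out, len(mapping)


# ---------------------------------------------------------------------------
# Ward hierarchical clustering
# ---------------------------------------------------------------------------

def ward_linkage(d: DissimilarityMatrix) -> np.ndarray:
    """Ward (D2 convention) linkage matrix from a dissimilarity matrix."""
    z = hierarchy.linkage(d.condensed(), method="ward")
    heights = z[:, 2]
    if np.any(np.diff(heights) < -1e-9):
        raise RuntimeError("non-monotone merge heights under Ward linkage")
    return z


def ward_hierarchical(d: DissimilarityMatrix, k: int,
                      linkage: np.ndarray | None = None) -> Partition:
    """Cut the Ward merge tree at k clusters."""
    if k > d.n:
        raise ValueError(f"k={k} exceeds n={d.n}")
    z = ward_linkage(d) if linkage is None else linkage
    raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    labels, k_eff = _relabel_canonical(raw)
    if k_eff != k:
        # tied heights can make maxclust fall short; cut by height rank instead
        order = np.argsort(z[:, 2])[::-1]
        raw = hierarchy.cut_tree(z, n_clusters=k).ravel() + 1
        labels, k_eff = _relabel_canonical(raw)
        if k_eff != k:
            raise RuntimeError(f"could not obtain exactly {k} clusters from the tree")
    return Partition(d.sample_ids, labels, k=k,
                     approach=None, linkage=z)


def linkage_to_newick(z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string (heights as branch lengths)."""
    tree = hierarchy.to_tree(z)

    def build(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.10g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return build(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# PAM (partitioning around medoids)
# ---------------------------------------------------------------------------

def _pam_build(d: np.ndarray, k: int) -> list[int]:
    n = d.shape[0]
    totals = d.sum(axis=1)
    medoids = [int(np.argmin(totals))]          # ties -> lowest index via argmin
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.clip(nearest[:, None] - d, 0.0, None).sum(axis=0)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        nearest = np.minimum(nearest, d[:, c])
    return medoids


def _pam_swap(d: np.ndarray, medoids: list[int]) -> list[int]:
    n = d.shape[0]
    medoids = sorted(medoids)
    while True:
        med = np.array(medoids)
        dm = d[:, med]                       # n × k
        order = np.argsort(dm, axis=1)
        nearest = dm[np.arange(n), order[:, 0]]
        if len(medoids) > 1:
            second = dm[np.arange(n), order[:, 1]]
        else:
            second = np.full(n, np.inf)
        nearest_med = med[order[:, 0]]
        cost = nearest.sum()
        best = (0.0, None, None)             # (delta, m_idx, h)
        non_medoids = np.setdiff1d(np.arange(n), med)
        for mi, m in enumerate(med):
            is_m = nearest_med == m
            # removing m: points served by m fall back to their second-best
            base = np.where(is_m, second, nearest)
            for h in non_medoids:
                new_cost = np.minimum(base, d[:, h]).sum()
                delta = new_cost - cost
                if delta < best[0] - 1e-12:
                    best = (delta, mi, int(h))
        if best[1] is None:
            return medoids
        medoids[best[1]] = best[2]
        medoids = sorted(medoids)


def pam(d: DissimilarityMatrix, k: int) -> Partition:
    """Classic deterministic PAM: greedy BUILD then steepest-descent SWAP."""
    n = d.n
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    dv = d.values
    medoids = _pam_build(dv, k)
    build_cost = dv[:, medoids].min(axis=1).sum()
    medoids = _pam_swap(dv, medoids)
    final_cost = dv[:, medoids].min(axis=1).sum()
    if final_cost > build_cost + 1e-9:
        raise RuntimeError("PAM SWAP increased the cost")  # pragma: no cover
    med = np.array(sorted(medoids))
    assign = med[np.argmin(dv[:, med], axis=1)]
    labels, k_eff = _relabel_canonical(assign)
    medoid_ids = tuple(d.sample_ids[m] for m in med)
    return Partition(d.sample_ids, labels, k=k_eff, medoids=medoid_ids)


def pam_cost(d: DissimilarityMatrix, medoid_indices: Sequence[int]) -> float:
    """Total dissimilarity of every sample to its nearest medoid."""
    med = np.asarray(medoid_indices, dtype=int)
    return float(d.values[:, med].min(axis=1).sum())


# ---------------------------------------------------------------------------
# PCoA embedding and K-means
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Embedding:
    """Classical-scaling coordinates (positive-eigenvalue axes only)."""

    sample_ids: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    negative_inertia_fraction: float = 0.0


def pcoa_embed(d: DissimilarityMatrix, rel_tol: float = 1e-9) -> Embedding:
    """Classical (metric) multidimensional scaling of a dissimilarity matrix.

    Double-centres the squared dissimilarities, eigendecomposes, and keeps the
    axes whose eigenvalue exceeds ``rel_tol`` times the largest one.  When the
    matrix is Euclidean-embeddable the embedded pairwise distances reproduce it
    exactly; otherwise the dropped negative-eigenvalue inertia is reported.
    """
    n = d.n
    if n < 3:
        raise ValueError("pcoa_embed requires at least 3 samples")
    d2 = d.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval[0] <= 0:
        raise ValueError("no positive eigenvalues; dissimilarity carries no metric signal")
    keep = eigval > rel_tol * eigval[0]
    neg = eigval[eigval < 0]
    neg_fraction = float(-neg.sum() / np.abs(eigval).sum()) if neg.size else 0.0
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    return Embedding(d.sample_ids, coords, eigval[keep], neg_fraction)


def kmeans(x: np.ndarray, k: int, sample_ids: Sequence[str],
           n_init: int = 25, seed: int | None = None,
           max_iter: int = 300, tol: float = 1e-6) -> Partition:
    """K-means (k-means++ restarts, Lloyd iterations, best WSS kept)."""
    x = np.asarray(x, dtype=float)
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds n={x.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed,
                max_iter=max_iter, tol=tol, init="k-means++", algorithm="lloyd")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")     # duplicate-point convergence chatter
        raw = km.fit_predict(x)
    labels, k_eff = _relabel_canonical(raw + 1)
    return Partition(tuple(sample_ids), labels, k=k_eff, seed=seed)


# ---------------------------------------------------------------------------
# The nine-approach runner
# ---------------------------------------------------------------------------

def prepare_variant(table: AbundanceTable, data_variant: str,
                    cfg: AnalysisConfig) -> tuple[DissimilarityMatrix, np.ndarray]:
    """Dissimilarity matrix and K-means coordinates for one data variant."""
    if data_variant == "log_bray":
        d = bray_curtis(log_transform(table, cfg))
        coords = pcoa_embed(d).coordinates
    elif data_variant == "sorensen":
        d = sorensen(to_presence_absence(table))
        coords = pcoa_embed(d).coordinates
    elif data_variant == "log_chord":
        lc = log_chord_transform(table, cfg)
        d = euclidean(lc)
        coords = lc.values
    else:
        raise ValueError(f"unknown data_variant {data_variant!r}")
    return d, coords


def run_approach(table: AbundanceTable, spec: ApproachSpec, k: int,
                 cfg: AnalysisConfig, seed: int | None = None,
                 _prepared: tuple[DissimilarityMatrix, np.ndarray] | None = None,
                 ) -> Partition:
    """Transform → dissimilarity/embedding → algorithm, per the approach spec.

    ``table`` is the curated raw table; each variant applies its own transform.
    """
    if table.transform_state != "raw":
        raise ValueError("run_approach expects the curated raw table")
    if seed is None:
        seed = cfg.rng_seed
    d, coords = _prepared if _prepared is not None else prepare_variant(
        table, spec.data_variant, cfg)
    if spec.algorithm == "ward_hier":
        part = ward_hierarchical(d, k)
    elif spec.algorithm == "pam":
        part = pam(d, k)
    elif spec.algorithm == "kmeans":
        part = kmeans(coords, k, table.sample_ids, n_init=cfg.kmeans_n_init,
                      seed=seed, max_iter=cfg.kmeans_max_iter, tol=cfg.kmeans_tol)
    else:  # pragma: no cover
        raise ValueError(spec.algorithm)
    return Partition(part.sample_ids, part.labels, part.k, approach=spec,
                     seed=part.seed, medoids=part.medoids, linkage=part.linkage)


def run_grid(table: AbundanceTable, cfg: AnalysisConfig,
             approaches: Sequence[ApproachSpec] = ALL_APPROACHES,
             ) -> list[Partition]:
    """All approaches × K = kmin..kmax (the 9 × 19 grid at the defaults).

    Transforms, dissimilarities, embeddings, and Ward trees are computed once
    per data variant and shared across K.
    """
    prepared = {v: prepare_variant(table, v, cfg)
                for v in {a.data_variant for a in approaches}}
    linkages = {v: ward_linkage(prepared[v][0])
                for v in prepared
                if any(a.data_variant == v and a.algorithm == "ward_hier"
                       for a in approaches)}
    out: list[Partition] = []
    for spec in approaches:
        d, coords = prepared[spec.data_variant]
        for k in range(cfg.kmin, cfg.kmax + 1):
            if spec.algorithm == "ward_hier":
                part = ward_hierarchical(d, k, linkage=linkages[spec.data_variant])
                part = Partition(part.sample_ids, part.labels, part.k,
                                 approach=spec, linkage=part.linkage)
            else:
                part = run_approach(table, spec, k, cfg, _prepared=(d, coords))
            out.append(part)
    return out
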