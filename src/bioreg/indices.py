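"""Ten goodness-of-clustering indices for community partitions.

Five indices read the (log-transformed) abundance table — IndVal, ISAMIC,
OptimClass, TABDEV, TOTCHI — and five read the log-chord dissimilarity
matrix — DISDIAM, PARTANA, silhouette, within-cluster sum of squares, and
Calinski-Harabasz.  Every partition is evaluated on the *same* inputs (the
log table and the log-chord dissimilarity of the curated data) regardless of
which approach produced it, so index values are comparable across approaches.

Each index declares a ranking direction (higher- or lower-is-better) used by
the selection protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .community import AbundanceTable
from .cluster import Partition
from .dissimilarity import DissimilarityMatrix

__all__ = [
    "IndexResult",
    "INDEX_DIRECTIONS",
    "INDEX_NAMES",
    "indval_total",
    "isamic",
    "optimclass",
    "tabdev",
    "totchi",
    "disdiam",
    "partana_ratio",
    "avg_silhouette",
    "wss_from_dissimilarity",
    "calinski_harabasz",
    "evaluate_partition",
]

#: ranking direction per index; "higher" = higher values indicate a better partition
INDEX_DIRECTIONS: dict[str, str] = {
    "indval": "higher_better",
    "isamic": "higher_better",
    "optimclass": "higher_better",
    "tabdev": "lower_better",
    "totchi": "lower_better",
    "disdiam": "lower_better",
    "partana": "higher_better",
    "silhouette": "higher_better",
    "wss": "lower_better",
    "calinski_harabasz": "higher_better",
}
INDEX_NAMES = tuple(INDEX_DIRECTIONS)


@dataclass(frozen=True)
class IndexResult:
    index_name: str
    value: float            # NaN when undefined; +inf allowed where flagged
    direction: str
    k: int
    approach: object = None

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.value))


def _groups(labels: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(labels == c) for c in np.unique(labels)]


def _cluster_matrix(labels: np.ndarray) -> np.ndarray:
    """K × n indicator matrix."""
    clusters = np.unique(labels)
    return (labels[None, :] == clusters[:, None]).astype(float)


# ---------------------------------------------------------------------------
# abundance-table indices
# ---------------------------------------------------------------------------

def indval_total(log_table: AbundanceTable, partition: Partition) -> IndexResult:
    """Mean over species of the maximal indicator value (0–100).

    For species j and cluster c, specificity A = mean abundance in c divided
    by the sum over clusters of mean abundances; fidelity B = fraction of the
    cluster's samples containing j; IndVal = 100·A·B, and each species scores
    its best cluster.
    """
    x = log_table.values
    labels = partition.labels_for(log_table.sample_ids)
    ind = _cluster_matrix(labels)                       # K × n
    sizes = ind.sum(axis=1)
    mean_ab = (ind @ x) / sizes[:, None]                # K × S
    col = mean_ab.sum(axis=0)
    absent = col == 0
    if absent.any():
        warnings.warn(f"{int(absent.sum())} species absent everywhere score 0 in IndVal")
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(col[None, :] > 0, mean_ab / np.where(col == 0, 1.0, col)[None, :], 0.0)
    b = (ind @ (x > 0)) / sizes[:, None]
    iv = 100.0 * a * b
    score = iv.max(axis=0)
    return IndexResult("indval", float(score.mean()), INDEX_DIRECTIONS["indval"],
                       partition.k, partition.approach)


def isamic(pa_table: AbundanceTable, partition: Partition) -> IndexResult:
    """Mean species constancy extremeness: 2·mean_k |constancy − 0.5| per species."""
    x = (pa_table.values > 0).astype(float)
    labels = partition.labels_for(pa_table.sample_ids)
    ind = _cluster_matrix(labels)
    sizes = ind.sum(axis=1)
    constancy = (ind @ x) / sizes[:, None]              # K × S
    score = 2.0 * np.abs(constancy - 0.5).mean(axis=0)
    return IndexResult("isamic", float(score.mean()), INDEX_DIRECTIONS["isamic"],
                       partition.k, partition.approach)


def optimclass(pa_table: AbundanceTable, partition: Partition,
               alpha: float = 0.001) -> IndexResult:
    """Count of species×cluster pairs with a one-sided Fisher p below alpha.

    The test asks whether a species' presences are enriched in the cluster:
    upper hypergeometric tail of the 2×2 presence/membership table.  Species
    present in all or in no samples get p = 1 by convention.
    """
    x = (pa_table.values > 0)
    labels = partition.labels_for(pa_table.sample_ids)
    ind = _cluster_matrix(labels).astype(bool)
    n = x.shape[0]
    total_pres = x.sum(axis=0)                          # per species
    sizes = ind.sum(axis=1)                             # per cluster
    in_cluster = ind.astype(float) @ x                  # K × S presences inside
    # hypergeom.sf(k-1, M, n_draws=K_j, N=n_c): P(X >= k)
    kk, ss = np.meshgrid(sizes, total_pres, indexing="ij")
    with np.errstate(invalid="ignore"):
        p = hypergeom.sf(in_cluster - 1, n, ss, kk)
    degenerate = (total_pres == 0) | (total_pres == n)
    p[:, degenerate] = 1.0
    count = int((p < alpha).sum())
    return IndexResult("optimclass", float(count), INDEX_DIRECTIONS["optimclass"],
                       partition.k, partition.approach)


def tabdev(pa_table: AbundanceTable, partition: Partition) -> IndexResult:
    """Summed binomial deviance of presence patterns given cluster occurrence rates."""
    x = (pa_table.values > 0).astype(float)
    labels = partition.labels_for(pa_table.sample_ids)
    ind = _cluster_matrix(labels)
    sizes = ind.sum(axis=1)[:, None]                    # K × 1
    njk = ind @ x                                       # K × S
    p = njk / sizes
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(njk > 0, njk * np.log(p), 0.0)
        t2 = np.where(sizes - njk > 0, (sizes - njk) * np.log(1.0 - p), 0.0)
    dev = -2.0 * (t1 + t2).sum()
    return IndexResult("tabdev", float(dev), INDEX_DIRECTIONS["tabdev"],
                       partition.k, partition.approach)


def _ca_inertia(sub: np.ndarray) -> float:
    """Correspondence-analysis total inertia: chi-square statistic / grand total."""
    sub = sub[sub.sum(axis=1) > 0][:, sub.sum(axis=0) > 0]
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        return 0.0
    total = sub.sum()
    expected = np.outer(sub.sum(axis=1), sub.sum(axis=0)) / total
    chi2 = ((sub - expected) ** 2 / expected).sum()
    return float(chi2 / total)


def totchi(log_table: AbundanceTable, partition: Partition) -> IndexResult:
    """Total chi-square inertia of each cluster's subtable, summed over clusters."""
    x = log_table.values
    labels = partition.labels_for(log_table.sample_ids)
    value = sum(_ca_inertia(x[idx]) for idx in _groups(labels))
    return IndexResult("totchi", float(value), INDEX_DIRECTIONS["totchi"],
                       partition.k, partition.approach)


# ---------------------------------------------------------------------------
# dissimilarity-matrix indices
# ---------------------------------------------------------------------------

def _aligned_labels(d: DissimilarityMatrix, partition: Partition) -> np.ndarray:
    return partition.labels_for(d.sample_ids)


def disdiam(d: DissimilarityMatrix, partition: Partition) -> IndexResult:
    """Mean per-cluster diameter (max within-cluster dissimilarity; singletons 0)."""
    labels = _aligned_labels(d, partition)
    diams = []
    for idx in _groups(labels):
        diams.append(0.0 if len(idx) < 2 else float(d.values[np.ix_(idx, idx)].max()))
    return IndexResult("disdiam", float(np.mean(diams)), INDEX_DIRECTIONS["disdiam"],
                       partition.k, partition.approach)


def partana_ratio(d: DissimilarityMatrix, partition: Partition) -> IndexResult:
    """Mean between-cluster over mean within-cluster dissimilarity."""
    labels = _aligned_labels(d, partition)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    within = d.values[iu][same[iu]]
    between = d.values[iu][~same[iu]]
    if within.size == 0:
        raise ValueError("PARTANA undefined: every cluster is a singleton")
    if between.size == 0:
        raise ValueError("PARTANA undefined for a single cluster")
    wm = within.mean()
    value = np.inf if wm == 0 else float(between.mean() / wm)
    return IndexResult("partana", value, INDEX_DIRECTIONS["partana"],
                       partition.k, partition.approach)


def avg_silhouette(d: DissimilarityMatrix, partition: Partition) -> IndexResult:
    """Mean silhouette width; members of singleton clusters contribute 0."""
    labels = _aligned_labels(d, partition)
    n = len(labels)
    clusters = np.unique(labels)
    ind = _cluster_matrix(labels)                       # K × n
    sizes = ind.sum(axis=1)
    sums = ind @ d.values                               # K × n: sum of d to each cluster
    s = np.zeros(n)
    for i in range(n):
        c = np.flatnonzero(clusters == labels[i])[0]
        if sizes[c] <= 1:
            continue                                    # singleton convention: s = 0
        a = sums[c, i] / (sizes[c] - 1)
        other = [sums[cc, i] / sizes[cc] for cc in range(len(clusters)) if cc != c]
        b = min(other)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return IndexResult("silhouette", float(s.mean()), INDEX_DIRECTIONS["silhouette"],
                       partition.k, partition.approach)


def wss_from_dissimilarity(d: DissimilarityMatrix, partition: Partition) -> IndexResult:
    """WSS = sum over clusters of (1 / 2 n_k) * sum of squared within-cluster d.

    The inner sum runs over ordered pairs, so on Euclidean dissimilarities this
    equals the coordinate-based sum of squared distances to cluster centroids.
    """
    labels = _aligned_labels(d, partition)
    total = 0.0
    for idx in _groups(labels):
        sub = d.values[np.ix_(idx, idx)]
        total += (sub ** 2).sum() / (2.0 * len(idx))
    return IndexResult("wss", float(total), INDEX_DIRECTIONS["wss"],
                       partition.k, partition.approach)


def calinski_harabasz(d: DissimilarityMatrix, partition: Partition) -> IndexResult:
    """CH = (BSS / (K−1)) / (WSS / (n−K)) with TSS and WSS from squared d."""
    labels = _aligned_labels(d, partition)
    n = len(labels)
    k = partition.k
    if k <= 1 or k >= n:
        raise ValueError("Calinski-Harabasz undefined for K = 1 or K = n")
    tss = (d.values ** 2).sum() / (2.0 * n)
    wss = wss_from_dissimilarity(d, partition).value
    bss = tss - wss
    value = np.inf if wss == 0 else float((bss / (k - 1)) / (wss / (n - k)))
    return IndexResult("calinski_harabasz", value, INDEX_DIRECTIONS["calinski_harabasz"],
                       partition.k, partition.approach)


# ---------------------------------------------------------------------------
# the ten together
# ---------------------------------------------------------------------------

def evaluate_partition(log_table: AbundanceTable, d_log_chord: DissimilarityMatrix,
                       partition: Partition, optimclass_alpha: float = 0.001,
                       ) -> list[IndexResult]:
    """All ten indices on the shared evaluation inputs.

    Undefined indices (e.g. PARTANA on an all-singleton partition) are
    returned with value NaN rather than dropped, so the score cube stays a
    complete grid with flagged holes.
    """
    from .community import to_presence_absence
    pa = to_presence_absence(log_table)
    out: list[IndexResult] = []
    for name in INDEX_NAMES:
        try:
            if name == "indval":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r = indval_total(log_table, partition)
            elif name == "isamic":
                r = isamic(pa, partition)
            elif name == "optimclass":
                r = optimclass(pa, partition, alpha=optimclass_alpha)
            elif name == "tabdev":
                r = tabdev(pa, partition)
            elif name == "totchi":
                r = totchi(log_table, partition)
            elif name == "disdiam":
                r = disdiam(d_log_chord, partition)
            elif name == "partana":
                r = partana_ratio(d_log_chord, partition)
            elif name == "silhouette":
                r = avg_silhouette(d_log_chord, partition)
            elif name == "wss":
                r = wss_from_dissimilarity(d_log_chord, partition)
            else:
                r = calinski_harabasz(d_log_chord, partition)
        except ValueError:
            r = IndexResult(name, float("nan"), INDEX_DIRECTIONS[name],
                            partition.k, partition.approach)
        out.append(r)
    return out
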