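"""Pairwise sample dissimilarities and the Mantel comparison between them.

Three dissimilarities span the method grid:

* Bray-Curtis on log-transformed abundances (semimetric, in [0, 1]),
* Sorensen on presence/absence — the binary analogue of Bray-Curtis,
* Euclidean distance on log-chord transformed abundances (a metric, in
  [0, sqrt(2)] because rows are unit vectors in the non-negative orthant).

Matrices carry a ``metric_tag`` recording which transform/metric produced
them, so downstream code can refuse mismatched inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .community import AbundanceTable

__all__ = [
    "DissimilarityMatrix",
    "MantelResult",
    "bray_curtis",
    "sorensen",
    "euclidean",
    "mantel_test",
]

METRIC_TAGS = ("bray_curtis_log", "sorensen", "euclid_log_chord", "other")


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric zero-diagonal pairwise dissimilarities with provenance."""

    sample_ids: tuple[str, ...]
    values: np.ndarray
    metric_tag: str = "other"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} samples")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix is not symmetric")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        if v.size and v.min() < -1e-12:
            raise ValueError("negative dissimilarities")
        v = np.clip(v, 0.0, None)
        v.setflags(write=False)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def submatrix(self, sample_ids: Sequence[str]) -> "DissimilarityMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids])
        return DissimilarityMatrix(tuple(sample_ids), self.values[np.ix_(idx, idx)],
                                   self.metric_tag)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, index=list(self.sample_ids),
                          columns=list(self.sample_ids))
        df.index.name = "sample_id"
        df.to_csv(path, float_format="%.12g")

    @classmethod
    def from_csv(cls, path, metric_tag: str = "other") -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(str(s) for s in df.index), df.to_numpy(dtype=float), metric_tag)


def _check_no_zero_rows(table: AbundanceTable) -> None:
    sums = table.values.sum(axis=1)
    if (sums == 0).any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(sums == 0)[:5]]
        raise ValueError(f"all-zero sample rows make the dissimilarity undefined: {bad}")


def bray_curtis(table: AbundanceTable) -> DissimilarityMatrix:
    """Bray-Curtis d(x, y) = sum|x - y| / sum(x + y) on a log table."""
    if table.transform_state != "log":
        raise ValueError("bray_curtis expects a log-transformed table; "
                         "compose with log_transform")
    _check_no_zero_rows(table)
    d = squareform(pdist(table.values, metric="braycurtis"))
    return DissimilarityMatrix(tuple(table.sample_ids), d, "bray_curtis_log")


def sorensen(table: AbundanceTable) -> DissimilarityMatrix:
    """Sorensen d = (b + c) / (2a + b + c) on a presence/absence table.

    Identical to Bray-Curtis applied to the binarized table.
    """
    if table.transform_state != "presence_absence":
        raise ValueError("sorensen expects a presence/absence table; "
                         "compose with to_presence_absence")
    _check_no_zero_rows(table)
    d = squareform(pdist(table.values, metric="braycurtis"))
    return DissimilarityMatrix(tuple(table.sample_ids), d, "sorensen")


def euclidean(table: AbundanceTable) -> DissimilarityMatrix:
    """Euclidean distance between log-chord transformed sample rows."""
    if table.transform_state != "log_chord":
        raise ValueError("euclidean expects a log-chord table; "
                         "compose with log_chord_transform")
    d = squareform(pdist(table.values, metric="euclidean"))
    return DissimilarityMatrix(tuple(table.sample_ids), d, "euclid_log_chord")


@dataclass(frozen=True)
class MantelResult:
    """Pearson correlation of two dissimilarity matrices with a permutation p."""

    r: float
    p: float
    n_permutations: int


def mantel_test(d1: DissimilarityMatrix, d2: DissimilarityMatrix,
                n_permutations: int = 999, seed: int | None = None) -> MantelResult:
    """One-sided (greater) Mantel test on the strictly-lower triangles.

    ``d2`` has its rows and columns permuted jointly; the p-value is
    ``(1 + #{permuted r >= observed r}) / (1 + n_permutations)``.
    """
    if d1.sample_ids != d2.sample_ids:
        raise ValueError("mantel_test requires identical sample ids in identical order")
    n = d1.n
    if n < 3:
        raise ValueError("mantel_test requires at least 3 samples")
    tri = np.tril_indices(n, k=-1)
    x = d1.values[tri]
    y = d2.values[tri]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a dissimilarity matrix; Mantel r undefined")
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    r_obs = float(np.mean(xc * yc))

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        yp = d2.values[np.ix_(perm, perm)][tri]
        ypc = (yp - yp.mean()) / yp.std()
        if float(np.mean(xc * ypc)) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return MantelResult(r=r_obs, p=p, n_permutations=n_permutations)
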