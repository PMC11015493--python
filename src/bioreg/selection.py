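"""Approach ranking, statistical comparison, and optimal-K selection.

For every (K, index) slice the nine approaches are ranked (1 = best,
direction-aware, average ranks on ties).  Per-index median ranks across K
summarize each approach; the pooled per-(index, K) ranks feed a
Kruskal-Wallis test across approaches with Dunn and pairwise Wilcoxon
rank-sum post hocs, both Benjamini-Hochberg adjusted over the 36 approach
pairs.  The optimal K is chosen per index — argmax for IndVal and silhouette,
an elbow criterion for the rest — and the modal vote is reported.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cluster import ALL_APPROACHES, ApproachSpec, run_grid
from .community import AbundanceTable, AnalysisConfig, log_transform, log_chord_transform
from .dissimilarity import euclidean
from .indices import INDEX_DIRECTIONS, INDEX_NAMES, evaluate_partition

__all__ = [
    "build_score_cube",
    "rank_approaches",
    "median_rankings",
    "compare_approaches",
    "elbow_k",
    "select_optimal_k",
    "SelectionReport",
    "KSelection",
]

CUBE_COLUMNS = ("approach", "k", "index", "value", "direction")


def build_score_cube(table: AbundanceTable, cfg: AnalysisConfig,
                     approaches=ALL_APPROACHES) -> pd.DataFrame:
    """Run the approach × K grid and score every partition with all ten indices.

    Returns a tidy frame with columns (approach, k, index, value, direction).
    Evaluation inputs are shared: the log table and log-chord dissimilarity of
    the curated data, whatever the approach.
    """
    log_tab = log_transform(table, cfg)
    d_lc = euclidean(log_chord_transform(table, cfg))
    rows = []
    for part in run_grid(table, cfg, approaches):
        for r in evaluate_partition(log_tab, d_lc, part,
                                    optimclass_alpha=cfg.optimclass_alpha):
            rows.append((str(part.approach), part.k, r.index_name, r.value, r.direction))
    return pd.DataFrame(rows, columns=CUBE_COLUMNS)


def rank_approaches(cube: pd.DataFrame) -> pd.DataFrame:
    """Rank approaches within each (k, index) slice; 1 = best, ties averaged.

    Undefined (NaN or infinite with adverse sign) entries are excluded from
    their slice; slices with fewer than two defined values are skipped with a
    warning.  Adds a ``rank`` column.
    """
    out = []
    for (k, index), grp in cube.groupby(["k", "index"], sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        direction = grp["direction"].iloc[0]
        # NaN = undefined and excluded; +/-inf are legitimate extreme values
        # (flagged cases such as WSS = 0) and still rank
        usable = ~np.isnan(vals)
        if usable.sum() < 2:
            warnings.warn(f"slice (k={k}, index={index}) has <2 defined values; skipped")
            continue
        v = vals[usable]
        oriented = -v if direction == "higher_better" else v
        ranks = stats.rankdata(oriented, method="average")
        sub = grp.loc[usable].copy()
        sub["rank"] = ranks
        out.append(sub)
    if not out:
        raise ValueError("no rankable slices in the score cube")
    return pd.concat(out, ignore_index=True)


def median_rankings(rank_table: pd.DataFrame) -> pd.DataFrame:
    """Median rank over K for each (approach, index); approaches × indices frame."""
    return (rank_table.groupby(["approach", "index"])["rank"]
            .median().unstack("index"))


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's z-test on rank means with tie correction; raw two-sided p-values."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_tot = len(pooled)
    all_ranks = stats.rankdata(pooled)
    sizes, mean_ranks, start = {}, {}, 0
    for g in names:
        m = len(groups[g])
        sizes[g] = m
        mean_ranks[g] = all_ranks[start:start + m].mean()
        start += m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    p = pd.DataFrame(1.0, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        pv = 2.0 * stats.norm.sf(abs(z))
        p.loc[a, b] = p.loc[b, a] = pv
    return p


def _bh_adjust_offdiag(p: pd.DataFrame) -> pd.DataFrame:
    names = list(p.index)
    pairs = list(itertools.combinations(names, 2))
    raw = np.array([p.loc[a, b] for a, b in pairs])
    adj = multipletests(raw, method="fdr_bh")[1]
    out = pd.DataFrame(1.0, index=names, columns=names)
    for (a, b), v in zip(pairs, adj):
        out.loc[a, b] = out.loc[b, a] = v
    return out


@dataclass
class SelectionReport:
    """Outcome of the approach comparison."""

    median_rank_by_index: pd.DataFrame      # approaches × indices
    overall_median: pd.Series               # per approach, pooled (index, K) ranks
    overall_mean: pd.Series
    kw_statistic: float
    kw_df: int
    kw_p: float
    dunn_p: pd.DataFrame                    # BH-adjusted
    wilcoxon_p: pd.DataFrame                # BH-adjusted
    winner: str | None
    mode: str = "all_k"

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "winner": self.winner,
            "kw_statistic": float(self.kw_statistic),
            "kw_df": int(self.kw_df),
            "kw_p": float(self.kw_p),
            "overall_median": {k: float(v) for k, v in self.overall_median.items()},
            "overall_mean": {k: float(v) for k, v in self.overall_mean.items()},
            "median_rank_by_index": {
                a: {i: float(v) for i, v in row.items()}
                for a, row in self.median_rank_by_index.iterrows()},
            "dunn_p": {a: {b: float(v) for b, v in row.items()}
                       for a, row in self.dunn_p.iterrows()},
            "wilcoxon_p": {a: {b: float(v) for b, v in row.items()}
                           for a, row in self.wilcoxon_p.iterrows()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def compare_approaches(rank_table: pd.DataFrame, mode: str = "all_k",
                       k: int | None = None) -> SelectionReport:
    """Kruskal-Wallis + Dunn + Wilcoxon rank-sum over the pooled slice ranks.

    ``mode="all_k"`` pools every (index, K) rank per approach; ``mode=
    "single_k"`` restricts to one K (pass ``k``), mirroring a "chosen-K only"
    comparison.  The winner is the approach with the best (lowest) overall
    median rank, ties broken by the mean.
    """
    rt = rank_table
    if mode == "single_k":
        if k is None:
            raise ValueError("single_k mode requires k")
        rt = rank_table[rank_table["k"] == k]
        if rt.empty:
            raise ValueError(f"no ranks at k={k}")
    elif mode != "all_k":
        raise ValueError("mode must be 'all_k' or 'single_k'")

    groups = {a: g["rank"].to_numpy(dtype=float)
              for a, g in rt.groupby("approach", sort=True)}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 approaches with >= 2 observations each")

    arrays = list(groups.values())
    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]) and np.ptp(arrays[0]) == 0:
        kw_stat, kw_p = 0.0, 1.0
    else:
        try:
            kw_stat, kw_p = stats.kruskal(*arrays)
        except ValueError:          # all observations identical across groups
            kw_stat, kw_p = 0.0, 1.0

    dunn = _bh_adjust_offdiag(_dunn_posthoc(groups))
    names = list(groups)
    wil = pd.DataFrame(1.0, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        if np.ptp(np.concatenate([groups[a], groups[b]])) == 0:
            pv = 1.0
        else:
            pv = stats.mannwhitneyu(groups[a], groups[b],
                                    alternative="two-sided").pvalue
        wil.loc[a, b] = wil.loc[b, a] = pv
    wil = _bh_adjust_offdiag(wil)

    overall_median = pd.Series({a: float(np.median(v)) for a, v in groups.items()})
    overall_mean = pd.Series({a: float(np.mean(v)) for a, v in groups.items()})
    if overall_median.nunique() == 1 and overall_mean.nunique() == 1:
        winner = None
    else:
        best = overall_median[overall_median == overall_median.min()]
        winner = (best.index[0] if len(best) == 1
                  else overall_mean[best.index].idxmin())

    med_by_index = median_rankings(rt)
    return SelectionReport(med_by_index, overall_median, overall_mean,
                           float(kw_stat), len(groups) - 1, float(kw_p),
                           dunn, wil, winner, mode=mode)


def elbow_k(values_by_k: pd.Series, direction: str,
            flatness: float = 0.05) -> int | None:
    """Elbow of an index-versus-K curve: K maximizing the second difference.

    The curve is oriented so that improvement decreases with K (higher-better
    curves are negated).  If the largest second difference is below
    ``flatness`` times the curve's total range, no clear elbow exists and
    ``None`` is returned.
    """
    s = values_by_k.dropna().sort_index()
    if len(s) < 3:
        return None
    ks = s.index.to_numpy()
    v = s.to_numpy(dtype=float)
    if direction == "higher_better":
        v = -v
    rng = v.max() - v.min()
    if rng == 0:
        return None
    d2 = v[:-2] - 2.0 * v[1:-1] + v[2:]         # indexed by interior points
    best = int(np.argmax(d2))
    if d2[best] < flatness * rng:
        return None
    return int(ks[best + 1])


@dataclass
class KSelection:
    """Per-index optimal-K votes and the modal choice."""

    per_index: dict[str, int | None]
    modal_k: int | None
    modes: list[int] = field(default_factory=list)
    counts: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"per_index": {k: (None if v is None else int(v))
                              for k, v in self.per_index.items()},
                "modal_k": None if self.modal_k is None else int(self.modal_k),
                "modes": [int(m) for m in self.modes],
                "counts": {str(k): int(v) for k, v in self.counts.items()}}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


#: indices whose optimum is simply the best value over K (rather than an elbow)
ARGBEST_INDICES = ("indval", "silhouette")


def select_optimal_k(cube: pd.DataFrame, winner_approach: str,
                     cfg: AnalysisConfig) -> KSelection:
    """Optimal K per index for the winning approach, plus the modal vote.

    IndVal and silhouette vote for their best K directly; the other indices
    vote via the elbow criterion and abstain when no clear elbow exists.
    Ties in the modal vote are reported (``modes``), not silently broken:
    ``modal_k`` is None when tied.
    """
    sub = cube[cube["approach"] == winner_approach]
    if sub.empty:
        raise ValueError(f"no scores for approach {winner_approach!r}")
    votes: dict[str, int | None] = {}
    for index in INDEX_NAMES:
        si = sub[sub["index"] == index].set_index("k")["value"].sort_index()
        si = si.replace([np.inf, -np.inf], np.nan)
        direction = INDEX_DIRECTIONS[index]
        if index in ARGBEST_INDICES:
            si = si.dropna()
            if si.empty:
                votes[index] = None
                continue
            votes[index] = int(si.idxmax() if direction == "higher_better"
                               else si.idxmin())
        else:
            votes[index] = elbow_k(si, direction, flatness=cfg.elbow_flatness)
    cast = [v for v in votes.values() if v is not None]
    if not cast:
        return KSelection(votes, None, [], {})
    vals, counts = np.unique(cast, return_counts=True)
    top = vals[counts == counts.max()]
    modes = [int(m) for m in top]
    modal = modes[0] if len(modes) == 1 else None
    return KSelection(votes, modal, modes,
                      {int(v): int(c) for v, c in zip(vals, counts)})
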