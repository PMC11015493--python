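"""Subsampling robustness experiments scored by label-matched classification error.

A reference bioregionalization (K-means on the log-chord transformed curated
table) is compared against bioregionalizations of data subsets.  The subset
is re-transformed and re-clustered at the reference K; the classification
error is the percentage of shared samples assigned to a different cluster
after optimally matching subset labels onto reference labels (Hungarian
assignment on the confusion matrix), disaggregated by reference cluster.

Experiment families: random sample/species fractions, sampling-method
category subsets and balanced draws, temporal subsets and balanced draws,
one-sample-per-grid-cell spatial thinning, and deterministic taxonomic
variants (rank aggregation, group restriction, rare-species inclusion,
presence/absence or biomass data types).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .cluster import Partition, kmeans
from .community import (AbundanceTable, AnalysisConfig, SampleMetadata,
                        TaxonMetadata, aggregate_taxonomy, apply_curation_filters,
                        chord_normalize, log_chord_transform, to_presence_absence)

__all__ = [
    "ExperimentSpec",
    "RobustnessResult",
    "match_labels",
    "classification_error",
    "categorize_error",
    "run_robustness",
    "experiment_battery",
    "iteration_seeds",
    "cluster_subset",
    "ERROR_BINS",
]

EXPERIMENT_KINDS = ("sample_fraction", "species_fraction", "category_subset",
                    "category_balanced", "temporal_subset", "temporal_balanced",
                    "spatial_grid", "taxonomic_variant")

#: qualitative bins: upper-closed intervals whose integer endpoints match the
#: conventional 0-5 / 6-10 / 11-15 / 16-33 / 34-100 percent labels
ERROR_BINS = (
    (5.0, "very low"),
    (10.0, "low"),
    (15.0, "moderately low"),
    (33.0, "moderately high"),
    (100.0, "high"),
)


@dataclass(frozen=True)
class ExperimentSpec:
    """One subsampling experiment: a kind, its parameters, iterations, seed."""

    kind: str
    params: dict = field(default_factory=dict)
    n_iterations: int = 1
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EXPERIMENT_KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        _REQUIRED = {
            "sample_fraction": ("fraction",),
            "species_fraction": ("fraction",),
            "category_subset": ("field", "levels"),
            "category_balanced": ("field",),
            "temporal_subset": ("field", "values"),
            "temporal_balanced": ("field",),
            "spatial_grid": ("resolution_deg",),
            "taxonomic_variant": ("variant",),
        }
        missing = [p for p in _REQUIRED[self.kind] if p not in self.params]
        if missing:
            raise ValueError(f"{self.kind} spec missing parameters {missing}")
        if "fraction" in self.params:
            f = self.params["fraction"]
            if not (0 < f <= 1):
                raise ValueError("fraction must lie in (0, 1]")
        if not self.name:
            object.__setattr__(self, "name", self._default_name())

    def _default_name(self) -> str:
        p = self.params
        if self.kind in ("sample_fraction", "species_fraction"):
            return f"{self.kind}_{p['fraction']:.2f}"
        if self.kind == "category_subset":
            return f"{p['field']}={'|'.join(map(str, p['levels']))}"
        if self.kind == "category_balanced":
            return f"balanced_{p['field']}"
        if self.kind == "temporal_subset":
            return f"{p['field']}={'|'.join(map(str, p['values']))}"
        if self.kind == "temporal_balanced":
            return f"balanced_{p['field']}"
        if self.kind == "spatial_grid":
            return f"grid_{p['resolution_deg']}deg"
        return f"taxonomic_{p['variant']}"

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": _jsonable(self.params),
                "n_iterations": self.n_iterations, "seed": self.seed,
                "name": self.name}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, AbundanceTable):
        return f"<AbundanceTable {obj.n_samples}x{obj.n_taxa}>"
    return obj


# ---------------------------------------------------------------------------
# classification error
# ---------------------------------------------------------------------------

def match_labels(confusion: np.ndarray) -> dict[int, int]:
    """Injective map of test labels (columns) onto reference labels (rows).

    Maximizes total agreement via optimal assignment on the negated
    contingency; labels are the 1-based row/column positions.  Test labels
    left unassigned (more test than reference clusters) are absent from the
    map, so all their samples count as mismatches.
    """
    c = np.asarray(confusion, dtype=float)
    if c.size == 0 or c.sum() == 0:
        raise ValueError("empty contingency: no shared samples to match")
    rows, cols = linear_sum_assignment(-c)
    return {int(j) + 1: int(i) + 1 for i, j in zip(rows, cols)}


def classification_error(ref: Partition, test: Partition,
                         ) -> tuple[float, dict[int, float]]:
    """Percent of shared samples whose cluster differs after label matching.

    Returns ``(overall_percent, contributions)`` where ``contributions[b]``
    is the share of the overall error carried by reference cluster ``b``;
    contributions sum to the overall error.
    """
    shared = [s for s in ref.sample_ids if s in set(test.sample_ids)]
    if not shared:
        raise ValueError("no shared samples between reference and test partitions")
    rl = ref.labels_for(shared)
    tl = test.labels_for(shared)
    ref_clusters = np.unique(ref.labels)
    test_clusters = np.unique(test.labels)
    confusion = np.zeros((len(ref_clusters), len(test_clusters)))
    rpos = {c: i for i, c in enumerate(ref_clusters)}
    tpos = {c: i for i, c in enumerate(test_clusters)}
    for a, b in zip(rl, tl):
        confusion[rpos[a], tpos[b]] += 1
    mapping = match_labels(confusion)
    # translate positional map back to actual label values
    label_map = {int(test_clusters[j - 1]): int(ref_clusters[i - 1])
                 for j, i in mapping.items()}
    mismatch = np.array([label_map.get(int(t), -1) != int(r)
                         for r, t in zip(rl, tl)])
    n = len(shared)
    overall = 100.0 * mismatch.sum() / n
    contributions = {int(b): 100.0 * float(mismatch[rl == b].sum()) / n
                     for b in ref_clusters}
    return float(overall), contributions


def categorize_error(pct: float) -> str:
    """Qualitative bin of a classification error percentage.

    Bins are upper-closed intervals [0, 5], (5, 10], (10, 15], (15, 33],
    (33, 100]; their integer endpoints match the conventional 0–5 / 6–10 /
    11–15 / 16–33 / 34–100 labels, and a value such as 5.4 % falls in "low".
    """
    if not (0 <= pct <= 100):
        raise ValueError("classification error must lie in [0, 100]")
    for hi, name in ERROR_BINS:
        if pct <= hi:
            return name
    raise AssertionError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# subset clustering
# ---------------------------------------------------------------------------

def iteration_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-iteration seeds derived from an experiment seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def cluster_subset(table: AbundanceTable, k: int, cfg: AnalysisConfig,
                   seed: int, data_type: str = "abundance") -> Partition:
    """Transform a (sub)table and K-means it at K; the robustness inner step.

    ``data_type`` "abundance"/"biomass" applies the log-chord transform;
    "presence_absence" binarizes then chord-normalizes.
    """
    if data_type == "presence_absence":
        coords = chord_normalize(to_presence_absence(table))
    else:
        coords = log_chord_transform(table, cfg)
    return kmeans(coords.values, k, table.sample_ids, n_init=cfg.kmeans_n_init,
                  seed=int(seed), max_iter=cfg.kmeans_max_iter, tol=cfg.kmeans_tol)


def _drop_zero_rows_forbidden(table: AbundanceTable) -> bool:
    return bool((table.values.sum(axis=1) == 0).any())


def _subset_samples(rng: np.random.Generator, ids: list[str], size: int) -> list[str]:
    idx = rng.choice(len(ids), size=size, replace=False)
    return [ids[i] for i in sorted(idx)]


def _build_subset(table: AbundanceTable, metadata: SampleMetadata | None,
                  taxa: TaxonMetadata | None, spec: ExperimentSpec,
                  cfg: AnalysisConfig, rng: np.random.Generator,
                  raw_table: AbundanceTable | None,
                  ) -> tuple[AbundanceTable, str]:
    """One iteration's subset table and the data type to cluster it with."""
    kind, p = spec.kind, spec.params
    data_type = "abundance"
    if kind == "sample_fraction":
        size = max(1, math.ceil(p["fraction"] * table.n_samples))
        sub = table.subset(sample_ids=_subset_samples(rng, table.sample_ids, size))
    elif kind == "species_fraction":
        size = max(1, math.ceil(p["fraction"] * table.n_taxa))
        idx = sorted(rng.choice(table.n_taxa, size=size, replace=False))
        sub = table.subset(taxon_ids=[table.taxon_ids[i] for i in idx])
    elif kind in ("category_subset", "temporal_subset"):
        md = metadata.aligned_to(table.sample_ids).data
        fieldname = p["field"]
        levels = set(p.get("levels", p.get("values")))
        keep = [s for s, v in md[fieldname].items() if v in levels]
        sub = table.subset(sample_ids=keep)
    elif kind in ("category_balanced", "temporal_balanced"):
        md = metadata.aligned_to(table.sample_ids).data
        fieldname = p["field"]
        groups = md.groupby(fieldname, dropna=True).groups
        m = min(len(v) for v in groups.values())
        keep: list[str] = []
        for level in sorted(groups, key=str):
            ids = [str(s) for s in groups[level]]
            keep.extend(_subset_samples(rng, ids, m))
        sub = table.subset(sample_ids=keep)
    elif kind == "spatial_grid":
        md = metadata.aligned_to(table.sample_ids).data
        r = float(p["resolution_deg"])
        cells = (np.floor(md["latitude"].to_numpy(dtype=float) / r).astype(int),
                 np.floor(md["longitude"].to_numpy(dtype=float) / r).astype(int))
        cell_of = pd.Series(list(zip(*cells)), index=md.index)
        keep = []
        for _, ids in sorted(cell_of.groupby(cell_of).groups.items()):
            ids = [str(s) for s in ids]
            keep.append(ids[int(rng.integers(len(ids)))] if len(ids) > 1 else ids[0])
        sub = table.subset(sample_ids=sorted(keep))
    elif kind == "taxonomic_variant":
        sub, data_type = _taxonomic_variant(table, taxa, p, cfg, raw_table)
    else:  # pragma: no cover
        raise ValueError(kind)
    return sub, data_type


def _taxonomic_variant(table: AbundanceTable, taxa: TaxonMetadata | None,
                       p: dict, cfg: AnalysisConfig,
                       raw_table: AbundanceTable | None,
                       ) -> tuple[AbundanceTable, str]:
    variant = p["variant"]
    if variant == "rank_aggregation":
        sub, _ = aggregate_taxonomy(table, taxa, p["rank"], on_missing="drop")
        return sub, "abundance"
    if variant == "group_subset":
        members = [t for t in taxa.taxa_in_group(p["group"]) if t in set(table.taxon_ids)]
        if not members:
            raise ValueError(f"no taxa in group {p['group']!r}")
        return table.subset(taxon_ids=members), "abundance"
    if variant == "include_rare":
        if raw_table is None:
            raise ValueError("include_rare variant needs the pre-curation raw table")
        cfg_all = AnalysisConfig(**{**cfg.to_dict(),
                                    "min_occurrence_fraction": 1e-12})
        sub, _ = apply_curation_filters(raw_table, taxa, cfg_all)
        return sub, "abundance"
    if variant == "data_type":
        dt = p["data_type"]
        if dt == "presence_absence":
            return table, "presence_absence"
        if dt == "biomass":
            alt = p.get("alt_table")
            if alt is None:
                raise ValueError("biomass variant needs params['alt_table']")
            return alt, "abundance"
        raise ValueError(f"unknown data_type {dt!r}")
    raise ValueError(f"unknown taxonomic variant {variant!r}")


# ---------------------------------------------------------------------------
# the experiment runner
# ---------------------------------------------------------------------------

@dataclass
class RobustnessResult:
    """Per-iteration classification errors for one experiment."""

    spec: ExperimentSpec
    overall: np.ndarray                       # percent, per completed iteration
    contributions: pd.DataFrame               # iterations × reference clusters
    n_shared: np.ndarray
    n_skipped: int = 0

    @property
    def mean_error(self) -> float:
        return float(np.mean(self.overall)) if self.overall.size else float("nan")

    def summary(self) -> dict:
        o = self.overall
        if o.size == 0:
            return {"name": self.spec.name, "n_iterations": 0,
                    "n_skipped": self.n_skipped}
        q1, med, q3 = np.percentile(o, [25, 50, 75])
        return {
            "name": self.spec.name,
            "kind": self.spec.kind,
            "n_iterations": int(o.size),
            "n_skipped": int(self.n_skipped),
            "mean": float(o.mean()), "min": float(o.min()), "max": float(o.max()),
            "q1": float(q1), "median": float(med), "q3": float(q3),
            "bin": categorize_error(float(o.mean())),
            "mean_shared": float(self.n_shared.mean()),
            "cluster_contributions_mean": {
                str(c): float(self.contributions[c].mean())
                for c in self.contributions.columns},
        }

    def to_tidy(self) -> pd.DataFrame:
        df = self.contributions.copy()
        df.columns = [f"cluster_{c}" for c in df.columns]
        df.insert(0, "experiment", self.spec.name)
        df.insert(1, "iteration", np.arange(1, len(df) + 1))
        df.insert(2, "overall_error_pct", self.overall)
        df.insert(3, "n_shared", self.n_shared)
        return df


def run_robustness(table: AbundanceTable, metadata: SampleMetadata | None,
                   taxa: TaxonMetadata | None, ref: Partition,
                   spec: ExperimentSpec, cfg: AnalysisConfig,
                   raw_table: AbundanceTable | None = None) -> RobustnessResult:
    """Run one subsampling experiment against the reference partition.

    Per iteration: build the subset, re-apply the transform, K-means at the
    reference K with a fresh iteration seed, and score the classification
    error on shared samples.  Iterations whose subset has fewer than K samples
    or an all-zero sample row are skipped and counted.
    """
    if set(ref.sample_ids) != set(table.sample_ids):
        raise ValueError("reference partition must cover exactly the curated table samples")
    k = ref.k
    ref_clusters = sorted(int(c) for c in np.unique(ref.labels))
    seeds = iteration_seeds(spec.seed, spec.n_iterations)
    overall, contribs, shared_counts = [], [], []
    skipped = 0
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    for it in range(spec.n_iterations):
        sub, data_type = _build_subset(table, metadata, taxa, spec, cfg, rng, raw_table)
        if sub.n_samples < k or _drop_zero_rows_forbidden(sub):
            skipped += 1
            continue
        test = cluster_subset(sub, k, cfg, seeds[it], data_type=data_type)
        if test.k < k:
            skipped += 1
            continue
        err, contrib = classification_error(ref, test)
        overall.append(err)
        contribs.append([contrib.get(c, 0.0) for c in ref_clusters])
        shared_counts.append(len([s for s in sub.sample_ids
                                  if s in set(ref.sample_ids)]))
    if not overall and spec.n_iterations > 0:
        warnings.warn(f"experiment {spec.name!r}: all {spec.n_iterations} iterations skipped")
    return RobustnessResult(
        spec=spec,
        overall=np.asarray(overall, dtype=float),
        contributions=pd.DataFrame(contribs, columns=ref_clusters),
        n_shared=np.asarray(shared_counts, dtype=int),
        n_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# the full battery
# ---------------------------------------------------------------------------

GRID_RESOLUTIONS_DEG = (0.01, 0.05, 0.10, 0.25, 0.50, 1.0, 2.0)
METHOD_FIELDS = ("day_night", "net_type", "mouth_diameter_m", "mesh_size_um")
SPRING_MONTHS = (4, 5, 6)
SUMMER_FALL_MONTHS = (7, 8, 9, 10)


def dominant_levels(series: pd.Series, coverage: float = 0.8) -> list:
    """Most frequent levels cumulatively covering >= ``coverage`` of samples."""
    counts = series.value_counts()
    cum = counts.cumsum() / counts.sum()
    n_keep = int(np.searchsorted(cum.to_numpy(), coverage) + 1)
    return counts.index[:n_keep].tolist()


def experiment_battery(table: AbundanceTable, metadata: SampleMetadata,
                       taxa: TaxonMetadata, ref: Partition, cfg: AnalysisConfig,
                       raw_table: AbundanceTable | None = None,
                       biomass_table: AbundanceTable | None = None,
                       base_seed: int | None = None) -> list[ExperimentSpec]:
    """Construct the full experiment grid (specs only; run with run_robustness).

    Fractions 0.05–1.00 in 5 % steps for samples and species; per-category,
    dominant-category, and balanced subsets for each sampling-method field;
    per-month, per-year, seasonal, 5/10-year, and balanced temporal subsets;
    the seven grid resolutions; and the deterministic taxonomic variants.
    """
    seed0 = cfg.rng_seed if base_seed is None else base_seed
    n_iter = cfg.n_iterations
    specs: list[ExperimentSpec] = []
    counter = [0]

    def add(kind: str, params: dict, iterations: int = 1, name: str = "") -> None:
        counter[0] += 1
        specs.append(ExperimentSpec(kind, params, n_iterations=iterations,
                                    seed=int((seed0 + 7919 * counter[0]) % (2 ** 31)),
                                    name=name))

    fractions = [round(0.05 * i, 2) for i in range(1, 21)]
    for f in fractions:
        add("sample_fraction", {"fraction": f}, n_iter)
    for f in fractions:
        add("species_fraction", {"fraction": f}, n_iter)

    md = metadata.aligned_to(table.sample_ids).data
    for fieldname in METHOD_FIELDS:
        if fieldname not in md.columns:
            continue
        col = md[fieldname].dropna()
        levels = sorted(col.unique(), key=str)
        for level in levels:
            add("category_subset", {"field": fieldname, "levels": [level]})
        if len(levels) > 2:
            dom = dominant_levels(col)
            if 1 < len(dom) < len(levels):
                add("category_subset", {"field": fieldname, "levels": sorted(dom, key=str)},
                    name=f"{fieldname}=dominant")
        add("category_balanced", {"field": fieldname}, n_iter)

    if "month" in md.columns:
        months = sorted(md["month"].dropna().unique())
        for m in months:
            add("temporal_subset", {"field": "month", "values": [int(m)]})
        add("temporal_subset", {"field": "month",
                                "values": [m for m in SPRING_MONTHS if m in months]},
            name="season=spring")
        add("temporal_subset", {"field": "month",
                                "values": [m for m in SUMMER_FALL_MONTHS if m in months]},
            name="season=summer_fall")
        add("temporal_balanced", {"field": "month"}, n_iter)
    if "year" in md.columns:
        years = sorted(int(y) for y in md["year"].dropna().unique())
        for y in years:
            add("temporal_subset", {"field": "year", "values": [y]})
        y0, y1 = min(years), max(years)
        for width in (5, 10):
            start = y0
            while start <= y1:
                window = [y for y in years if start <= y < start + width]
                if window:
                    add("temporal_subset", {"field": "year", "values": window},
                        name=f"years_{start}-{start + width - 1}")
                start += width
        add("temporal_balanced", {"field": "year"}, n_iter)

    if {"latitude", "longitude"}.issubset(md.columns):
        for r in GRID_RESOLUTIONS_DEG:
            add("spatial_grid", {"resolution_deg": r}, n_iter)

    for rank in ("genus", "family"):
        if rank in taxa.data.columns:
            add("taxonomic_variant", {"variant": "rank_aggregation", "rank": rank})
    if "group_labels" in taxa.data.columns:
        groups = sorted({g for t in table.taxon_ids for g in taxa.groups_of(t)})
        for g in groups:
            add("taxonomic_variant", {"variant": "group_subset", "group": g})
    if raw_table is not None:
        add("taxonomic_variant", {"variant": "include_rare"})
    add("taxonomic_variant", {"variant": "data_type", "data_type": "presence_absence"})
    if biomass_table is not None:
        add("taxonomic_variant", {"variant": "data_type", "data_type": "biomass",
                                  "alt_table": biomass_table})
    return specs


def results_to_tidy(results: Sequence[RobustnessResult]) -> pd.DataFrame:
    return pd.concat([r.to_tidy() for r in results], ignore_index=True)


def results_summary(results: Sequence[RobustnessResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        s = r.summary()
        contrib = s.pop("cluster_contributions_mean", {})
        for c, v in contrib.items():
            s[f"cluster_{c}_mean"] = v
        rows.append(s)
    return pd.DataFrame(rows)


def results_to_json(results: Sequence[RobustnessResult], path) -> None:
    payload = [{"spec": r.spec.to_dict(), "summary": r.summary()} for r in results]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
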