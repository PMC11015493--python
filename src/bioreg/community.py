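"""Site-by-species community tables, curation filters, and abundance transforms.

The central container is :class:`AbundanceTable`, a thin immutable wrapper
around a samples × taxa :class:`pandas.DataFrame` that tracks what kind of
values it holds (abundance, biomass, presence/absence) and which transform
chain produced it (raw, log, chord, log-chord, presence/absence).  All
downstream stages — dissimilarities, clustering, goodness-of-clustering
indices, robustness experiments — consume this type.

Curation follows the usual practice for heterogeneous community compilations:
drop taxa flagged for exclusion, drop taxa observed in too small a fraction of
samples, and drop samples whose species richness is too low to carry a
community signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "SampleMetadata",
    "TaxonMetadata",
    "AnalysisConfig",
    "CurationReport",
    "CurationError",
    "apply_curation_filters",
    "log_transform",
    "chord_normalize",
    "log_chord_transform",
    "to_presence_absence",
    "aggregate_taxonomy",
]

VALUE_KINDS = ("abundance", "biomass", "presence_absence")
TRANSFORM_STATES = ("raw", "log", "chord", "log_chord", "presence_absence")


class CurationError(ValueError):
    """Raised when curation removes everything or inputs violate a contract."""


@dataclass(frozen=True)
class AbundanceTable:
    """Samples × taxa matrix of non-negative values.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by sample id, columns by taxon id, non-negative values.
    value_kind : {"abundance", "biomass", "presence_absence"}
    transform_state : {"raw", "log", "chord", "log_chord", "presence_absence"}
    """

    data: pd.DataFrame
    value_kind: str = "abundance"
    transform_state: str = "raw"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.transform_state not in TRANSFORM_STATES:
            raise ValueError(f"unknown transform_state {self.transform_state!r}")
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dup}")
        values = df.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValueError("non-finite values in abundance table")
        if values.size and values.min() < 0:
            raise ValueError("negative values in abundance table")
        if self.value_kind == "presence_absence" and values.size:
            if not np.isin(values, (0.0, 1.0)).all():
                raise ValueError("presence_absence table must contain only {0, 1}")
        # normalise dtype once so downstream numeric code is uniform
        object.__setattr__(self, "data", df.astype(float))

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def taxon_ids(self) -> list[str]:
        return [str(t) for t in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def richness(self) -> pd.Series:
        """Number of taxa with a positive value, per sample."""
        return (self.data > 0).sum(axis=1)

    def prevalence(self) -> pd.Series:
        """Fraction of samples in which each taxon is present."""
        if self.n_samples == 0:
            return pd.Series(0.0, index=self.data.columns)
        return (self.data > 0).mean(axis=0)

    def subset(self, sample_ids: Sequence[str] | None = None,
               taxon_ids: Sequence[str] | None = None) -> "AbundanceTable":
        df = self.data
        if sample_ids is not None:
            df = df.loc[list(sample_ids)]
        if taxon_ids is not None:
            df = df[list(taxon_ids)]
        return replace(self, data=df)

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, value_kind: str = "abundance", sep: str | None = None) -> "AbundanceTable":
        """Read a wide matrix: first column sample id, header row = taxon ids."""
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        state = "presence_absence" if value_kind == "presence_absence" else "raw"
        return cls(df, value_kind=value_kind, transform_state=state)

    def to_csv(self, path, sep: str = ",") -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep=sep, float_format="%.10g")


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns: {missing}")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample metadata: position, date, and gear descriptors.

    Expected columns (missing cells allowed, flagged via :meth:`missing_report`):
    latitude, longitude, year, month, day_night, net_type, mouth_diameter_m,
    mesh_size_um, plus arbitrary extra categorical fields.
    """

    data: pd.DataFrame

    KNOWN = ("latitude", "longitude", "year", "month", "day_night",
             "net_type", "mouth_diameter_m", "mesh_size_um")

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                df = df.rename_axis("sample_id")
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            raise ValueError("duplicate sample_id rows in sample metadata")
        if "latitude" in df.columns:
            lat = pd.to_numeric(df["latitude"], errors="coerce")
            if ((lat < -90) | (lat > 90)).any():
                raise ValueError("latitude outside [-90, 90]")
        if "longitude" in df.columns:
            lon = pd.to_numeric(df["longitude"], errors="coerce")
            if ((lon < -180) | (lon > 180)).any():
                raise ValueError("longitude outside [-180, 180]")
        if "month" in df.columns:
            mo = pd.to_numeric(df["month"], errors="coerce").dropna()
            if ((mo < 1) | (mo > 12)).any():
                raise ValueError("month outside 1..12")
        object.__setattr__(self, "data", df)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def missing_report(self) -> pd.Series:
        """Count of missing cells per known column."""
        cols = [c for c in self.KNOWN if c in self.data.columns]
        return self.data[cols].isna().sum()

    def aligned_to(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        missing = set(sample_ids) - set(self.data.index)
        if missing:
            raise ValueError(f"metadata missing samples: {sorted(missing)[:5]} ...")
        return SampleMetadata(self.data.loc[list(sample_ids)])

    @classmethod
    def from_csv(cls, path, sep: str | None = None) -> "SampleMetadata":
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        return cls(pd.read_csv(path, sep=sep))

    def to_csv(self, path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, float_format="%.10g")


RANKS = ("species", "genus", "family", "order", "class", "other")


@dataclass(frozen=True)
class TaxonMetadata:
    """Per-taxon metadata: rank, lineage labels, functional groups, curation flag.

    ``group_labels`` is stored as a pipe-separated string on disk (e.g.
    ``"holoplankton|crustacean|copepod"``); :meth:`groups_of` returns a set.
    ``curation_flag`` follows the 1–4 convention: 1 = include, 2–4 = exclude
    for data-driven reasons supplied by the curator.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "taxon_id":
            if "taxon_id" in df.columns:
                df = df.set_index("taxon_id")
            else:
                df = df.rename_axis("taxon_id")
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            raise ValueError("duplicate taxon_id rows in taxon metadata")
        if "curation_flag" in df.columns:
            flags = pd.to_numeric(df["curation_flag"], errors="coerce")
            bad = flags.dropna()[~flags.dropna().isin([1, 2, 3, 4])]
            if len(bad):
                raise ValueError(f"curation_flag outside 1..4 for: {bad.index.tolist()[:5]}")
        if "rank" in df.columns:
            bad = df["rank"].dropna()[~df["rank"].dropna().isin(RANKS)]
            if len(bad):
                raise ValueError(f"unknown rank for: {bad.index.tolist()[:5]}")
        object.__setattr__(self, "data", df)

    @property
    def taxon_ids(self) -> list[str]:
        return [str(t) for t in self.data.index]

    def flag_of(self, taxon_id: str) -> int:
        if "curation_flag" not in self.data.columns:
            return 1
        v = self.data.loc[taxon_id, "curation_flag"]
        return 1 if pd.isna(v) else int(v)

    def included_taxa(self) -> list[str]:
        """Taxa with curation_flag == 1 (missing flag counts as include)."""
        if "curation_flag" not in self.data.columns:
            return self.taxon_ids
        flags = pd.to_numeric(self.data["curation_flag"], errors="coerce").fillna(1)
        return [str(t) for t in self.data.index[flags == 1]]

    def groups_of(self, taxon_id: str) -> set[str]:
        if "group_labels" not in self.data.columns:
            return set()
        v = self.data.loc[taxon_id, "group_labels"]
        if pd.isna(v) or not str(v):
            return set()
        return {g for g in str(v).split("|") if g}

    def taxa_in_group(self, group: str) -> list[str]:
        return [t for t in self.taxon_ids if group in self.groups_of(t)]

    def label_for_rank(self, rank: str) -> pd.Series:
        """Rank label per taxon (genus or family column); NaN where absent."""
        if rank not in ("genus", "family"):
            raise ValueError("rank must be 'genus' or 'family'")
        if rank not in self.data.columns:
            return pd.Series(np.nan, index=self.data.index)
        return self.data[rank]

    @classmethod
    def from_csv(cls, path, sep: str | None = None) -> "TaxonMetadata":
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        return cls(pd.read_csv(path, sep=sep))

    def to_csv(self, path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep)


@dataclass
class AnalysisConfig:
    """Tunable constants of the whole pipeline.

    Defaults follow the conventions for compiled zooplankton surveys: samples
    must hold at least 15 species, taxa must occur in at least 3 % of samples,
    abundances are log10(x+1) transformed, candidate partitions span K = 2–20,
    subsampling experiments run 1000 iterations, and Mantel tests use 999
    permutations.
    """

    min_richness: int = 15
    min_occurrence_fraction: float = 0.03
    log_base: str = "10"          # "10" or "e"
    pseudocount: float = 1.0
    kmin: int = 2
    kmax: int = 20
    n_iterations: int = 1000
    mantel_permutations: int = 999
    optimclass_alpha: float = 0.001
    kmeans_n_init: int = 25
    kmeans_max_iter: int = 300
    kmeans_tol: float = 1e-6
    elbow_flatness: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_occurrence_fraction < 1):
            raise ValueError("min_occurrence_fraction must lie in (0, 1)")
        if self.kmin < 2:
            raise ValueError("kmin must be >= 2")
        if self.kmax < self.kmin:
            raise ValueError("kmax must be >= kmin")
        if self.log_base not in ("10", "e"):
            raise ValueError("log_base must be '10' or 'e'")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.n_iterations < 1 or self.mantel_permutations < 1:
            raise ValueError("iteration counts must be >= 1")

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class CurationReport:
    """Counts removed at each curation step, in application order."""

    n_taxa_flag_removed: int = 0
    n_taxa_rare_removed: int = 0
    n_samples_low_richness_removed: int = 0
    n_passes: int = 1
    removed_taxa: list[str] = field(default_factory=list)
    removed_samples: list[str] = field(default_factory=list)
    n_samples_retained: int = 0
    n_taxa_retained: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def apply_curation_filters(table: AbundanceTable, taxa: TaxonMetadata,
                           cfg: AnalysisConfig) -> tuple[AbundanceTable, CurationReport]:
    """Curate a raw table: exclusion flags, then prevalence, then richness.

    Taxa whose curation flag is not 1 are removed first.  Then taxa present in
    fewer than ``cfg.min_occurrence_fraction`` of the current samples are
    removed, then samples with richness below ``cfg.min_richness``.  Because
    removing samples can in turn push taxa below the prevalence threshold, the
    prevalence and richness steps are alternated until nothing changes, so the
    operation is idempotent; the report accumulates counts per step and the
    number of passes taken.
    """
    if table.transform_state != "raw" and table.transform_state != "presence_absence":
        raise CurationError("curation operates on raw (or presence/absence) tables")
    missing = set(table.taxon_ids) - set(taxa.taxon_ids)
    if missing:
        raise CurationError(f"taxon metadata does not cover: {sorted(missing)[:5]} ...")

    report = CurationReport()
    keep_taxa = [t for t in table.taxon_ids if t in set(taxa.included_taxa())]
    report.n_taxa_flag_removed = table.n_taxa - len(keep_taxa)
    report.removed_taxa.extend(t for t in table.taxon_ids if t not in set(keep_taxa))
    df = table.data[keep_taxa]

    passes = 0
    while True:
        passes += 1
        changed = False
        if df.shape[0]:
            prev = (df > 0).mean(axis=0)
            rare = prev.index[prev < cfg.min_occurrence_fraction].tolist()
            if rare:
                report.n_taxa_rare_removed += len(rare)
                report.removed_taxa.extend(str(t) for t in rare)
                df = df.drop(columns=rare)
                changed = True
        rich = (df > 0).sum(axis=1)
        poor = rich.index[rich < cfg.min_richness].tolist()
        if poor:
            report.n_samples_low_richness_removed += len(poor)
            report.removed_samples.extend(str(s) for s in poor)
            df = df.drop(index=poor)
            changed = True
        if not changed:
            break
    report.n_passes = passes

    if df.shape[0] == 0 or df.shape[1] == 0:
        raise CurationError("all data filtered out by curation; "
                            "loosen min_richness/min_occurrence_fraction or check flags")
    report.n_samples_retained, report.n_taxa_retained = df.shape
    return replace(table, data=df), report


def log_transform(table: AbundanceTable, cfg: AnalysisConfig) -> AbundanceTable:
    """Replace each value x by log(x + pseudocount) in the configured base."""
    if table.transform_state != "raw":
        raise ValueError(f"log_transform expects a raw table, got {table.transform_state}")
    x = table.values + cfg.pseudocount
    out = np.log10(x) if cfg.log_base == "10" else np.log(x)
    df = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return replace(table, data=df, transform_state="log")


def chord_normalize(table: AbundanceTable) -> AbundanceTable:
    """Scale every sample row to unit Euclidean norm (the chord transform)."""
    norms = np.linalg.norm(table.values, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        bad = [table.sample_ids[i] for i in zero[:5]]
        raise ValueError(f"cannot chord-normalize all-zero sample rows: {bad}")
    df = table.data.div(pd.Series(norms, index=table.data.index), axis=0)
    state = {"raw": "chord", "log": "log_chord"}.get(table.transform_state, "chord")
    # normalized values are no longer strictly binary
    kind = "abundance" if table.value_kind == "presence_absence" else table.value_kind
    return replace(table, data=df, transform_state=state, value_kind=kind)


def log_chord_transform(table: AbundanceTable, cfg: AnalysisConfig) -> AbundanceTable:
    """log(x+pseudocount) per cell, then rows scaled to unit norm."""
    return chord_normalize(log_transform(table, cfg))


def to_presence_absence(table: AbundanceTable) -> AbundanceTable:
    """Binarize: positive values become 1."""
    df = (table.data > 0).astype(float)
    return AbundanceTable(df, value_kind="presence_absence",
                          transform_state="presence_absence")


def aggregate_taxonomy(table: AbundanceTable, taxa: TaxonMetadata, rank: str,
                       on_missing: str = "error") -> tuple[AbundanceTable, list[str]]:
    """Sum columns that share a genus or family label.

    Returns the aggregated table (columns = rank labels) and the list of taxa
    dropped because they carried no label at the target rank.  ``on_missing``
    is ``"error"`` (default) or ``"drop"``.
    """
    if rank not in ("genus", "family"):
        raise ValueError("rank must be 'genus' or 'family'")
    labels = taxa.label_for_rank(rank).reindex(table.taxon_ids)
    unlabeled = [str(t) for t in labels.index[labels.isna()]]
    if unlabeled and on_missing == "error":
        raise ValueError(f"no {rank} label for taxa {unlabeled[:5]} "
                         f"(pass on_missing='drop' to discard them)")
    kept = labels.dropna()
    df = table.data[kept.index]
    agg = df.T.groupby(kept.astype(str)).sum().T
    agg.columns = agg.columns.astype(str)
    out = replace(table, data=agg)
    return out, unlabeled
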