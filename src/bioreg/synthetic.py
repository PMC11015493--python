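"""Synthetic multi-region communities with region-correlated metadata.

The generator plants K latent regions.  Species fall into three pools:
region indicators (high occupancy and abundance inside their home region,
low outside), cosmopolitans (common everywhere), and rare species (sparse
everywhere — these exercise the prevalence filter).  Abundances are
overdispersed lognormal counts; a ``separation`` knob scales the in/out
contrast from no signal (0) to the full planted contrast (1, the "strong"
preset).  Metadata ties each region to a lat/lon box and draws months,
years, and gear categories, optionally confounding gear with region to
emulate systematic method-by-region sampling bias.

Everything is driven by one seed and is bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cluster import Partition
from .community import AbundanceTable, SampleMetadata, TaxonMetadata

__all__ = ["SyntheticSpec", "CommunityBundle", "generate_community",
           "make_study_fixture"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-region community generator.

    Defaults are the "strong separation" study conditions: 4 regions of 100
    samples, 160 species of which 20 % are cosmopolitan and 20 % rare,
    indicator occupancy 0.85 in-region versus 0.10 outside, lognormal
    log10-abundance means 2.0 (in) and 0.5 (out) with sigma 0.7.
    """

    n_regions: int = 4
    samples_per_region: tuple[int, ...] = (100, 100, 100, 100)
    n_species: int = 160
    fraction_cosmopolitan: float = 0.2
    fraction_rare: float = 0.2
    occupancy_in_region: float = 0.85
    occupancy_out_region: float = 0.10
    occupancy_cosmopolitan: float = 0.90
    occupancy_rare: float = 0.02
    mean_log_abundance_in: float = 2.0
    mean_log_abundance_out: float = 0.5
    overdispersion: float = 0.7           # sigma of log10 abundance
    separation: float = 1.0               # 0 = no regional signal
    round_to_counts: bool = True
    confound_gear: bool = False
    months: tuple[int, ...] = tuple(range(4, 11))
    years: tuple[int, ...] = tuple(range(1995, 2015))
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples_per_region) != self.n_regions:
            raise ValueError("samples_per_region length must equal n_regions")
        if any(s < 1 for s in self.samples_per_region):
            raise ValueError("samples_per_region entries must be >= 1")
        for p in (self.fraction_cosmopolitan, self.fraction_rare,
                  self.occupancy_in_region, self.occupancy_out_region,
                  self.occupancy_cosmopolitan, self.occupancy_rare):
            if not (0 <= p <= 1):
                raise ValueError("probabilities/fractions must lie in [0, 1]")
        if self.fraction_cosmopolitan + self.fraction_rare > 1:
            raise ValueError("cosmopolitan + rare fractions exceed 1")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")


NET_TYPES = ("bongo_vnh", "scor_vnh", "ring_vnh")
NET_PROBS = (0.6, 0.3, 0.1)
MOUTH_BY_NET = {"bongo_vnh": 0.56, "scor_vnh": 0.50, "ring_vnh": 0.42}
MESH_BY_NET = {"bongo_vnh": 236.0, "scor_vnh": 250.0, "ring_vnh": 200.0}


@dataclass
class CommunityBundle:
    """A generated community with its metadata and the planted truth."""

    table: AbundanceTable
    sample_metadata: SampleMetadata
    taxon_metadata: TaxonMetadata
    truth: Partition
    spec: SyntheticSpec

    def write(self, out_dir) -> dict[str, str]:
        """Write the CSV bundle plus a manifest; returns the file map."""
        import os
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "abundance": os.path.join(out_dir, "abundance.csv"),
            "sample_metadata": os.path.join(out_dir, "samples.csv"),
            "taxon_metadata": os.path.join(out_dir, "taxa.csv"),
            "truth": os.path.join(out_dir, "true_partition.csv"),
            "manifest": os.path.join(out_dir, "bundle_manifest.json"),
        }
        self.table.to_csv(paths["abundance"])
        self.sample_metadata.to_csv(paths["sample_metadata"])
        self.taxon_metadata.to_csv(paths["taxon_metadata"])
        self.truth.to_csv(paths["truth"])
        spec_d = asdict(self.spec)
        with open(paths["manifest"], "w") as fh:
            json.dump({"spec": spec_d, "files": {k: v for k, v in paths.items()
                                                 if k != "manifest"}},
                      fh, indent=2, sort_keys=True, default=list)
        return paths


def _species_pools(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-species pool ('indicator'/'cosmo'/'rare') and home region (or -1)."""
    s = spec.n_species
    n_cosmo = int(round(spec.fraction_cosmopolitan * s))
    n_rare = int(round(spec.fraction_rare * s))
    n_ind = s - n_cosmo - n_rare
    pool = np.array(["indicator"] * n_ind + ["cosmo"] * n_cosmo + ["rare"] * n_rare)
    home = np.full(s, -1)
    home[:n_ind] = np.arange(n_ind) % spec.n_regions
    return pool, home


def generate_community(spec: SyntheticSpec) -> CommunityBundle:
    """Draw one community table, metadata, and true partition from the spec."""
    rng = np.random.default_rng(spec.seed)
    n = int(sum(spec.samples_per_region))
    s = spec.n_species
    region = np.repeat(np.arange(spec.n_regions), spec.samples_per_region)
    pool, home = _species_pools(spec)

    # occupancy and mean-log-abundance per sample × species
    sep = spec.separation
    p_out = spec.occupancy_out_region
    p_in_eff = np.clip(p_out + sep * (spec.occupancy_in_region - p_out), 0, 1)
    mu_out = spec.mean_log_abundance_out
    mu_in_eff = mu_out + sep * (spec.mean_log_abundance_in - mu_out)

    occ = np.empty((n, s))
    mu = np.empty((n, s))
    is_ind = pool == "indicator"
    in_home = region[:, None] == home[None, :]
    occ[:, is_ind] = np.where(in_home[:, is_ind], p_in_eff, p_out)
    mu[:, is_ind] = np.where(in_home[:, is_ind], mu_in_eff, mu_out)
    occ[:, pool == "cosmo"] = spec.occupancy_cosmopolitan
    mu[:, pool == "cosmo"] = mu_in_eff
    occ[:, pool == "rare"] = spec.occupancy_rare
    mu[:, pool == "rare"] = mu_out

    present = rng.random((n, s)) < occ
    logab = rng.normal(mu, spec.overdispersion)
    values = np.where(present, 10.0 ** logab, 0.0)
    if spec.round_to_counts:
        values = np.where(present, np.maximum(np.rint(values), 1.0), 0.0)

    sample_ids = [f"s{i + 1:04d}" for i in range(n)]
    taxon_ids = [f"sp{j + 1:03d}" for j in range(s)]
    table = AbundanceTable(pd.DataFrame(values, index=sample_ids, columns=taxon_ids))

    sample_md = _draw_metadata(spec, rng, region, sample_ids)
    taxon_md = _taxon_metadata(spec, pool, taxon_ids)
    truth = Partition(tuple(sample_ids), region + 1, k=spec.n_regions)

    rich = table.richness()
    if (rich < 15).any():
        warnings.warn(
            f"{int((rich < 15).sum())} samples fall below richness 15 "
            f"(expected richness ≈ {float(occ.sum(axis=1).mean()):.1f}); "
            "default curation would drop them")
    return CommunityBundle(table, sample_md, taxon_md, truth, spec)


def _draw_metadata(spec: SyntheticSpec, rng: np.random.Generator,
                   region: np.ndarray, sample_ids: list[str]) -> SampleMetadata:
    n = len(sample_ids)
    # each region occupies its own 1.5° × 2.5° box along a coastal gradient
    lat0 = 48.0 + 2.0 * region
    lon0 = -134.0 + 3.0 * region
    lat = lat0 + rng.random(n) * 1.5
    lon = lon0 + rng.random(n) * 2.5
    month = rng.choice(spec.months, size=n)
    year = rng.choice(spec.years, size=n)
    day_night = np.where(rng.random(n) < 0.75, "day", "night")
    if spec.confound_gear:
        # each region leans on a different net type
        probs = np.array([[0.8, 0.15, 0.05], [0.15, 0.8, 0.05],
                          [0.05, 0.15, 0.8], [0.6, 0.3, 0.1]])
        net = np.array([NET_TYPES[rng.choice(3, p=probs[r % 4])] for r in region])
    else:
        net = rng.choice(NET_TYPES, size=n, p=NET_PROBS)
    df = pd.DataFrame({
        "sample_id": sample_ids,
        "latitude": lat,
        "longitude": lon,
        "year": year.astype(int),
        "month": month.astype(int),
        "day_night": day_night,
        "net_type": net,
        "mouth_diameter_m": [MOUTH_BY_NET[t] for t in net],
        "mesh_size_um": [MESH_BY_NET[t] for t in net],
    })
    return SampleMetadata(df)


def _taxon_metadata(spec: SyntheticSpec, pool: np.ndarray,
                    taxon_ids: list[str]) -> TaxonMetadata:
    s = len(taxon_ids)
    # plant a many-to-one genus mapping: reuse genera for a fraction of species
    n_genera = max(1, int(round(0.744 * s)))          # 160 species -> 119 genera
    genus_idx = np.concatenate([np.arange(n_genera),
                                np.arange(s - n_genera) % n_genera])
    n_families = max(1, int(round(0.5625 * s)))       # 160 species -> 90 families
    family_idx = genus_idx % n_families
    groups = []
    for j, p in enumerate(pool):
        labels = {"holoplankton"} if j % 5 != 0 else {"meroplankton"}
        if "holoplankton" in labels and j % 3 != 2:
            labels.add("crustacean")
            if j % 2 == 0:
                labels.add("copepod")
        groups.append("|".join(sorted(labels)))
    df = pd.DataFrame({
        "taxon_id": taxon_ids,
        "rank": "species",
        "genus": [f"g{i + 1:03d}" for i in genus_idx],
        "family": [f"f{i + 1:03d}" for i in family_idx],
        "group_labels": groups,
        "curation_flag": 1,
    })
    return TaxonMetadata(df)


def make_study_fixture(seed: int = 0, separation: float = 1.0,
                           confound_gear: bool = False) -> CommunityBundle:
    """The desk-scale study stand-in: 4 regions, ~400 samples, 160 species.

    A handful of extra flagged taxa (curation_flag 2–4) are appended so the
    curation flag filter has work to do; metadata fields carry the gear
    descriptors the method-heterogeneity experiments group by.
    """
    spec = SyntheticSpec(seed=seed, separation=separation,
                         confound_gear=confound_gear)
    bundle = generate_community(spec)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF1A6)))
    n = bundle.table.n_samples
    extra_ids = [f"flagged{j + 1:02d}" for j in range(6)]
    extra_vals = np.where(rng.random((n, 6)) < 0.3,
                          np.rint(10.0 ** rng.normal(1.0, 0.5, (n, 6))), 0.0)
    data = bundle.table.data.copy()
    for j, t in enumerate(extra_ids):
        data[t] = extra_vals[:, j]
    table = AbundanceTable(data)
    extra_md = pd.DataFrame({
        "taxon_id": extra_ids,
        "rank": "other",
        "genus": [np.nan] * 6,
        "family": [np.nan] * 6,
        "group_labels": ["meroplankton"] * 6,
        "curation_flag": [2, 2, 3, 3, 4, 4],
    })
    taxa = TaxonMetadata(pd.concat([bundle.taxon_metadata.data.reset_index(),
                                    extra_md], ignore_index=True))
    return CommunityBundle(table, bundle.sample_metadata, taxa,
                           bundle.truth, spec)
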