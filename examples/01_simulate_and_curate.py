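"""Generate a synthetic multi-region zooplankton-like community and curate it.

The generator plants 4 latent bioregions with region-indicator, cosmopolitan,
and rare species; curation then removes flagged taxa, taxa rarer than 3 % of
samples, and samples with fewer than 15 species.
"""

from bioreg import AnalysisConfig, apply_curation_filters
from bioreg.synthetic import make_study_fixture

bundle = make_study_fixture(seed=1)
print(f"raw table: {bundle.table.n_samples} samples x {bundle.table.n_taxa} taxa")

cfg = AnalysisConfig(rng_seed=1)
curated, report = apply_curation_filters(bundle.table, bundle.taxon_metadata, cfg)
print(f"removed: {report.n_taxa_flag_removed} flagged taxa, "
      f"{report.n_taxa_rare_removed} taxa below {cfg.min_occurrence_fraction:.0%} "
      f"prevalence, {report.n_samples_low_richness_removed} samples below "
      f"richness {cfg.min_richness}")
print(f"curated table: {curated.n_samples} samples x {curated.n_taxa} taxa")
print(f"median sample richness: {curated.richness().median():.0f} species")
# The curated table is the input every later stage (dissimilarities,
# clustering, indices, robustness) consumes.
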