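"""Choose the number of bioregions from the goodness-of-clustering curves.

IndVal and silhouette vote for their best K directly; the other indices vote
through an elbow criterion and abstain when their curve has no clear elbow.
The modal vote is the suggested K (here the planted 4 regions).
"""

from bioreg import AnalysisConfig, apply_curation_filters
from bioreg.selection import build_score_cube, select_optimal_k
from bioreg.synthetic import make_study_fixture

bundle = make_study_fixture(seed=1)
cfg = AnalysisConfig(rng_seed=1)          # K = 2..20
curated, _ = apply_curation_filters(bundle.table, bundle.taxon_metadata, cfg)

cube = build_score_cube(curated, cfg)
ks = select_optimal_k(cube, "log_chord:kmeans", cfg)
print("per-index optimal K (None = no clear elbow, abstains):")
for index, k in ks.per_index.items():
    print(f"  {index:18s} {k}")
print(f"modal K = {ks.modal_k} (votes: {ks.counts})")
# The planted community has 4 regions; most indices should agree on 4.
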