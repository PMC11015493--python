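# bioreg — data-driven bioregionalization of community data

`bioreg` identifies **bioregions** — spatial units with characteristic
community composition — from site × species abundance tables, the way
biological oceanographers partition an ocean from zooplankton net samples.
Instead of picking one clustering recipe a priori, it runs a data-driven
method-selection protocol and then quantifies how robust the resulting
bioregionalization is to the messiness of compiled survey data (uneven
sampling, mixed gear, variable taxonomy).

It is a Python library first (see `examples/`), with a thin `bioreg` CLI for
shell pipelines.

## What it computes

**Method selection.** Three community dissimilarities — Bray-Curtis on
log10(x+1) abundances, d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ); Sørensen
(b+c)/(2a+b+c) on presence/absence; and Euclidean distance on the
**log-chord** transform (log10(x+1) then row-normalization to unit norm) —
are crossed with three algorithms (Ward.D2 hierarchical, K-means, PAM),
giving nine approaches. K-means needs coordinates, so the two matrix-only
variants are bridged through principal-coordinates analysis (all positive
axes). Every partition at K = 2–20 is scored by ten goodness-of-clustering
indices (IndVal, ISAMIC, OptimClass, TABDEV, TOTCHI, DISDIAM, PARTANA,
silhouette, within-cluster sum of squares, Calinski-Harabasz), each with a
declared ranking direction, all evaluated on the *same* inputs (the log
table and the log-chord dissimilarity). Approaches are ranked per (K,
index), compared by Kruskal-Wallis with Dunn and Wilcoxon rank-sum post
hocs (Benjamini-Hochberg adjusted), and the optimal K is chosen per index
(argmax for IndVal/silhouette, an elbow criterion for the rest) with a
modal vote.

**Robustness.** A reference partition is compared against re-clusterings of
data subsets. The **classification error** is the percentage of shared
samples assigned to a different cluster after optimally matching subset
labels onto reference labels (Hungarian assignment on the confusion
matrix), disaggregated by reference cluster. Experiment families cover
random sample/species fractions (5 % steps), gear-category subsets and
balanced draws, monthly/yearly/seasonal subsets, one-sample-per-grid-cell
spatial thinning at seven resolutions, and taxonomic variants
(genus/family aggregation, group restriction, rare-species inclusion,
presence-absence or biomass data).

**Synthetic communities.** `bioreg.synthetic` plants K latent regions with
region-indicator, cosmopolitan, and rare species, overdispersed lognormal
counts, and region-correlated metadata, so the whole pipeline is testable
without any download.

## Worked example

```bash
python examples/01_simulate_and_curate.py
python examples/04_robustness.py
```

prints (seed 1):

```
raw table: 400 samples x 166 taxa
removed: 6 flagged taxa, 28 taxa below 3% prevalence, 0 samples below richness 15
curated table: 400 samples x 132 taxa
median sample richness: 57 species

reference partition sizes: {1: 100, 2: 100, 3: 100, 4: 100}
sample_fraction 50%: mean error 0.00% (very low), range 0.00-0.00%
sample_fraction 25%: mean error 0.00% (very low), range 0.00-0.00%
species_fraction 25%: mean error 0.03% (very low), range 0.00-0.25%
species_fraction 5%: mean error 24.67% (moderately high), range 12.75-49.50%
```

Curation removed flagged and rare taxa but no samples; the 4-region map is
insensitive to halving the samples, while keeping only 5 % of the species
degrades it badly — community structure lives in the species, not in any
particular subset of sites. `examples/02_compare_approaches.py` and
`examples/03_select_k.py` show the method comparison (Mantel r = 0.96–0.99
between the three dissimilarities; Kruskal-Wallis χ² = 109.2, df = 8 on the
K = 2–8 demo grid) and the optimal-K vote (modal K = 4, the planted number).

The same pipeline from the shell:

```bash
bioreg simulate --preset study --seed 1 --out-dir sim
bioreg curate --abundance sim/abundance.csv --taxa sim/taxa.csv --out-dir cur
bioreg compare-approaches --abundance cur/curated_abundance.csv --seed 1 --out-dir cmp
bioreg select-k --scores cmp/scores.csv --out-dir cmp
bioreg bioregionalize --abundance cur/curated_abundance.csv --k 4 --seed 1 --out-dir bio
bioreg robustness --abundance cur/curated_abundance.csv --metadata sim/samples.csv \
    --taxa sim/taxa.csv --reference bio/partition.csv --battery --n-iterations 100 \
    --seed 1 --out-dir rob
```

Every command writes a `manifest.json` with the config snapshot, seeds, and
input digests, and identical inputs + seeds give byte-identical outputs.

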