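# Methods

This note documents the models, conventions, and design choices behind
`bioreg`, in the order the pipeline runs them.

## Data model and curation

The central object is an `AbundanceTable`: a samples × taxa matrix of
non-negative reals tagged with a `value_kind` (abundance, biomass,
presence/absence) and a `transform_state` (raw, log, chord, log-chord,
presence/absence). Transform functions check the state they require, so a
Bray-Curtis on raw counts or a Euclidean on un-normalized rows is a hard
error rather than a silent unit mistake.

Curation applies three filters:

1. **flags** — taxa whose `curation_flag ≠ 1` are removed (flags are
   data-driven labels supplied in `TaxonMetadata`; nothing taxonomic is
   hardcoded);
2. **prevalence** — taxa present in fewer than `min_occurrence_fraction`
   (default 3 %) of the current samples are removed;
3. **richness** — samples with fewer than `min_richness` (default 15)
   present taxa are removed.

Because removing samples can push taxa back below the prevalence threshold,
steps 2–3 are alternated to a fixed point. This makes the operation
idempotent — re-curating a curated table changes nothing — at the price of
occasionally removing slightly more than a single pass would; the
`CurationReport` records the counts per step and the number of passes, so
the result is auditable. Prevalence is always evaluated on the current
(curated) sample set, not the raw one. An empty result raises an
"all data filtered" error rather than returning an empty success.

## Transforms and dissimilarities

* log transform: `x → log10(x + 1)` by default. The log base (10 or e) and
  pseudocount are configurable; log10(x+1) is the dominant convention for
  zooplankton abundance data and neither constant is dictated by the
  protocol itself.
* chord: each sample row divided by its Euclidean norm. The **log-chord**
  transform is the composition (log, then chord); Euclidean distance on
  log-chord rows is bounded by √2 because rows are unit vectors in the
  non-negative orthant. Log breaks the chord transform's scale invariance,
  which is intended: fold-changes in abundance should matter.
* Bray-Curtis `Σ|x−y| / Σ(x+y)` on the log table (a semimetric — the
  triangle inequality is not asserted); Sørensen `(b+c)/(2a+b+c)` on
  presence/absence, which is exactly Bray-Curtis applied to the binarized
  table (a tested identity).
* Mantel test: Pearson correlation of strictly-lower-triangle vectors,
  one-sided (greater) permutation p-value with joint row/column permutations
  of the second matrix, `p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm)`,
  999 permutations by default. One-sided "greater" is the ecological
  convention when asking whether two dissimilarity structures concord.

## The nine approaches

Three data variants × three algorithms:

* **Ward** hierarchical clustering uses the ward.D2 convention (the
  Lance-Williams update on squared dissimilarities, as scipy implements
  it); merge heights are checked to be monotone, and cutting the tree at K
  then K−1 only merges clusters. The merge tree is exportable as Newick.
* **PAM** is the classic deterministic BUILD + SWAP: greedy seeding that
  minimizes total dissimilarity, then steepest-descent single swaps
  accepted only on strict cost decrease, ties broken by lowest sample
  index. Determinism means robustness variance comes only from the data
  subsets, never from PAM itself. Like every single-swap local search
  (including the canonical R implementation), PAM can terminate in a local
  optimum a few percent of the time on adversarial random matrices; tests
  assert the attainable contracts — swap-local optimality and final cost ≤
  BUILD cost — and global optimality on clearly separated instances.
* **K-means** runs on coordinates: log-chord rows directly, or, for the
  Bray-Curtis/Sørensen variants, the positive-eigenvalue axes of a
  classical principal-coordinates embedding (double-centred Gower matrix;
  negative-eigenvalue inertia is reported, and embedded distances reproduce
  the input exactly when it is Euclidean-embeddable). The protocol itself
  does not dictate how a dissimilarity-only variant meets a coordinate
  algorithm; PCoA is the standard bridge and is isolated behind
  `run_approach` so an alternative could be swapped in. K-means uses
  k-means++ seeding with 25 restarts, 300 Lloyd iterations, tolerance 1e-6,
  and a recorded seed; empty clusters are repaired internally by the
  underlying implementation.

The grid runner shares transforms, dissimilarities, embeddings, and Ward
trees across K, producing 9 × 19 = 171 partitions at the default K = 2–20.

## The ten indices

Evaluation is deliberately decoupled from the approach that produced a
partition: all ten indices are computed on the same log table and log-chord
dissimilarity, so values are comparable across approaches. Directions
(higher/lower = better) are fixed per index.

Abundance-table indices: **IndVal** (per species and cluster, specificity ×
fidelity × 100; the index is the mean over species of the per-species
maximum — the mean, rather than the sum, keeps the value on the 0–100 scale,
and the ranking protocol is invariant to that monotone choice at a fixed
species set), **ISAMIC** (2 · mean over clusters of |constancy − 0.5|,
averaged over species; 1 when every species is always present or always
absent within each cluster), **OptimClass** (count of species × cluster
pairs whose one-sided Fisher enrichment p — the upper hypergeometric tail —
falls below α = 0.001; species present everywhere or nowhere get p = 1 by
convention), **TABDEV** (summed binomial deviance of presence patterns under
cluster occurrence rates, 0·log 0 = 0), **TOTCHI** (correspondence-analysis
total inertia, χ²/N of each cluster's subtable after dropping all-zero rows
and columns, summed; singleton clusters contribute 0).

Dissimilarity indices: **DISDIAM** (mean per-cluster maximum within-cluster
dissimilarity; singletons count 0), **PARTANA** (mean between- over mean
within-cluster dissimilarity; computed directly on dissimilarities as a
between/within ratio with higher = better — a deliberate, documented
divergence from similarity-based formulations; all-singleton partitions are
undefined, a zero within-mean is reported as +∞ with a flag),
**silhouette** (standard, with members of singleton clusters contributing
0), **WSS** `Σ_k (1/2n_k) Σ_{i,j∈k} d²` and **Calinski-Harabasz**
`(BSS/(K−1)) / (WSS/(n−K))` with `TSS = (1/2n) Σ d²` — both equal their
coordinate-based closed forms on Euclidean inputs to 1e-9 (tested).

Undefined values (e.g. CH at K = n) are recorded as NaN, kept in the score
cube as flagged holes, and excluded from ranking slices — never silently
dropped.

## Ranking, statistics, and optimal K

Within each (K, index) slice the nine approaches are ranked 1 = best
(direction-aware, average ranks on ties); a slice with fewer than two
defined values is skipped with a warning. Two summaries are computed and
labeled separately: the per-index **median rank across K** (the boxplot
view), and the pooled per-(index, K) ranks — 190 observations per approach
on the full grid — which feed the Kruskal-Wallis test (df = 8 for nine
approaches; only the pooled view has enough observations for a meaningful
H). Dunn's post hoc (z on rank means with tie correction) and pairwise
Wilcoxon rank-sum tests are each Benjamini-Hochberg adjusted within their
own family of 36 pairs. The Wilcoxon test is unpaired (rank-sum, not
signed-rank). The winner is the approach with the best pooled median rank,
ties broken by the mean; an all-tied table declares no winner.

Optimal K: IndVal and silhouette vote for their best value over K; every
other index votes through an **elbow** rule made algorithmic as follows —
orient the curve so improvement decreases with K (negate higher-better
curves), take the K maximizing the second difference, and declare "no clear
elbow" (abstain) when that maximum is below 5 % (configurable) of the
curve's total range. The modal vote is reported with its full count table;
a tied mode is reported as a tie, never silently broken.

## Classification error and label matching

Cluster labels are arbitrary, so a subset partition is compared to the
reference only after matching labels: an injective assignment of test
labels onto reference labels maximizing total agreement (Hungarian
algorithm on the negated confusion matrix of shared samples). Majority-vote
mapping was rejected because it can be non-injective and inflate agreement.
The overall classification error is 100 × mismatches / shared samples;
per-reference-cluster contributions partition it exactly. Matching equals
exhaustive permutation search (fuzz-tested on thousands of confusions), so
a relabeled copy of the reference scores exactly 0 %.

Qualitative bins are upper-closed intervals [0, 5], (5, 10], (10, 15],
(15, 33], (33, 100] percent, named "very low" through "high"; their integer
endpoints match the conventional 0–5 / 6–10 / 11–15 / 16–33 / 34–100
labels, and a non-integer value such as 5.4 % falls in "low".

## Robustness experiments

Each experiment draws subsets per its spec, re-applies the log-chord
transform to the subset, re-clusters with K-means at the reference K using
fresh per-iteration seeds (deterministically derived from the experiment
seed via a seed sequence; the reference seed is not reused because subset
geometry differs), and scores the classification error. Iterations whose
subset has fewer than K samples, an all-zero sample row, or fewer than K
non-empty clusters are skipped and counted, never silently re-run.

Subset builders: sample/species fractions without replacement (⌈f·n⌉);
category subsets (metadata level membership); balanced category draws (the
minimum level size from every level, per iteration); month/year subsets
and balanced temporal draws; spatial thinning on half-open grid cells
`[i·r, (i+1)·r)` indexed by `floor(coordinate / r)` (floor, not truncation,
so negative longitudes bin correctly) with exactly one random sample per
occupied cell per iteration — one-per-cell is the reading of "even cell
representation", and the count is configurable; and deterministic taxonomic
variants (genus/family aggregation, functional-group restriction, rare-
species inclusion via re-curation with the prevalence threshold disabled
but the richness filter kept, presence-absence — binarize then chord —
and biomass tables). "Dominant categories" are formalized as the most
frequent levels cumulatively covering ≥ 80 % of samples.

The full battery generates 20 sample-fraction and 20 species-fraction specs
(5 % steps), per-category/dominant/balanced specs for each gear field,
per-month/per-year/seasonal/5-year/10-year/balanced temporal specs, the
seven grid resolutions 0.01°–2.0°, and the taxonomic variants, each
carrying its spec for provenance. Default 1000 iterations for randomized
specs; tests and the acceptance script run 100 (and the battery integration
test 1) to keep desk-scale runtimes, with sizes stated below.

## Synthetic communities

The generator plants `n_regions` latent regions. Species pools: region
**indicators** (occupancy 0.85 in-region vs 0.10 outside; mean log10
abundance 2.0 vs 0.5, σ = 0.7 lognormal, rounded to counts ≥ 1),
**cosmopolitans** (occupancy 0.9 everywhere, high abundance), and **rare**
species (occupancy 0.02, low abundance — these exercise the prevalence
filter). A `separation ∈ [0, 1]` knob interpolates the in/out contrast from
no signal to the full planted contrast; recovery of the planted partition
is monotone in separation (tested on a 0 / 0.5 / 1 grid). Metadata ties
each region to a disjoint lat/lon box and draws months (Apr–Oct), years
(1995–2014), day/night, and net type with mouth/mesh descriptors; an
optional switch confounds gear with region to emulate systematic
method-by-region sampling bias. Everything derives from one seed and is
bit-reproducible.

The default "study-scale" fixture has 4 regions × 100 samples and 160
retained species plus 6 flagged ones; at the default curation it keeps all
400 samples and ~130 species. What the generator does **not** emulate:
spatial autocorrelation within regions, species interactions, temporal
abundance dynamics, gradient (non-discrete) community turnover, and
detection differences between gears. Passing tests therefore demonstrate
the machinery is correct and the protocol recovers planted discrete
structure; they do not certify behavior on real gradient-dominated data,
where cluster boundaries are genuinely fuzzier.

## Numerical choices and problem sizes

* Ranks, medians, and all statistics use scipy/statsmodels primitives;
  ties get average ranks everywhere.
* Dissimilarity matrices are symmetrized to 1e-12, diagonals forced to 0,
  and stored read-only.
* PCoA keeps eigenvalues > 1e-9 × the largest; Ward heights tolerate
  −1e-9 jitter; chord norms are checked to 1e-12.
* Seeds: every stochastic component (K-means restarts, Mantel
  permutations, subset draws, the generator) takes an explicit seed;
  per-iteration seeds come from `numpy.random.SeedSequence` and stay below
  2³¹.
* Test and acceptance problem sizes: index oracles on 200 tables with
  n ≤ 12, S ≤ 10, K ≤ 4; label-matching oracles on 1000 confusions of size
  4–5; the selection protocol on the 400 × ~130 fixture over K = 2–20;
  robustness at 100 iterations per fraction. These sizes are chosen so the
  whole suite runs in well under a minute per module on a laptop core
  while still exercising every code path at full protocol width.

## Known limitations

* PAM's single-swap local search is not globally optimal on a few percent
  of adversarial instances (shared with the reference implementations);
  the grid comparison is unaffected in practice because all approaches are
  ranked by the same indices, but PAM partitions should not be read as
  exact k-medoid optima.
* The Kruskal-Wallis observations (per-(index, K) ranks) are not fully
  independent — indices are correlated — so the H statistic is a
  descriptive effect-size ordering more than a calibrated test; the post
  hocs inherit this caveat.
* OptimClass and TOTCHI curves often lack a clear elbow (they abstain from
  the K vote by design) and OptimClass is sensitive to α.
* The elbow rule reads only second differences; smooth curves with
  gradual knees abstain rather than guess.
* Biomass-based robustness requires the caller to supply a biomass table;
  the synthetic generator emits abundance (optionally interpretable as
  biomass) only.
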