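# Methods

## Model and procedure

`cmapmeta` treats connectivity mapping as a three-level stratified
enrichment problem over a perturbation reference.

**Level 0 — connectivity.** For query contrast *y* and reference experiment
*x_i*, the connectivity is the Spearman correlation
ρ_i = cor(R(x_i), R(y)), computed as Pearson correlation of average-tie
ranks on the gene intersection of query and reference. Genes are matched by
exact whitespace-trimmed identifier: no case folding and no alias
resolution, because silent symbol remapping is a larger hazard than a
slightly smaller intersection. Where either vector has missing entries the
pair is correlated on its pairwise-complete genes — missingness is
structural in landmark-gene assays, which measure only ~1000 genes — and a
constant (zero-variance) vector yields a missing ρ rather than a spurious
value. Missing ρ entries are dropped from all downstream rankings with a
logged count. All shared genes enter the correlation; no top-k truncation
of the query is applied, which is the most literal reading of the rank
statistic and keeps the operation parameter-free.

**Level 1 — compound scores.** Experiments are ranked by ρ (descending) and
each drug's experiment set D_j is scored by preranked GSEA, giving the
compound score x_j = NES(D_j, ρ). Drugs with fewer than
`min_experiments = 20` experiments in the reference are excluded: pooled
scores over very few experiments are dominated by single-experiment noise,
and 20 is the recommended floor. The boundary is inclusive (exactly 20 is
retained).

**Level 2 — MoA and target scores.** Drugs are ranked by their compound
NES and drug sets sharing an MoA label (M_j) or an annotated target gene
(T_j) are scored by the same GSEA engine: q_j = NES(M_j, x),
r_j = NES(T_j, x). Three deliberate choices:

* the stage-2 ranking metric is the compound NES itself, not a p-value —
  the NES carries the sign and the effect size;
* drugs whose NES is undefined (see below) are excluded from the stage-2
  universe, so enrichment is relative to what was actually scored rather
  than to the full annotation;
* a drug with k MoA labels belongs to all k sets (the annotation is
  many-to-many), and a drug with no labels contributes to no set but still
  occupies its rank position.

Drug names are matched against the annotation's `drug` column exactly
(no case normalization); the convention is documented rather than guessed.

## The GSEA engine

The enrichment statistic is the classic weighted Kolmogorov–Smirnov running
sum: walking the list sorted by decreasing statistic, a set member at
position *p* adds |s_p|^w / Σ_hits |s|^w and a non-member subtracts
1/(N − n_hits); the ES is the running-sum value of largest magnitude. The
weight exponent defaults to w = 1, the standard choice that rewards
enrichment among extreme statistics; w = 0 recovers the unweighted KS
statistic. The leading edge is the set members at or before the extremum
(at or after, for a negative ES).

The null is the only one available for preranked input: B random sets of
the same size (default B = 1000), drawn without replacement from the ranked
items under one seeded generator. NES = ES / mean(|same-sign null ES|), and
the p-value is one-sided within the ES sign with add-one smoothing,
p = (1 + #{|null_same| ≥ |ES|}) / (1 + #null_same), so p ≥ 1/(B+1) and
a permutation count can never produce p = 0. If no null value shares the
observed sign (possible for extremely lopsided statistics, e.g. an
annotation-free compound ranking where every useful score is positive) the
NES is reported missing with a warning and such entries are excluded from
stage 2. Benjamini–Hochberg is used for the adjusted q-values (delegated to
statsmodels), applied separately within each level and contrast — compound,
MoA and target results are distinct hypothesis families. Stage-2 set-size
filtering uses `min_set_size = 3`: with fewer member drugs a class
enrichment is indistinguishable from its best single drug.

Numerical conventions, chosen once for determinism:

* list sorting is by descending statistic with ties broken by item id
  ascending;
* a magnitude tie between the positive and negative running-sum extremum
  resolves toward the positive extremum;
* all-zero hit weights (possible at w > 0 when every hit statistic is 0)
  fall back to equal weights;
* all sets of equal size within one call share one null distribution — the
  null depends only on set size, so this is a pure performance measure and
  is tested against independent per-set nulls;
* every random draw flows from a single integer seed, and identical inputs
  plus seed give bit-identical results (the CLI reproduces output files
  byte for byte).

A set covering the whole ranked list is rejected (the miss normalizer is
zero), as is a set with no members on the list.

## Activation matrix

For multiple contrasts, the per-contrast top `top_n = 15` drugs by |NES|
(optionally gated by a q-value cap, default uncapped) are pooled; the
matrix holds NES / max|NES| over all shown cells, so values live in
[−1, 1] and signs are preserved; rows are ordered by descending row mean.
"Relative activation" is not given a formula by convention anywhere, so the
max-normalization is this package's own documented choice.

## Synthetic scenarios

`generate_scenario` emulates the structure that makes stratified pooling
necessary: ~1000 genes, tens of drugs, `experiments_per_drug = 25` repeats,
MoA classes and target annotations. The query is i.i.d. standard normal per
gene. Inactive experiments are i.i.d. Normal(0, noise_sd); an active
experiment with signed strength s is s·query + sqrt(1 − s²)·noise, mixed in
value space. With noise_sd = 1 this induces a bivariate-normal Pearson
correlation of exactly s, hence an expected Spearman of (6/π)·asin(s/2) —
about 0.48 at s = 0.5, slightly attenuated below s. Tests against planted
signal use this corrected expectation, verified empirically against the
closed form. Active drugs share one MoA label and one target gene; decoy
drugs draw labels round-robin from small pools so decoy classes clear the
stage-2 size filter. Active experiments are planted against the first
query contrast; additional contrasts are independent noise relative to the
reference.

The generator does **not** emulate dose–response ordering, cell-line batch
structure, landmark-to-inferred gene imputation, or correlated gene-gene
covariance. Passing tests therefore demonstrate that the pipeline recovers
monotone planted rank signal at realistic sizes and stays calibrated under
the null — not that it is robust to batch confounding in real catalogues.

Default sizes (50 drugs × 25 experiments, 1000 genes, 3 active drugs at
strength 0.5, B = 1000) run the full pipeline in under a second, so the
acceptance checks replicate over 10–20 seeds in well under a minute.

## I/O conventions

Reference headers encode the perturbagen as a prefix: `drug@profileID` or
`drug_profileID`. `'@'` takes precedence and the split is at the first
occurrence, because profile ids routinely contain underscores; a header
with neither separator becomes its own drug with a warning instead of an
error, so toy inputs work. Duplicate gene rows collapse to the row with the
largest |mean| (keeps the strongest signal, deterministically). Annotation
cells are `'|'`-delimited for multi-valued MoA/target entries, matching
common repurposing-hub exports. Matrices are read from TSV or GCT v1.2;
GCTX (HDF5) reading is available behind the same interface when h5py is
installed. Result tables are TSV with values printed to 10 significant
digits, sorted by level, contrast, then descending NES with name as the
tiebreak.

## Known limitations

* Connectivity variants (cosine, extreme-gene scores) and Kendall
  correlation are out of scope; the rank statistic is Spearman only.
* p-values are plain Monte-Carlo; no adaptive refinement below 1/(B+1).
* Cross-contrast consensus scores and within-drug stratification by cell
  line or dose are not computed.
* The stage-2 universe excludes NES-undefined drugs, so an annotation class
  consisting mostly of such drugs may be silently reduced below the size
  filter (the retained size is reported in `set_size`).
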