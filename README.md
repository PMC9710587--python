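# cmapmeta

Stratified connectivity mapping of gene-expression signatures against a
drug-perturbation reference.

Connectivity mapping asks: given a differential-expression signature — say,
disease vs. healthy, or treated vs. untreated — which catalogued
perturbagens (drugs, compounds) produce a similar or an opposite expression
profile? A similar profile hints at a shared mechanism; an opposite one
suggests a repurposing candidate that could counteract the queried state.
Catalogues like LINCS L1000 complicate this: each drug appears in dozens to
hundreds of experiments (cell lines × doses × times), and scoring
experiments one at a time drowns the signal in repetition.

`cmapmeta` instead scores the reference at three stratified levels:

1. **Connectivity.** For a query fold-change vector *y* and each reference
   experiment *x<sub>i</sub>*, compute the Spearman rank correlation
   ρ<sub>i</sub> = cor(R(x<sub>i</sub>), R(y)) on the shared genes.
2. **Compound scores.** Group experiments by drug: D<sub>j</sub> is the set
   of experiment ids of drug d<sub>j</sub> (parsed from column headers of
   the form `drug@profileID` or `drug_profileID`). Rank all experiments by
   ρ and score each drug with preranked GSEA — the weighted
   Kolmogorov–Smirnov running-sum statistic — yielding a normalized
   enrichment score x<sub>j</sub> = NES(D<sub>j</sub>, ρ). Drugs with fewer
   than 20 experiments are excluded by default for robustness.
3. **MoA / target scores.** Rank the drugs by their compound NES and run a
   second GSEA pass over drug sets sharing a mechanism-of-action label
   (M<sub>j</sub>) or an annotated target gene (T<sub>j</sub>):
   q<sub>j</sub> = NES(M<sub>j</sub>, x), r<sub>j</sub> = NES(T<sub>j</sub>, x).

Each NES carries a permutation p-value (random sets of the same size,
one-sided within the score's sign) and a Benjamini–Hochberg q-value,
adjusted within each level and contrast. For multiple query contrasts an
*activation matrix* summarizes the strongest signed compound scores across
contrasts. No external data is required: a synthetic-scenario generator
emulates the reference structure with planted ground truth.

## Worked example

Simulate a reference of 50 drugs × 25 experiments on 1000 genes with three
active drugs planted at correlation strength 0.5, then analyze it:

```
cmapmeta simulate --seed 7 --outdir sim --n-genes 1000 --n-drugs 50 \
    --experiments-per-drug 25 --n-active 3 --strength 0.5
cmapmeta run --query sim/query.tsv --reference sim/reference.tsv \
    --annotation sim/annotation.tsv --outdir out --seed 42
```

`out/results.tsv` begins (columns truncated):

```
level     contrast   name         set_size  es      nes     pval      qval
compound  contrast1  drug02       25        0.962   1.798   0.00115   0.0192
compound  contrast1  drug01       25        0.960   1.795   0.00115   0.0192
compound  contrast1  drug03       25        0.959   1.793   0.00115   0.0192
compound  contrast1  drug42       25        0.312   0.584   0.916     0.997
...
moa       contrast1  planted-moa  3         1.000   1.914   0.00254   0.0228
target    contrast1  PLANTED1     3         1.000   1.914   0.00254   0.0228
```

The three planted drugs (drug01–drug03) head the compound ranking with
NES ≈ 1.8 and q < 0.05 while every inactive drug is insignificant; the
planted mechanism class and target gene likewise rank first at their
levels. `out/activation.tsv` holds the drugs × contrasts activation values
(here drug02 tops at 0.973), `out/manifest.txt` records every parameter,
seed and input checksum, and `out/plots/` contains the enrichment curves
for the top and bottom drug, NES barplots per level, and the activation
dot matrix. Re-running with the same flags reproduces every output byte
for byte.

The same analysis is available as a scikit-learn-style estimator:

```python
from cmapmeta import ConnectivityMapper
from cmapmeta.synthdata import generate_scenario

query, ref, ann, truth = generate_scenario(seed=7)
table = ConnectivityMapper(random_state=42).fit(ref, ann).transform(query)
```

To analyze real data, point `--query` and `--reference` at tab-delimited
(or GCT v1.2) matrices with gene identifiers in the first column, with
reference headers prefixed `drug@profileID`, and `--annotation` at a
CSV/TSV with columns `drug`, `moa`, `target` (multi-valued cells joined
with `|`).

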