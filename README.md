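# repliorg

Replication-origin-biased genome organisation analysis for circular
prokaryotic chromosomes with multiple replication origins.

Crenarchaea of the genus *Sulfolobus* replicate their single circular
chromosome from three unevenly spaced origins that fire in near synchrony,
so distance to the nearest origin is a proxy for replication timing. This
package implements the full analysis chain for asking whether genome
organisation tracks that distance:

- **two-channel microarray expression**: background-subtracted log2
  cDNA/gDNA ratios (gDNA from stationary cells, in which all loci are at
  equal copy number), per-array mean-centring, averaging first over
  replicate spots and then over arrays;
- **circular-genome geometry**: modular origin distances, intergenic gaps
  of divergently transcribed adjacent gene pairs, union coding density;
- **archaeal core genes**: COGs present in single copy in every considered
  genome (multi-copy families excluded, symbionts excludable), mapped onto
  genes;
- **window tracks**: the six organisation features over 100 kb sliding
  (1 kb steps) or non-overlapping windows, written as bedGraph/TSV;
- **rank statistics**: Spearman correlations and Mann-Whitney tests with
  exact enumeration p-values on small tie-free samples, the pairwise
  window-feature correlation matrix, and the 12-bin expression-stratified
  test of whether core genes sit near origins independently of expression;
- **gene-dosage null model**: in an exponentially growing population a
  locus replicated at cell-age fraction *a* averages `2^(1-a)` copies per
  cell, so the earliest/latest copy ratio is `2^(S-phase fraction)` —
  about 1.26-fold for an S phase of a third of a generation, and never
  more than 2-fold — far below the observed expression gradients;
- **synthetic data**: a generator that emulates all of the above with
  known injected gradients (configurable slopes, logistic core/transposon
  placement, distance-dependent intergenic gaps, duplicate spots ×
  triplicate arrays, low-quality spot fraction), so every stage is
  testable without external downloads.

It is aimed at readers who want to rerun or stress the analysis on their
own annotations and spot tables, or to use the generator as a ground-truth
test bed for similar replication-timing analyses.

## Worked example

The numbered scripts under `analysis/` run the whole study on a full-scale
synthetic dataset (2.2 Mb, three origins, ~2,100 genes):

```sh
python analysis/01_simulate_data.py
python analysis/02_expression_pipeline.py
python analysis/03_window_organisation.py
python analysis/04_core_gene_confound.py
python analysis/05_dosage_null_model.py
python analysis/06_method_validation.py
```

Output of steps 02, 04 and 05 (verbatim):

```
2100 of 2100 genes carry expression after filtering
gene-level expression vs origin distance: rho = -0.43, P = 1.74e-96 (n = 2100)
proximal/distal (quartile) expression fold: 3.17x
  core_only              rho = -0.21, P = 0.00541, n = 179
  noncore_only           rho = -0.44, P = 7.81e-91, n = 1921
  excl_txn_translation   rho = -0.43, P = 3.46e-90, n = 1943

core genes higher expressed overall: Mann-Whitney P = 8.33e-06 (179 core vs 1921 non-core)
12/12 bins held both core and non-core genes; origin distance differed (P < 0.05) in 11 of them (expression differed in 1).
direction 'core shorter' in 11/12 usable bins

dosage model: S phase = 1/3 of generation -> earliest/latest copy ratio 1.26 (~1.3-fold); hard upper bound 2.0
observed proximal/distal expression fold: 3.17x (2.5x beyond what dosage alone predicts)
```

Reading: expression declines with origin distance genome-wide (rho = −0.43
over 2,100 genes); the gradient survives excluding transcription/translation
genes and holds within core and non-core genes separately (weaker in the
small core set); core genes remain nearer to origins in 11 of 12
expression-matched bins, so their clustering is not an expression artefact;
and the observed expression fold is well beyond the ≤ 2-fold that gene
dosage alone could produce. Step 03 prints the pairwise Spearman matrix of
the six feature tracks over 22 non-overlapping 100 kb windows (expression,
core density and coding density negative against origin distance;
divergent-pair distances and transposon density positive), and writes
sliding-window bedGraph tracks under `results/run/tracks/`.

The same stages are available as a CLI for running on your own data
(`repliorg simulate | normalize | distance | windows | correlate | bins |
dosage-curve | run`); `repliorg run --config cfg.yaml` executes the whole
pipeline from one YAML file. Gene annotations are read from GFF3 or a TSV
gene table, spot tables from GenePix-like TSVs with configurable column
names.

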