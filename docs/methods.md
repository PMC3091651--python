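# Methods

## The problem

Sulfolobus species carry a single circular chromosome with three replication
origins that fire in near synchrony; because the origins are unevenly
spaced, replication terminates asynchronously. Distance along the circle to
the nearest origin is therefore a proxy for replication timing under
constant fork speed. `repliorg` quantifies how genome organisation tracks
that distance: per-gene expression from two-channel microarrays, archaeal
core-gene density, protein-coding density, intergenic distances between
divergently transcribed neighbours, and transposon density — together with
a gene-dosage null model that bounds how much of an expression gradient
replication timing alone can produce.

## Coordinate model

All coordinates are 0-based half-open on a circle of length L; a gene with
`end < start` wraps across position 0. The origin distance of a position is
`min over origins o of min(|p-o|, L-|p-o|)`, which lies in `[0, L/2]`. A
gene's reference point is its modular midpoint — the chromosome does not
say whether a long gene "is" at its start or end, and the midpoint is
unbiased for either. Divergent pairs are *immediately* adjacent genes in
(−,+) strand order (5' ends facing across a shared upstream region);
adjacency wraps across position 0, and overlapping divergent genes get gap
0 so the quantity stays a non-negative distance. Coding density of an
interval is the fraction of its base pairs covered by the union of
protein-coding spans (overlaps counted once), computed from a merged
segment list with a prefix-sum coverage function so window tracks cost
O(log n) per window.

## Two-channel expression

Labelled cDNA is co-hybridised against genomic DNA from stationary-phase
cells. Stationary cells hold only fully replicated chromosomes, so every
locus is at equal copy number in the reference channel and the
background-subtracted log2 cDNA/gDNA ratio estimates relative transcript
abundance; any multiplicative probe effect common to both channels (spot
amount, hybridisation efficiency) cancels exactly in the ratio. Processing:

1. drop spots flagged low-quality or with foreground ≤ background in either
   channel (the quality flag is consumed as input, not recomputed);
2. per-array mean-centring of log ratios (mean, not median);
3. per-gene averaging first over replicate spots, then over arrays — arrays
   contribute equally regardless of how many replicates survived.

A gene losing all spots is absent from downstream tables, not zero. With
noise-free inputs the pipeline inverts the generative model exactly up to
the one additive constant the centring removes (checked to 1e-9).

## Core genes

The archaeal core is called from a genomes × COGs copy-count matrix: a COG
is core iff it is present in *exactly one* copy in every considered genome.
Absence anywhere disqualifies; so does any genome with ≥ 2 copies (large
families are unlikely to be uniformly essential — the motivating example is
an acetyl-CoA acetyltransferase COG with 11 copies in one genome). Reduced
symbiont genomes can be excluded from the requirement. Orthology inference
itself is out of scope: the matrix and the gene→COG map are inputs.

## Window tracks

Two window modes over the circle: sliding (default 100 kb windows
translocated in 1 kb steps, wrapping across position 0 — the visualisation
geometry) and non-overlapping (abutting 100 kb windows — the inference
geometry). Genes join a window by modular midpoint; divergent pairs by the
midpoint of their intergenic gap; windows with no qualifying members carry
a missing value. Transposon density is the *proportion of member genes*
labelled transposon, not a bp fraction. Window-level correlations are
computed on non-overlapping windows only: adjacent sliding windows share
99% of their content, so their n would be fictitious; a config switch
exists for readers who want the sliding version anyway.

## Rank statistics

Spearman's rho is the Pearson correlation of mid-ranks. Its two-sided p is
exact — full enumeration of the n! rank permutations, cached per n — for
tie-free samples with n ≤ 10, and otherwise uses the t approximation
`t = rho·sqrt((n-2)/(1-rho^2))` on n−2 df (at n = 10 the two agree within
0.013 over random draws). Mann-Whitney U credits ties 0.5; the p-value is
exact by enumeration of group assignments when the pooled sample is
tie-free, the smaller group has ≤ 8 observations *and* the number of
assignments C(n1+n2, n1) stays below 100,000 — the budget keeps every
balanced small case exact while preventing a 5-vs-500 comparison from
demanding 10^10 enumerations; everything else uses the normal approximation
with tie correction and a 0.5 continuity correction (verified to match an
independent implementation digit-for-digit, and calibrated: type-I rate
0.0498 at 54 vs 121 over 20,000 null draws). All p-values are two-sided and
clamped into (0, 1].

The confound analysis sorts genes by expression (stable ties) into n_bins
contiguous bins whose sizes differ by at most one, earlier bins taking the
remainder. Within each bin holding both categories it runs Mann-Whitney on
expression (the check that binning removed the expression difference) and
on origin distance, recording the direction of the median difference. Bins
are counted at raw α (default 0.05) with no multiple-testing correction —
the quantity of interest is the count itself.

## Gene-dosage null model

In a steady-state exponential population the cell-age density is
`f(a) = 2 ln2 · 2^(−a)` on [0, 1]. A locus replicated at age `a` has mean
copy number `2^(1−a)`. With synchronous firing and equal constant fork
speed, replication age is linear in origin distance:
`a(p) = s_start + s_duration · d(p)/d_max`. The earliest/latest copy ratio
is then `2^(s_duration)` — independent of when S phase starts, equal to
2^(1/3) ≈ 1.26 for an S phase of a third of the generation time, and never
above 2. Defaults: `s_start = 0.1` (short pre-replicative phase),
`s_duration = 1/3`. A Monte-Carlo population (inverse-CDF age sampling)
reproduces the closed form within 0.5% at 10^6 cells. Stochastic origin
firing and termination-zone effects are not modelled.

## Synthetic data

The generator emulates the study system so that every stage has a ground
truth. Full-scale preset: L = 2.2 Mb; origins at (0, 700 kb, 1 250 kb),
giving inter-origin arcs of 700/550/950 kb and a maximum origin distance
d_max = 475 kb. Genes are laid down in one walk around the circle:
lognormal lengths (median 750 bp, log-sd 0.6, clipped to [100, 5000]) and
exponential intergenic gaps whose mean grows linearly with origin distance
(60 bp at an origin, +0.4 bp per kb), yielding ~2,100 genes. Per gene:

- true log2 expression `beta0 + beta1·d + N(0, sigma)` with
  `beta1 = −5.0e-6 log2/bp` and `sigma = 1.32`;
- core label ~ Bernoulli(logistic: intercept −0.8, slope −1.2e-5/bp), so
  ~8% of genes are core, strongly depleted far from origins;
- transposon label (mutually exclusive with core) ~ Bernoulli(logistic:
  intercept −4.5, slope +6.0e-6/bp), ~4% of genes, enriched distally;
- an independent 8% "transcription/translation" functional label, used to
  exercise category-restricted correlations.

Calibration of `beta1` and `sigma` (fixed once, from the study conditions):
the proximal→distal span `|beta1|·d_max ≈ 2.4 log2` units reproduces a
greater-than-4-fold expression range between the extremes, and `sigma` is
set so the population Spearman between distance and expression is ≈ −0.4
(for d roughly uniform per arc, σ_d ≈ 121 kb, the Pearson signal fraction
is `|beta1|σ_d / sqrt(beta1²σ_d² + sigma²) ≈ 0.42`, i.e. ρ_S ≈ 0.40 via the
bivariate-normal rank mapping). The recovered correlation in the
exponential condition runs slightly stronger (≈ −0.44) because the dosage
term adds its own distance-coupled log2(copy) component — exactly as in the
real system, where the measured gradient also contains the dosage part.

The array model: per (gene, replicate, array) spot, one lognormal probe
efficiency multiplying *both* channels (log-sd 0.5); per-array channel
scales (log-sd 0.3, removed by mean-centring); cDNA signal proportional to
`2^expression × copy(d)` in exponential phase (copy = 1 in stationary);
gDNA signal proportional to 1 (stationary reference); additive background
(mean 50) reported alongside; lognormal measurement noise (log-sd 0.15) per
channel; 5% of spots flagged low-quality at random. 3 arrays × 2 replicate
spots. All randomness flows from one integer seed through fixed per-stage
substreams, so changing the number of arrays cannot perturb the genome
draw, and identical parameters give byte-identical outputs.

The scaled-down test preset shrinks the chromosome 11× (200 kb, origins at
0/64/114 kb) and scales every per-bp coefficient up 11×, preserving all
dimensionless gradients with ~200 genes; the default test suite runs mostly
at this scale.

What the generator does **not** emulate: operon structure (expression noise
is i.i.d. per gene, not shared along polycistronic units), sequence
content, intensity-dependent dye bias (so loess-style normalisation is
deliberately absent), spatial print-tip artefacts, and genome
rearrangements. Passing tests therefore show that the pipeline recovers
gradients of this idealised form, not that real-array artefacts are
handled.

## Validation experiments and problem sizes

- **Gradient recovery**: 20 independent full-scale replicates; the pipeline
  recovers gene-level rho ≈ −0.44 ± 0.02, every replicate at P far below
  10^-5.
- **Null calibration**: 500 replicates with all distance coefficients zero
  in the stationary condition (the exponential condition is *not* a null:
  its dosage term is a real distance signal). Rejection rates of the
  gene-level correlation and of the per-bin distance tests at α = 0.05 sit
  inside the 99% binomial envelope.
- **Confound analysis**: replicates with `beta1 = 0` (expression carries no
  distance signal, so the groups are expression-matched by construction)
  and the default negative core-distance coefficient: essentially all
  usable bins are significant for distance with direction "core shorter",
  while per-bin expression tests fire at ~α.
- **Kernel oracles**: circular distance, coding density, window means and
  the exact Spearman/Mann-Whitney p-values agree with brute-force
  enumeration on over a thousand random small instances (max deviation 0).

## Degenerate inputs and tie-breaking

Empty spot tables are legal (logged, empty outputs); genes with no
surviving spots vanish rather than becoming zeros. Zero rank variance
raises an explicit undefined-correlation error instead of returning NaN.
Equal medians in a bin record direction "tied". Expression ties in binning
are broken by stable input order. Windows never exceed the chromosome;
full-circle intervals are not representable in the `[a, b)` interval API
(use a window of size L). GFF3 cannot encode a wrap-around gene; the TSV
gene table can (`end < start`), and the generator never emits wrap genes.

## Known limitations

Exact Mann-Whitney p-values are skipped for extremely unbalanced group
pairs (enumeration budget above); replication timing is linear in distance
(no fork stalling, no stochastic firing); window assignment is by midpoint
with no fractional overlap weighting; the Table-1-style correlation uses
whatever genes carry the needed attributes per track rather than one fixed
gene universe; and the dosage model's 1.26-fold ratio reproduces the
measured marker-frequency value only under its idealisations.
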