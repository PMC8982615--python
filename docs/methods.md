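# Methods

## Fitness readout and normalization

A transposon library is a pool of insertion mutants competed over many
growth cycles; the insertions surviving in a gene measure how dispensable
that gene is under the tested condition. The package's currency is the
per-gene transposon count (number of distinct insertion sites) and read
count (clone abundance), kept side by side because both are informative:
TN counts are robust to PCR jackpots, read counts carry abundance.
TN counts are the default everywhere.

Counts are normalized to the per-library total of mapped events —
including intergenic sites, which form the depth reference unaffected by
selection on genes:

x̃_gℓ = (x_gℓ + c) (N_ℓ + cG)⁻¹ · 10⁶.

The pseudocount c (default 1 raw count per gene per library) keeps
log fold changes finite for fully depleted genes and shrinks noise in
low-coverage genes; it is applied symmetrically to every library. With
c = 0 the transform is exactly scale-free: multiplying one library's
counts and total by any factor changes nothing downstream (this is the
tested invariance; with c > 0 the invariance is approximate at low
counts by construction).

Coordinates follow one internal convention — 0-based half-open — with
dialects honored at the file boundary: BED taken as-is, WIG shifted from
1-based, GFF3 converted from 1-based inclusive. Strand is recorded but
ignored in gene assignment, since transposon disruption is orientation-
agnostic. A site inside k overlapping genes increments all k (no
fractional assignment). Gene termini are not truncated; a truncation
fraction parameter exists (default 0) for sensitivity analysis, since
some insertion-screen pipelines exclude gene ends. No repeat or
pericentromeric masking is applied.

## Volcano comparisons

For disjoint library sets T and R, each gene gets
log₂FC = log₂(x̄_T / x̄_R) and a two-sided Student's two-sample t-test
(pooled variance) over per-library normalized counts. The equal-variance
form is the primary statistic; Welch is available behind a flag.
Degenerate cases are explicit: p is undefined (NaN, class *untestable*)
when either set has fewer than two libraries, and when both sets are
constant with different means; both sets constant at the same value give
p = 1. Undefined p-values are always reported, never dropped — single-
library comparisons still carry a fold change. Classification defaults:
*required* = p < 0.05 ∧ log₂FC < −0.5; *dispensable* = p < 0.05 ∧
log₂FC > 2. No multiple-testing correction is applied to the volcano
calls (thresholds operate on raw p, matching how such screens are read);
a Benjamini–Hochberg column is emitted alongside for users who want it.

## Profiles and clustering

Variable genes are ranked by the sample StdDev (n−1) of normalized TN
counts across libraries, ties broken lexicographically so output is
reproducible. Library clustering is agglomerative with the Ward
criterion on Euclidean distances over raw normalized counts (no feature
scaling by default; a log₂(x+1) variance-stabilization flag exists). The
co-essentiality clusterogram computes pairwise Pearson r of gene
profiles over the top-k variable genes (default k = 500; restricting to
variable genes suppresses noise from genes whose counts barely move) and
Ward-clusters on distance 1 − r, the standard co-fitness convention.
Zero-variance genes get undefined correlations and are excluded from
clustering with a warning. Dendrograms are exported as Newick.

Because selection by absolute StdDev favors long genes (their counts,
and hence count fluctuations, are larger), depletion signal in very
short genes can rank below the sampling noise of long neutral genes;
this mirrors the real detection limit of insertion screens and is why
the module-recovery experiment (below) plants its modules in genes of
near-median length.

## Saturation pairs and flux ratios

The remodeling readout compares, within each phospholipid class, 0- vs
1-double-bond species for ≤30 total acyl carbons and 1- vs 2-double-bond
species for ≥32 carbons. The per-class, per-sample fraction

f = Σ(more unsaturated) / Σ(more + less)

pools the two carbon groups intensity-weighted (one number per class per
condition; a per-chain-group mode exists). A sample missing a pair
member entirely yields an undefined fraction rather than an implicit
zero, to avoid biasing remodeling estimates. Group differences use
two-sided two-sample Student's t-tests over replicate fractions, with no
correction across classes (per-class calls). Species nomenclature is
"CLASS C:D"; ether/odd-chain species fall outside the pairs.

Flux ratios from ¹⁵N pulse labeling follow the CDP-DAG order PS → PE →
PC: ratio-to-precursor = ¹⁵N-product / ¹⁵N-precursor per timepoint
(PS has none), ratio-to-unlabeled = ¹⁵N-X / ¹⁴N-X. Both are invariant to
per-timepoint intensity rescaling (instrument drift). Raw intensities
are used, not mole fractions. Zero denominators give undefined points,
logged.

## Synthetic-data generator

The generator emulates the screen's study conditions with known truth:

- **Genome**: log-normal gene lengths (median 1.4 kb, σ = 0.55 — the
  scale of the yeast ORFeome), placed without overlap on 3 chromosomes
  with random intergenic gaps filling ~31% of the genome (yeast is ~70%
  coding).
- **Insertions**: uniform over the genome. No target-site bias model is
  applied (a known limitation; real Ac/Ds transposition has hotspots).
- **Selection**: an insertion in gene g survives with probability
  d(g, condition)^(cycles/13), capping at 1 — depletion compounds
  exponentially over growth cycles, normalized so the stated depletion
  factor is the retention after the 13-cycle minimum of the protocol;
  intergenic insertions always survive. Insertions landing on the same
  position/strand merge into one site (sites are unique positions).
- **Reads**: 1 + negative binomial (size 0.5, mean 20) per retained
  site — strongly overdispersed, as PCR/sequencing jackpots make real
  read counts.
- **Scale**: desk default 10⁵ insertions/library over a ~2 Mb, 1000-gene
  genome (the published scale of 2×10⁶–1.5×10⁷ events over 12 Mb is a
  parameter away). The per-bp insertion density of the default is
  comparable to saturated real libraries.
- **Determinism**: every draw comes from streams derived from the config
  seed; identical config + seed reproduce outputs byte for byte.

What the generator does *not* model — biological replicate structure
(each simulated library is an independent insertion pool, so all-neutral
libraries are exchangeable noise and do not cluster by genotype the way
real replicate libraries sharing a transposition pool do), chromatin or
sequence insertion bias, gene-gene interactions, and read-mapping
artifacts. Passing recovery tests therefore demonstrates that the
statistics recover the programmed fitness structure from realistic
counting noise, not that they are robust to alignment or bias artifacts.

The lipidome generator places, per class, pair species at 28/30 carbons
(0/1 double bonds) and 32/34 carbons (1/2), plus an outside-pair
species holding 10% of the class. The warm more-unsaturated fraction is
0.40; cold shifts it by δ (default +0.10) in the wild type and β·δ in
the mutant (β = 0 reproduces a remodeling-blind genotype). Replicate
intensities get mean-preserving log-normal noise (CV 5%, n = 3 — the
experiment's replicate scale). Labeling uses a linear three-compartment
chain with constant uptake u and rates k₁ (PS→PE), k₂ (PE→PC), solved
exactly via the matrix exponential of the augmented system; labeled
pools start at zero, so every pool is proportional to u and precursor
ratios depend only on the rates — the structure that makes precursor
normalization separate transport/conversion from uptake. The labeling
series is deterministic (no noise) so that ratio identities are exact.

## Validation experiment sizes

The validation suite (mirrored by `scripts/acceptance.py`) uses:

- counting oracle: 100 random instances, ≤50 genes (overlapping
  allowed), ≤10⁴ sites, vs a brute-force membership scan;
- t-test: 1000 random instances vs the closed form; 100 instances vs a
  4000-permutation oracle, with effect sizes drawn uniform(−1.5, 1.5) so
  p-values span a wide range while staying above the permutation
  resolution floor 1/(n_perm+1) — beyond it all strong effects tie and
  rank agreement is uninformative;
- conditional-essentiality recovery: the full design (24 libraries,
  1000 genes, 10⁵ insertions/library, 50 genes at depletion 0.05 in 3
  OFF conditions, 3 test vs 3 reference libraries);
- type-I calibration: 10 all-neutral screens of 300 genes, 12 libraries,
  2×10⁴ insertions each;
- module recovery: 10 screens of 200 genes, 24 libraries, 5×10⁴
  insertions each; modules of 4, 4, 3 genes planted in near-median-length
  genes with distinct condition patterns; correlation over the top 50
  variable genes (50/200 matches the proportion of the 200–500 most
  variable of ~6600 used in real screens);
- remodeling: 10 seeds at δ = 0.10, β = 0, n = 3, CV 5%.

These sizes were chosen to make each effect measurable at desk scale
while exercising exactly the code paths used at full scale.

## Known limitations

Uniform insertion model; no bias correction or masking; equal-variance
t-test assumes comparable within-set spread (Welch available); the
pseudocount default trades a small bias at low counts for finite fold
changes; co-essentiality detection is limited by variable-gene selection
on absolute StdDev, which under-ranks short genes.
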