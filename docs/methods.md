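# Methods

## The model

`riscape` simulates a continuously distributed, dioecious, diploid
population on a binary habitat map, to study when spatially heterogeneous
viability selection lets reproductively isolated clusters of genotypes
emerge and persist inside a single population, without any geographic
barrier.

Reproductive isolation comes from a two-locus Dobzhansky–Muller
incompatibility. Individuals carry `n_loci` unlinked biallelic loci; locus
0 (alleles *A*/*a*) and locus 1 (alleles *B*/*b*) are under selection, the
rest are neutral markers. Alleles *a* and *B* are jointly lethal: the four
classes carrying both (*AaBB*, *AaBb*, *aaBB*, *aaBb*) have zero viability
everywhere. The two doubly homozygous classes *AABB* and *aabb* are
therefore mutually incompatible — all their F1 offspring are *AaBb* and die
— while *AABb*, *AAbb* and *Aabb* can act as genetic "bridges" between
them. Heterogeneous selection favors *AABB* in one habitat type and *aabb*
in the other: with selection strength *s*, the favored homozygote survives
settlement with probability 0.5 + *s*/2 in its own habitat and 0.5 − *s*/2
in the other, and the three bridge classes sit at the 0.5 baseline in both
habitats. An optional `het_gradient` mode instead gives *AABb*/*Aabb* a
half-strength gradient (0.5 ± *s*/4) following their homozygous background;
it is off by default because the flat-0.5 table is the operational
definition used everywhere else in the package.

### Generation cycle

Generations are non-overlapping. Each generation:

1. **Mate selection.** Every female draws one male from those within the
   maximum movement distance, with probability ∝ 1/*d*² (truncated
   inverse-square kernel). Males mate with replacement; a female with no
   male in range produces nothing.
2. **Reproduction.** Each pair produces Poisson(mean 4) offspring.
   Inheritance is Mendelian with free recombination; each allele copy then
   mutates (flips, K = 2 allele model) with probability `mu` (default
   5 × 10⁻⁴ per copy per generation). Offspring sex is i.i.d. uniform.
3. **Adult mortality.** All adults die.
4. **Dispersal and settlement.** Offspring are processed in random order.
   Each draws a vacant home site from the same truncated inverse-square
   kernel around its natal site (= mother's site); it then survives
   settlement with the probability its genotype class has in the habitat of
   that site. Failed settlers die and leave the site vacant for later
   settlers; settlement ends when all sites are occupied or the pool is
   spent, so excess offspring are discarded once the carrying capacity
   (`n_sites`, default 5000) is reached.

The same maximum movement distance (`max_move_frac` × landscape extent)
truncates both mating and dispersal; it is the experiment's dispersal
factor (3, 5, 10, 15, 25, 50% of extent). A site at distance zero (the
natal site itself) is never a kernel candidate, which keeps 1/*d*² finite;
vacated natal sites at positive distance are ordinary candidates.

### Burn-in semantics

Runs start from maximum diversity (every allele i.i.d. uniform) and run a
burn-in (default 250 of 1250 generations) before habitat-dependent
selection switches on. Two readings of "no selection during burn-in" are
possible, and the package had to choose:

* **Incompatibility always on (default).** The zero-viability rule applies
  from generation 0; burn-in withholds only the habitat-dependent
  mortality (viable classes settle unconditionally). The *a*/*B*
  combinations are purged gradually while spatial genetic structure builds
  up, so the later onset of habitat selection is a mild shock (baseline
  mortality only). This matches the pure isolation-by-distance regime that
  the *s* = 0 control reenacts, and is the only reading under which
  desk-scale populations survive selection onset: with a fully neutral
  burn-in, 9/16 of offspring (at Hardy–Weinberg frequencies near 0.5)
  become inviable in a single generation *and* baseline mortality halves
  recruitment, which in our measurements drove small populations extinct
  within ~10 generations of onset regardless of selection strength.
* **Fully neutral burn-in** (`incompatibility_during_burn_in=False`): no
  viability selection of any kind until burn-in ends. This is the right
  configuration for drift validation and capacity checks (Wright–Fisher
  comparisons, constant-population-size tests), and is used there.

### Landscapes

Habitat maps are neutral landscape models: midpoint-displacement
(diamond-square) fractal surfaces whose displacement standard deviation
shrinks by 2^(−H) per subdivision level, rank-binarized so that *exactly*
half the cells (or any requested proportion `p`) are habitat 1. The
aggregation parameter H ∈ [0, 1] tunes spatial autocorrelation: join-count
aggregation (share of rook-adjacent like pairs) rises monotonically with H
(measured ≈0.83 at H = 0.1, ≈0.95 at H = 0.5, ≈0.99 at H = 0.9 on 256²
maps). Binarization thresholds cell *ranks*, with ties broken in
raster-scan order, so the 50/50 split is exact on every replicate rather
than approximate. Rasters read/write the ESRI ASCII grid dialect.

The default cell size is 100 distance units, making the published
1024 × 1024 map 102,400 units across. The physical unit is a package
convention (no physical extent is inherent to the model); it was chosen so
that the cluster-detection radius ε = 2000 is ~2% of the extent — below
the smallest dispersal level — keeping detected clusters sub-dispersal-
scale. Desk-profile maps shrink the extent but preserve the full-scale
*site density* (individuals per unit area), so absolute quantities like ε
keep their meaning.

### Cluster detection and RI events

Each post-burn-in generation, DBSCAN (ε = 2000 distance units, k = 4
points, the point itself counted) is run separately on the positions of
*AABB* carriers and *aabb* carriers. A generation is an **RI event** when
both genotypes form at least one cluster — two groups present
simultaneously whose hybrids are inviable. Maximal runs of consecutive
event generations give event **duration**; **number** is the pooled
AABB + aabb cluster count and **size** the mean individuals per cluster,
both averaged over event-positive generations. Runs with no event score 0
on all three responses (kept, not dropped, so factorial designs stay
balanced). The DBSCAN implementation is scikit-learn's, wrapped to fix the
classical conventions (min-points counts the point itself; contested
border points go to the first cluster discovered in index order); the test
suite verifies exact agreement with an explicit reachability-graph flood
fill on random instances.

Duration is a run length of the global event indicator, not an identity
tracking of individual clusters through time; no cluster-matching rule
across generations is defined.

## The factorial experiment

The full design crosses 6 dispersal × 6 selection × 3 aggregation levels
(108 cells) with replicate landscapes per H and paired Monte Carlo
replicates (landscape *i* runs with dynamics seed *i*; a fully crossed
landscape × seed layout is available via the design's replication fields).
Replicate summaries are averaged into one row per cell, and each response
is analyzed by a balanced three-way factorial ANOVA — main effects, all
two-way interactions, and the three-way stratum as residual, i.e.
sequential sums of squares, which are unique under balance. On the full
design the degrees of freedom are (2, 5, 5, 10, 10, 25) with residual 50.
The fit goes through statsmodels OLS; tests cross-check the sums of
squares against a direct marginal-means decomposition and calibrate the
null rejection rate by Monte Carlo. A constant response across cells
yields all-zero sums of squares and undefined (NaN) F ratios.

Dynamics seeds derive from (dispersal, H, replicate) but *not* from *s*,
so scenarios differing only in selection strength share home sites,
initial population and burn-in trajectory (common random numbers) —
paired contrasts across *s* then isolate the selection effect.

### Scale profiles

The published scale (5000 individuals, 1024² map, 1250 generations, 10
replicates; ~10⁴ runs for the full design) is available as the `full`
profile but needs cluster-class compute. The `desk` profile keeps the
factor structure and shrinks the run:

| parameter | full | desk |
|---|---|---|
| individuals / home sites | 5000 | 2000 |
| map | 1024², cell 100 | 256², cell ≈253 (density-matched) |
| generations (burn-in) | 1250 (250) | 300 (50) |
| replicates per cell | 10 | 3 |

Desk N is 2000 rather than something smaller because the expected number
of potential mates within reach scales as π·N·D²: at the smallest
interesting dispersal levels (D ≈ 0.05), an N = 500 population averages
~2 reachable males, collapses through mate-finding failure whatever the
selection regime, and cannot express the phenomena of interest; N = 2000
(~8 reachable mates) is the smallest population we found dynamically
viable across the desk conditions. Desk-scale responses are qualitatively,
not quantitatively, comparable to full scale: clusters are smaller and
scarcer in absolute terms, so desk results support ordering statements
(selection strength increases duration/number/size) rather than the
published magnitudes.

## What the synthetic fixtures emulate

`riscape.fixtures` generates (a) planted point patterns — isotropic
Gaussian clusters of AABB/aabb carriers plus uniform background noise,
with ground-truth cluster ids — emulating the simulator's per-generation
genotype point tables so detection and bookkeeping are testable without
simulation; (b) deterministic toy habitat maps (half-split, checkerboard)
with exact 50/50 proportions; (c) miniature run configurations (200
sites, 20 loci, 60 generations) for engine invariants. Planted patterns
have isotropic, stationary clusters and i.i.d. noise; real simulator
output has habitat-shaped, drifting, spatially autocorrelated clusters.
Passing the planted-recovery tests therefore validates the detector's
semantics, not its behavior on every realistic geometry.

## Numerical and degenerate-input choices

* Survival tables are rounded to 12 decimals so decimal selection
  strengths produce the exact decimal survival entries (0.34, not
  0.33999…97) without distorting non-decimal inputs.
* Constant fractal surfaces binarize deterministically by the stable
  rank tie-break; `p` at the extremes (all-ones) is honored exactly.
* A female or offspring whose kernel has an empty feasible set (nothing
  in range / nothing vacant in range) is skipped or dies; this is a
  signaled non-exceptional outcome, distinct from errors such as
  out-of-extent coordinates or non-finite input.
* Population extinction ends a run early and is logged; extinct or
  event-free runs contribute zero responses.
* All randomness flows from numpy `SeedSequence` spawning: one stream for
  home sites, one for dynamics, so a single seed reproduces a run
  bit-for-bit. Fixture generators are pure functions of (spec, seed).

## Validation against theory

The movement kernel is selectable (`kernel="inverse_square"` by default,
`"uniform"` for random mating within range). With the uniform kernel,
dispersal unrestricted, mutation off and all selection disabled, the
engine is an (approximately) exchangeable dioecious population: mean
expected heterozygosity across 50 unlinked neutral loci at N = 200 decays
along H_t = H₀(1 − 1/2N)^t and stays inside the 95% Monte Carlo envelope
of pure binomial Wright–Fisher resampling over 100 generations (the
envelope also brackets the analytic curve). The inverse-square kernel
deliberately fails this: even untruncated, near-neighbor weighting
inflates variance in male reproductive success and accelerates drift
(measured effective size ≈ 0.6 N) — that localization is the
isolation-by-distance mechanism the model is built on, so the panmictic
validation uses the uniform parameterization.

## Known limitations

* No overlapping generations, age structure, sex-biased dispersal, or
  density-dependent fecundity; sex ratio is binomial, not enforced 50:50.
* The movement model is the truncated inverse-square kernel only (no
  cost-distance or resistance surfaces).
* Whether published replicate landscapes and Monte Carlo seeds were fully
  crossed or paired is not recoverable; the default is paired.
* Published F statistics and response magnitudes require the full-scale
  design; this package reproduces the design's *structure* exactly and its
  effects qualitatively at desk scale.
* At desk scale the *s* = 0 / very-weak-selection arms often decline to
  extinction within the run (baseline 50% settlement mortality is a
  knife-edge for recruitment at Poisson mean-4 fecundity); this is the
  model's behavior at that scale, and such runs legitimately score ~0.
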