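# riscape

Individual-based, spatially explicit simulation of **reproductive isolation
evolving inside a continuous population** under a two-locus
Dobzhansky–Muller hybrid incompatibility, heterogeneous habitat selection,
and distance-limited mating and dispersal — plus the machinery to detect
reproductively isolated clusters and analyze them factorially.

It is written for evolutionary and landscape geneticists who want to ask:
when does gene–environment association, acting on loci that are also
involved in hybrid incompatibility, let mutually incompatible genotype
clusters emerge, grow and persist *without* geographic isolation?

## Model in brief

A population of N diploid individuals occupies fixed home sites on a
binary habitat raster. Two selected loci follow the Dobzhansky–Muller
model: alleles *a* and *B* are jointly lethal, so the four classes
{*AaBB*, *AaBb*, *aaBB*, *aaBb*} have fitness 0 and the homozygotes *AABB*
and *aabb* are mutually incompatible (their F1 are all *AaBb*). With
selection strength *s*, settlement survival is

| class | AABB habitat | aabb habitat |
|---|---|---|
| *AABB* | 0.5 + s/2 | 0.5 − s/2 |
| *aabb* | 0.5 − s/2 | 0.5 + s/2 |
| *AABb*, *AAbb*, *Aabb* | 0.5 | 0.5 |
| *AaBB*, *AaBb*, *aaBB*, *aaBb* | 0 | 0 |

Mating partners and offspring settlement sites are drawn from a truncated
inverse-square kernel (p ∝ 1/d² up to a maximum fraction of the landscape
extent). Habitat maps are midpoint-displacement fractal surfaces
rank-binarized to an exact 50/50 split, with aggregation tuned by
H ∈ [0, 1]. Each generation, DBSCAN (ε = 2000 distance units, k = 4) is
run on the *AABB* and *aabb* carriers separately; a generation with at
least one cluster of each is a **reproductive isolation (RI) event**, and
events are summarized by duration (consecutive generations), cluster
number, and cluster size.

See `docs/methods.md` for the full model description, scale profiles, and
design choices.

## Worked example

Run the paired desk-scale contrast between strong heterogeneous selection
(s = 0.64) and the pure isolation-by-distance control (s = 0) at 5%
dispersal on blocky (H = 0.9) landscapes:

```python
from riscape.experiment import build_design, landscape_for, run_scenario

design = build_design("desk")          # N=2000, 256x256 map, 300 generations
landscape = landscape_for(design, H=0.9, rep=0, base_seed=1)
for s in (0.64, 0.0):
    row = run_scenario(design, dispersal=0.05, s=s, H=0.9, rep=0,
                       base_seed=1, landscape=landscape)
    print(s, round(row["duration"], 1), round(row["number"], 2),
          round(row["size"], 1), row["final_pop"])
```

prints

```
0.64 123.5 12.51 119.4 1637
0.0 9.0 8.17 8.6 0
```

i.e. with s = 0.64 the population survives (1637 individuals at
generation 300) and carries RI events averaging ~124 consecutive
generations, with ~13 coexisting AABB/aabb clusters of ~119 individuals;
the neutral control collapses to extinction and its events last ~9
generations with clusters an order of magnitude smaller. Both runs
share the same landscape, home sites and burn-in random numbers, so the
difference is the selection regime. (`analysis/03_selection_contrast.py`
repeats this over 5 replicates and 4 selection levels.)

The numbered scripts under `analysis/` walk the full study: example
landscapes and their aggregation statistics (`01`), the survival tables
(`02`), the selection contrast (`03`), the factorial sweep with resumable
per-cell caching (`04`), and the three-way factorial ANOVA with response
surfaces (`05`).

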