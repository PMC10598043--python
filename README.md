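# nichegrad

Dual-gradient analysis of soil bacterial communities: every OTU in a
count table is classified along **two independent gradients** — a
*habitat-specialization* gradient (generalist / neutral / specialist,
from Levins niche breadth against a permutation null) and an *abundance*
gradient (six relative-abundance categories collapsing to abundant /
medium / rare) — and the resulting subgroups are compared for
α-diversity, niche width, read share and community structure against
vegetation, soil-chemistry and spatial covariates.

The package is aimed at microbial ecologists studying how land use or
afforestation reshapes the rare biosphere versus the dominant taxa, and
habitat specialists versus generalists, from 16S OTU tables with a
modest number of quadrat-style samples.

## The two classifications

**Habitat specialization.** For OTU *i* with occupancy proportions
*P<sub>ij</sub>* over *r* resource states (by default the individual
samples of one soil layer), Levins niche breadth is

> B<sub>i</sub> = 1 / Σ<sub>j</sub> P<sub>ij</sub>²,   1 ≤ B<sub>i</sub> ≤ r.

Each OTU's reads are re-dealt 1000 times across the states by a
multinomial draw proportional to state read totals ("sampling with
replacement"); an OTU whose observed B exceeds the null's 95% quantile
is **habitat-generalized**, one below the 5% quantile is
**habitat-specialized**, and the rest are **habitat-neutral**.  A
fixed-margin whole-matrix null (quasiswap-style, via Patefield sampling)
is available as an alternative.

**Abundance.** With per-sample relative abundances and thresholds 1%
and 0.01%, an OTU is AAT (always > 1%), ART (always < 0.01%), MT (always
in between), CAT (never < 0.01%, sometimes > 1%), CRT (sometimes
< 0.01%, never > 1%) or CRAT (below 0.01% in some samples *and* above 1%
in others).  AAT+CAT form the abundant subgroup, ART+CRT the rare
subgroup, MT+CRAT the medium subgroup.

Downstream, the package computes Shannon–Wiener, unbiased Simpson and
three evenness indices plus richness per sample × subgroup, one-way
ANOVA with Tukey-HSD compact letter displays across stand types,
Bray–Curtis distances, NMDS (Kruskal stress-1), ANOSIM, Mantel tests
(including 3-D spatial distance from lon/lat/elevation) and redundancy
analysis (RDA) with Monte-Carlo model and envfit-style per-variable
tests.

A synthetic-community generator reproduces the study design the
analyses expect — 20 quadrats over four stand types (shrub, coniferous,
mixed, broad-leaved; 3/3/3/11), two soil layers, ~1200 OTUs, realistic
sequencing depths — with *planted* niche archetypes and abundance
classes recorded in a truth table, so the whole battery is testable
without any sequencing data.

## Worked example

```python
from nichegrad import (SimulationParams, simulate_community,
                       to_relative_abundance, classify_abundance,
                       subgroup_summary, classify_niche_table)

sim = simulate_community(SimulationParams(seed=42))
samples = sim.metadata.samples_in_layer("topsoil")
topsoil, _ = sim.table.subset_samples(samples).drop_empty_otus()

abund = classify_abundance(to_relative_abundance(topsoil))
print(subgroup_summary(topsoil, abund).round(4))

niche = classify_niche_table(topsoil, n_perm=1000, seed=42)
print(niche.niche_class.value_counts())

recovered = (niche.assignments.join(sim.truth)
             .query("archetype == 'specialist'")["niche_class"]
             .eq("specialized").mean())
print(f"planted specialists recovered: {recovered:.1%}")
```

prints

```
          n_otus  otu_fraction  read_fraction
subgroup
abundant      35        0.0292        0.5748
medium        85        0.0708        0.3451
rare        1080        0.9000        0.0801
niche_class
specialized    796
neutral        321
generalized     83
planted specialists recovered: 100.0%
```

Read this as the classic rare-biosphere contrast: 2.9% of OTUs are
abundant yet carry 57% of all reads, while the rare subgroup holds 90%
of the species but only 8% of the reads.  On the niche gradient, twenty
samples and a 1000-draw null classify two thirds of OTUs as habitat
specialists — and every OTU the generator *planted* as a specialist is
among them.

There is also a thin CLI:

```sh
nichegrad simulate --seed 42 --out-dir sim/
nichegrad classify-abundance --otu-table sim/otu_table.tsv \
    --metadata sim/metadata.tsv --layer topsoil --out abundance.tsv
nichegrad classify-niche --otu-table sim/otu_table.tsv \
    --metadata sim/metadata.tsv --layer topsoil --n-perm 1000 \
    --seed 42 --out niche.tsv
nichegrad run-all --config config.yaml
```

All outputs are TSV with `#` header comments recording the package
version, seeds and parameters.

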