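# Methods

## Data model and conventions

Community data are non-negative integer read counts, held samples ×
OTUs.  Classic OTU-table files (OTUs × samples) are transposed at the
boundary via an explicit orientation flag; inside the package there is
exactly one orientation.  Relative abundances are within-sample
proportions; every abundance threshold acts on them, so all
classifications are invariant to sequencing depth differences between
samples.  Non-integer tables are rejected by the count reader because
the unbiased Simpson estimator and the multinomial null are defined on
counts; proportion-valued data (plant importance values) go through
separate plug-in entry points.

Distance matrices use `skbio.DistanceMatrix` (symmetry, zero diagonal
and id alignment are enforced by the container).

## Abundance-gradient classification

Thresholds default to 1% (`hi`) and 0.01% (`lo`) of a sample's reads.
With `m`/`n` the maximum/minimum relative abundance of an OTU across the
analyzed sample set: AAT if `n > hi`; ART if `m < lo`; MT if
`lo ≤ n` and `m ≤ hi`; CAT if `n ≥ lo` and `m > hi`; CRT if `n < lo`
and `m ≤ hi`; CRAT if `n < lo` and `m > hi`.  Two conventions are
deliberate and documented because they matter for reproducibility:

* inequalities at the thresholds are *strict* for "above"/"below", so
  threshold-equal values fall to the middle categories (MT/CAT/CRT);
* CRAT is defined as "below `lo` somewhere **and** above `hi`
  somewhere" — the only reading under which the six categories
  partition all OTUs (a literal "ranging from 0.01% to 1%" would
  duplicate MT).

Classification is computed per soil layer, matching the topsoil /
subsoil split of the sampling design.  OTUs absent from every sample of
the layer are excluded with a logged count, not classified.

## Habitat-specialization classification

Levins niche breadth `B = 1/Σ P_j²` is computed from the OTU's raw read
counts over resource states; the default state is the individual sample
(quadrat × layer), with stand-type aggregation available for
sensitivity analysis.  The default null re-deals the OTU's total reads
by a single multinomial draw with probabilities proportional to state
read totals, 1000 times; empirical 5%/95% quantiles use the inclusive
(type-7) definition, and ties with a quantile classify as neutral.  A
naive within-row shuffle is *not* offered as a null: Levins B is
invariant to state order, which would make that null degenerate.  The
alternative `quasiswap` null recomputes B from whole-matrix
randomizations with both margins fixed, sampled exactly with
Patefield's algorithm (`scipy.stats.random_table`) rather than by a
swap chain.

Because the null redistributes *reads proportional to state depths*, an
OTU whose counts are more even than the depth profile (in the limit,
exactly equal counts everywhere) exceeds the null's upper quantile,
while an OTU concentrated relative to the depth profile falls below the
lower quantile.  No rarefaction is applied by default; an optional
rarefy-to-minimum-depth switch exists because unequal depths shift the
null.

## Diversity indices and group comparisons

Shannon–Wiener uses natural logs (`0·ln 0 := 0`).  Simpson diversity is
the unbiased finite-sample form `1 − Σ n_i(n_i−1)/(N(N−1))` on integer
counts; for importance-value vectors the plug-in `1 − Σ P_i²` is used
instead (counts of individuals are not defined there).  The three
evenness indices divide by `log m`; with a uniform natural-log base the
Shannon and Pielou evenness coincide by construction — this is reported
once per run rather than hidden.  A base-10 switch exists for
comparison with sources that mix log bases.

Subgroup α-diversity restricts each sample's counts to the subgroup's
OTUs without renormalization (the indices are scale-free per sample);
subgroups with zero reads in a sample are reported absent.  Group
comparisons across stand types use classical one-way ANOVA with
Tukey-HSD pairwise tests at α = 0.05 summarized as a compact letter
display (insert-and-absorb construction; groups sharing a letter are
not significantly different).  A fully degenerate input (every
observation identical) reports F = 0, p = 1 rather than NaN.

## Community structure battery

* **Bray–Curtis** on relative abundances by default (raw-count switch
  available), via `scipy.spatial.distance`.
* **Spatial distance**: local equirectangular projection about the mean
  latitude (1° lat = 111 320 m, 1° lon scaled by cos lat̄), elevation as
  the third axis, 3-D Euclidean distance.
* **Covariate distances**: Euclidean on z-standardized variables for
  soil chemistry and plant diversity; Bray–Curtis for species
  importance-value vectors, with the empty-vector convention d = 0 for
  two all-zero vectors and d = 1 against a non-zero vector (shrub-only
  stands have no tree layer).  An absent covariate group skips the
  dependent analysis with a warning, never imputes.
* **NMDS**: non-metric SMACOF (scikit-learn) from a PCoA start plus
  random restarts, best solution kept; misfit is reported as Kruskal
  stress-1 computed against the isotonic regression of embedded on
  observed dissimilarities; coordinates are centred and
  Procrustes-rotated onto the PCoA configuration for orientation
  stability.
* **ANOSIM**: Clarke's R on ranked off-diagonal distances with the
  standard divisor n(n−1)/4 (verified identical to vegan/scikit-bio on
  fixtures); null by random relabeling.
* **Mantel**: Pearson (default) or Spearman correlation of distance
  triangles; null by simultaneous row/column permutation of the second
  matrix (which matrix is permuted does not affect the null).
* All permutation p-values use `(1 + #{null ≥ obs})/(1 + n_perm)`,
  which can never return 0 and is exact at the conventional 999
  permutations.

## Redundancy analysis

The community table is Hellinger-transformed by default (square root of
within-sample proportions) — the standard pre-treatment that makes
species data compatible with RDA's Euclidean geometry; a raw/centred
option exists.  Numeric explanatory variables are z-standardized,
factors treatment-coded, aliased (collinear) columns dropped with a
warning via rank-revealing QR.  Constrained axes are the principal
components of the fitted values of the multivariate regression of the
centred response on the centred design; eigenvalue sums decompose the
total variance exactly.  Model significance uses pseudo-F
`(SS_fit/q)/(SS_res/(n−q−1))` under row permutations of the response;
per-variable significance follows the envfit interpretation (variable
regressed on the constrained axes, r² tested by permuting the
variable), not marginal anova-by-term — the two are one switch apart in
intent but envfit is what the workflow names.

## Synthetic communities

The generator emulates the field design: 4 stand types (S/CF/MF/BF)
with 3/3/3/11 quadrats, two soil layers per quadrat, per-sample depths
uniform on 46 595–73 284 reads, 1200 OTUs with a lognormal abundance
spectrum, and counts drawn multinomially per sample (preserving the
compositional coupling the thresholds act on).  Three planted niche
archetypes and three planted abundance classes are recorded in a truth
table:

* **Specialists** (65% of OTUs by default) concentrate mass in a home
  set of stand types: home weight = `habitat_effect` (default 100),
  away weight = 1, normalized so the OTU's expected total mass is
  preserved, i.e. the home/away fold-change equals `habitat_effect`.
  Home stands are drawn with probability proportional to stand quadrat
  counts so that no stand's samples are systematically over-filled with
  boosted specialist mass (uniform choice would overload the small
  stands and distort every planted abundance band after per-sample
  normalization).
* **Neutrals** (30%) have equal expected relative abundance in every
  sample — exactly the expectation of the classification null, so they
  populate the neutral class up to the nominal 10% two-tail error.
* **Generalists** (5%) have equal expected *reads* in every sample,
  i.e. an occupancy profile strictly more even than the
  depth-proportional null.

Abundance classes are expected-RA bands: abundant 1.2–2.2% (3% of
OTUs), medium 0.05–0.9%, rare 0.005–0.0099% (90% of OTUs).  A per-OTU
lognormal draw is rank-mapped into the band; per-sample expected
proportions are then assembled so that the neutral and generalist
guarantees hold exactly after normalization, with specialists absorbing
the per-sample slack (their home/away contrast of 100× dwarfs the
residual rescaling).  Layers share the OTU plan and differ by
independent lognormal jitter (σ = 0.15) and independent counting noise,
so topsoil/subsoil contrasts exist without being confounded with stand
type.

**Design choices fixed by an identifiability analysis (run before any
defaults were frozen):** under the depth-proportional multinomial null
with the realistic depth spread, an even-occupancy generalist is
statistically separable from the null only above roughly 3000 reads per
layer, while a 100-fold specialist stays separable down to ~50 reads.
The defaults therefore place generalists in the upper-medium band
(0.3–0.7% expected RA) and floor the rare band at 0.005%, and the joint
archetype × class allocation is structured rather than independent:
generalists occupy medium-band slots, specialists split between rare
and abundant slots, neutrals fill the remainder.  Two consequences are
worth stating plainly.  First, medium-band specialists are avoided
because a 100-fold away-suppression pushes them below the 0.01%
threshold in away stands, which would silently convert planted medium
OTUs into recovered rare ones.  Second, the generated generalists carry
a much larger read share (~25–30%) than field surveys typically report
for habitat generalists; the generator trades that piece of realism for
recoverable planted ground truth, which is what the test suite scores.

**What the generator does not emulate:** taxonomic or phylogenetic
structure, OTU co-occurrence beyond the shared multinomial constraint,
clustering/chimera artifacts, overdispersion beyond multinomial
(no per-sample lognormal noise on neutrals), and any coupling between
the microbial community and the simulated covariates other than stand
type.  Passing tests therefore demonstrate that the estimators and
classifiers recover a known, cleanly planted signal at realistic sample
sizes and depths — not that field data will show effects of this size.

Covariates: coordinates uniform in a box matching the study region
(117.41–117.57°E, 36.40–36.49°N, 300–760 m), shared by a quadrat's two
layers; soil variables normal around stand-specific means with offsets
scaled by `covariate_effect` (0 gives stand-independent covariates);
tree/shrub importance-value vectors are stand-preferenced Dirichlet
draws, from which vegetation diversity indices are computed with the
plug-in Simpson form.

## Problem sizes and runtime

Default analyses run one soil layer at a time: ≤ ~1400 present OTUs ×
20 samples with a 1000-draw null (a few seconds; the null is drawn in
vectorized per-OTU batches).  Calibration checks use 1000 null
simulations of n = 20 samples with 199 permutations per test — at 199
permutations the 5% level is exactly attainable under the
`(1+exceed)/(1+n_perm)` convention.  Recovery checks run 20 replicate
communities at the full 1000-permutation null.

## Known limitations

* Whether the original field workflow randomized read counts or
  presence/absence frequencies is ambiguous; read counts are used
  because Levins B is defined on abundance proportions.  Both
  interpretations are one switch apart in the null module.
* Per-OTU nulls are computed independently; no multiplicity control is
  applied to the 5%/95% classification quantiles (by design — the
  classes are descriptive strata, not hypothesis tests).
* The BIOM format is not read; TSV is the interchange format.
* The compact letter display uses the standard insert–absorb algorithm,
  which is not guaranteed letter-minimal for pathological overlap
  patterns (the displays are correct, possibly one letter longer than
  optimal).
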