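# Methods

This note documents the statistical model behind `seedtrace`, the choices
made where the design was genuinely open, and what the synthetic validation
does and does not demonstrate about real data.

## The compartment model

A study is a set of integer count tables (ASVs × samples) over five
compartments. Seed samples are location-agnostic: the seed pool comes from a
gene bank and the same pool is sown at every site, so every location is
compared against the same per-species seed community. Seedbed samples are
species-agnostic: they are field soil collected before sowing. Bulk soil,
rhizosphere and endorhiza samples carry the full (species, location, block)
factorial. These two structural rules are enforced by the metadata
validator rather than left as conventions.

Bacterial (16S) and fungal (ITS) datasets are treated as fully independent
runs of the same pipeline; ASV identifiers are never compared across the
two. The only parameter that conventionally differs is the core-prevalence
threshold (0.85 for bacteria, 0.75 for fungi, reflecting the much larger
bacterial ASV inventory).

## Seed-transmission statistic

For species *s*, location *l*, and a root-associated replicate *r*:

1. detection means count ≥ 1 — no abundance floor is applied at ASV level;
2. the candidate set is the intersection of ASVs detected in the seed pool
   of *s* and in *r*;
3. any candidate whose **genus** is detected in **any** seedbed replicate of
   *l* is removed (the union over replicates is the conservative reading);
4. the replicate's proportion is the seed-read mass of the surviving set
   divided by the total seed-read mass of the species' seed pool.

Sharing is assessed at ASV level and exclusion at genus level — mixing the
two resolutions is deliberate: ASV identity is the evidence of transmission,
while the genus-level exclusion acknowledges that a seedbed genus makes the
seed origin of any of its ASVs unconvincing. Using *seed* counts in the
numerator (rather than target counts) makes the statistic a fraction of the
seed community accounted for, hence bounded in [0, 1] and comparable across
compartments with very different absolute loads; the target-count weighting
is available via `numerator="target"` for sensitivity analysis. Per-location
(not global) seedbed exclusion is used because seedbeds are sampled per
field.

The headline summary is the replicate **median**, with one-way ANOVA +
Tukey HSD compact letters across species within each location, and across
locations within each species (α = 0.05). Degenerate designs with zero
within-group variance are handled by exact separation: groups with unequal
means are declared different, all-equal groups share one letter.

Genus-level "species-specific" transmitted taxa are those appearing in the
transmitted sets of exactly one species (per target compartment) in at least
two locations.

## Compositional machinery

Counts are compositions; all between-sample geometry runs on the centred
log-ratio transform with an additive pseudocount (default 0.5, chosen to
match the Dirichlet prior of the effect-size module). Key numerical
contracts, all tested: CLR columns sum to zero (|Σ| < 1e−9), CLR is
invariant to per-sample scaling, full-dimensional PCA scores reproduce
Aitchison distances to 1e−8, and the distance-based PERMANOVA total sum of
squares equals the sum of squared deviations from the grand CLR centroid.

* **PERMANOVA** (one-way): SS_total = (1/N)·Σ_{i<j} d²ᵢⱼ, SS_within summed
  per group with the analogous 1/n_g normalisation, pseudo-F =
  (SS_b/(a−1))/(SS_w/(N−a)), p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) so a
  reported p is never exactly zero. Ties are broken by the ≥ comparison
  (conservative). 999 permutations by default. Multi-factor designs are
  expressed as one factor at a time within strata (metadata subsetting);
  sequential multi-factor partitioning is out of scope, so multi-factor R²
  values from other toolkits are not directly comparable.
* **Dispersion test**: distances to the own-group centroid (computed in CLR
  space, or recovered from squared distances via the Huygens identity when
  only a distance matrix is available — valid because the Aitchison metric
  is Euclidean), then a one-way ANOVA F assessed by permuting group labels
  over the fixed distances. The centroids are *not* re-estimated per
  permutation; this is the classical permutest construction and is very
  slightly liberal (measured null rejection ≈ 5–7 % at α = 0.05).
* **RDA, single variable**: the standardized covariate is regressed onto
  each sample-centred CLR feature; constrained inertia is the sum of squared
  fitted values, F = constrained/(residual/(n−2)), p by permuting the
  covariate rows. For a binary covariate the constrained-inertia fraction
  equals the PERMANOVA R² of the same grouping — an identity used as a
  cross-module test.

## Alpha diversity

Exact rarefaction without replacement (multivariate hypergeometric) to an
even depth; samples below depth are dropped with a logged warning, mirroring
the removal of shallow field samples. The even depth defaults to the minimum
sample total of the compared set. Indices (observed richness, Shannon in
nats, Gini-Simpson 1 − Σp²) are averaged over `n_rarefactions` draws
(default 10, seeded); a single-draw analysis is the `n_rarefactions=1`
special case, since the convention of one vs many rarefactions varies
between studies. Kruskal–Wallis (midrank ties, χ² reference) compares groups;
an all-identical input returns H = 0, p = 1 rather than an error.

## Core filtering and effect sizes

A genus is *core* when its relative abundance exceeds the detection floor
(default 0 — presence) in at least the threshold fraction of samples.
"Prevalence" is the chosen reading of a core threshold (the convention of
the microbiome core-analysis toolkits); abundance-ranking cores are not
implemented.

The effect size for a two-group contrast, per genus: draw `n_mc = 128`
compositions per sample from Dirichlet(counts + 0.5) and CLR-transform each
draw; per instance, btw = median over **all** between-group sample pairs of
the CLR difference (B − A), win = max over the two groups of the median
absolute within-group pairwise difference (floored at 1e−8); the effect is
the median over instances of btw/win. Enumerating all pairs rather than
random pairing removes one stochastic layer and makes the estimate
deterministic given the seed. Positive effect = higher in group B; for the
rhizosphere-vs-bulk contrast B is the rhizosphere, so "enriched in the
rhizosphere" is effect > 1. Core filtering precedes the test, computed on
the contrast's own samples. Measured calibration at n = 6+6, depth 5,000,
40 genera: > 99 % of null genera below |1|; an 8-fold spike recovered with
correct sign in ≥ 90 % of repeats. Effects are invariant to per-sample
depth (CLR removes scale); only the Dirichlet posterior tightens with depth.

Pairwise species contrasts (same construction between two species'
rhizospheres) use the count of |effect| > 1 genera as the dissimilarity
readout; the contrast is symmetrised by sorting samples into a canonical
order before the Monte-Carlo draws, so contrast(A,B) and contrast(B,A) give
identical magnitudes with opposite signs.

## Synthetic generator

The generator is the package's ground-truth instrument, emulating the field
design: 4 species × 3 locations × 3 blocks by default, five compartments,
50,000 reads per sample, one pooled seed sample per species.

* **Seed community**: `n_seed_asvs` (default 50) ASVs with *uniform*
  expected relative abundance, one genus each. Uniformity is a modelling
  choice, not an empirical claim: it makes the expected transmission
  proportion exactly τ · (1 − overlap), giving the closed-form recovery
  target used throughout validation.
* **Overlap**: a fraction `seed_seedbed_genus_overlap` (default 0.2) of seed
  genera also occurs in the soil pool, so the exclusion rule strikes those
  ASVs; the remaining seed ASVs are *eligible*.
* **Soil**: `n_soil_asvs` (default 200) ASVs with log-normal base
  abundances (σ = 1) plus additive per-location Normal(0, 1) shifts on the
  log scale — the simplest mechanism producing clean location separation in
  ordination.
* **Transmission**: each eligible seed ASV enters a given root-compartment
  replicate independently with probability τ[species][compartment], at a
  fixed 0.2 % relative abundance (seed-derived taxa are minor members of
  root communities). Default τ values encode the qualitative field pattern
  the statistic should resolve: endorhiza (0.6) above rhizosphere (0.3),
  with the wild diploid higher (0.8 / 0.5).
* **Enrichment**: per-(species, genus) log2 fold changes applied to the
  rhizosphere relative to bulk (default +2.5 for five genera per species,
  three of them shared within each genetically related couple). The
  endorhiza receives no fold changes — it is modelled as the location soil
  profile plus seed spikes.
* **Counts**: Dirichlet-multinomial at fixed depth; `overdispersion = inf`
  collapses to multinomial, making column totals exactly equal to depth.
  Truth bookkeeping records, per replicate, which eligible ASVs were
  transmitted (entered the expected composition) and which survived
  subsampling (count ≥ 1), so detection loss is measurable.
* An optional **synthetic soil-chemistry table** (NH₄, NO₃, C, N, S, C:N,
  water content; location-specific baselines + unit noise) feeds the RDA
  stage end-to-end. It is a stand-in with no geochemical model behind it.

What the generator does **not** emulate: phylogenetic correlation among
taxa, sequencing error and chimeras, compositional interactions between
compartments beyond the shared soil pool, rank-deficient taxonomy
(everything is classified to genus except where tests construct unclassified
lineages directly), temporal dynamics, and abundance structure of real seed
communities. Passing validation therefore demonstrates correctness of the
*statistical machinery* under a known model — not field-data performance.

## Determinism and problem sizes

Every stochastic step takes an explicit seed; the pipeline derives all stage
seeds from one config seed, and two runs of the same config produce
byte-identical artifacts (sha256-checksummed manifest, output-dir
normalised). Validation uses deliberately small problem sizes — e.g. depth
2,000 and ~65 ASVs for end-to-end determinism, depth 50,000 with 50
replicates for the transmission expectation, 20 simulation repeats for
effect-size calibration — chosen so the full suite runs in well under a
minute while keeping Monte-Carlo standard errors far below the tested
margins.

## Known limitations

* One-way PERMANOVA only; no interaction partitioning.
* The dispersion permutation test is marginally liberal (see above).
* The exhaustive PERMANOVA enumeration used as an oracle supports two
  groups only.
* `species_specific_transmitted` is a set-logic summary; it inherits any
  detection-loss false negatives from the underlying transmitted sets.
* The transmission statistic's seed-count numerator treats the seed pool as
  the reference population; studies wanting colonisation *success* per
  target community should use the target-count variant and interpret it as
  a target-side fraction instead.
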