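# Methods

`soilpool` simulates soil eDNA metabarcoding campaigns end to end —
community → field sampling → wet lab → sequencing → analysis — so that the
consequences of sampling-design and pooling choices can be studied under a
known ground truth. This note documents the models, their assumptions, the
defaults and why they were chosen, and what the simulations can and cannot
say about real surveys.

## Community model (`synthcomm`)

Each species is an independent Thomas cluster process on the square plot:
parent cluster centres are Poisson with intensity `kappa` (per m²), each
parent scatters `Poisson(mu)` propagules with isotropic Gaussian
displacement of sd `sigma` (m). The Thomas process is the standard minimal
model of spatial patchiness: it has two interpretable knobs (how many
patches, how tight) and produces positive spatial autocorrelation of
community composition at scales below `sigma`, which
`commstats.mantel_correlogram` can verify on simulated cores. Points
displaced outside the plot are reflected at the boundary, keeping the
intensity uniform and avoiding edge depletion.

Vertical structure: propagule depth is an exponential distribution with
per-species decay rate (`depth_decay`, per cm) truncated to 0–40 cm —
surface-concentrated communities, uniform in the zero-decay limit. A small
fraction of species (`subsoil_unique_fraction`) are subsoil specialists
with a triangular density on 30–40 cm; they are the only OTUs a subsoil
core can contribute uniquely. The group presets use 0.006, 0.049 and 0.015
for animal-, bacteria- and fungus-like pools, and order total richness
bacteria > fungi > animals.

Per-species heterogeneity comes from distributions over the cluster
parameters: `kappa ~ Gamma`, `mu ~ LogNormal` (the heavy right tail makes
most species locally rare — essential, because every interesting
design/pooling contrast acts on the rare tail), `sigma ~ LogNormal`, and a
log-normal PCR `bias_factor` per species. All parameters are documented in
`GROUP_PRESETS` and overridable per call. Randomness everywhere derives
from `SeedSequence([seed, *keys])` substreams hashed from stable tokens,
so results are independent of iteration order and each stage is
reproducible in isolation.

## Field sampling (`fieldsim`)

`builtin_designs()` encodes the twelve compared protocols (subsample
number N, sampled area, depth intervals, core diameter, and — for the
composite protocols — the pooling tree, e.g. 75 cores as 3 composites of 5
composites of 5). Design areas are concentric squares around the plot
centre (the published layouts nest areas but do not specify shapes or
offsets; a square is the simplest consistent choice). Core positions are
uniform within the design square with a hard-core minimum spacing of twice
the core diameter, by rejection. A core counts the propagules inside its
cylinder; depth intervals are half-open [top, bottom) so stacked intervals
partition counts exactly.

## Wet lab (`labsim`)

The chain mirrors the physical workflow and is where the pooling
mechanisms live:

* **Soil pooling** averages the cores' relative template compositions
  (equal 3-g aliquots idealised to exact equality; log-normal mass jitter
  is available, default off), nested along the composite tree.
* **DNA pooling** first extracts each core separately, then averages the
  extract compositions (equal volumes of equal-concentration extracts;
  concentration jitter available, default off).
* **Extraction** recovers `Poisson(T · p_s)` template molecules per
  species from one fixed-size aliquot (`templates_per_extraction`, default
  T = 6000). This single step produces the dilution effect: a species
  private to one of N pooled cores at within-core proportion q survives
  extraction with probability 1 − exp(−T·q/N), monotone decreasing in N.
* **PCR + sequencing** weights templates by species bias factors times a
  per-PCR log-normal jitter (`bias_sd`), then draws a multinomial read
  vector at a negative-binomial per-sample depth. Each PCR also spawns
  `Poisson(depth/1000 · (artefact_rate + chimera_coeff · ¹D(templates)))`
  brand-new artefact OTUs (¹D = exponential Shannon of the template mix,
  so chimera formation escalates with template diversity), each holding a
  small fixed share (`artefact_read_share`) of the amplicon mass.
  Artefact OTUs are unique to their generating PCR — the worst case for
  unpooled uniqueness counts; a collision option is out of scope.

Cores whose cylinder holds no propagules yield 0-read rows (no DNA, no
library), keeping one row per physical core.

Default rates (T = 6000, artefact_rate = 0.05 per 1000 reads,
chimera_coeff = 1e-4, reads ~ NB(mean 800, shape 0.8) for unpooled
samples) were calibrated once so the qualitative pooling phenomenology —
richness loss for many-subsample pools, gain for few-subsample pools,
more unique artefacts in unpooled processing — emerges from the intended
mechanisms at problem sizes that run in seconds. They are model-scale
quantities, not measurements; nothing here targets the magnitudes of any
real survey.

## Diversity kernels (`divmetrics`)

Good's coverage 1 − f1/n; Hill numbers q = 0 (richness) and q = 1
(exp Shannon, the effective OTU number whose ratios are interpretable);
analytic rarefaction via the hypergeometric closed form
Σ_s [1 − C(n−n_s, d)/C(n, d)] evaluated with log-gamma (stable to ≥1e6
reads); Monte-Carlo rarefaction without replacement (default 1000
iterations) whose oracle is the closed form; bias-corrected Chao1
(f1(f1−1)/(2(f2+1)), defined when f2 = 0; classical form by flag);
exact sample-based accumulation curves and their permutation estimate;
size-based richness extrapolation S_obs + f̂0·[1 − (1 − f1/(n·f̂0+f1))^m]
bounded by Chao1. Coverage-based rarefaction and Hill orders ≥ 2 are out
of scope. Fractional rarefaction depths are floored to integers.

## Design analytics (`design_eval`)

Summaries drop samples under 100 reads, rarefy each remaining sample to
the stratum's minimum depth, and compute site-level totals per iteration
on the union of the rarefied samples (so per-sample and site-level values
share one depth standard). Ratios, rankings (Kendall-τ concordance, ties
broken by site id) and the pooling effect follow.

**Pooling effect.** PE = pooled / unpooled for richness or effective OTU
number. The unpooled reference is the observed site-level value over the
design's unpooled samples at full depth; the pooled sample is rarefied to
`fraction × summary depth` (summary depth = total unpooled reads of that
design), default grid {0.25, 0.5, 0.75, 1.0}. Requests beyond the pooled
read count are flagged, never extrapolated. A both-sides-rarefied variant
was considered and rejected as default because the reference would then
depend on the Monte-Carlo grid; the one-sided definition matches the
sequencing-budget question the statistic answers.
`costcalc.break_even_depth` reports the first grid fraction with PE ≥ 1
plus a linear interpolation.

**Area test.** Subsets of k unpooled cores whose axis-aligned bounding
rectangle is near-square (|width − length| ≤ tolerance) and whose area
falls in the requested range are drawn by rejection, stratified over five
equal area bins for even coverage. Union richness is regressed on area
(OLS with site fixed effects). Because subsets overlap, the permutation
null shuffles the community-to-position assignment within each site and
recomputes every subset's richness — this preserves the overlap structure
and keeps the test at its nominal size (combination-level label shuffling
does not, and inflates rejections).

## Community statistics (`commstats`)

First-principles implementations with small-instance oracles: Bray–Curtis
(NaN for double-zero pairs); one-way PERMANOVA on squared distances with
free, stratified or exhaustive permutations (p = (b+1)/(m+1)); the
dispersion-homogeneity test via principal-coordinate embedding keeping
negative-eigenvalue axes imaginary, distances to group spatial medians
(Weiszfeld; centroids by flag) with imaginary contributions subtracted
under the square root, ANOVA-F and label permutations; Mantel correlogram
with half-open distance classes, two-sided permutation p per class and
Holm correction across classes (a correction choice, made explicit since
conventions differ). Mixed-model marginal contrasts are out of scope;
design-level permutation tests take their place.

## Artefact screening (`screenfx`)

Rare OTUs: relative abundance ≤ 0.05% of the stratum's total reads
(inclusive boundary; stratum defaults to site). Unique OTUs: detected at
a site by exactly one design. Sequence screening flags (i) any gap run
longer than 20 bases, (ii) more than one single-base gap run inside a
200-base window given in reference coordinates, (iii) p-distance strictly
above 2% — on a global affine-gap pairwise alignment against the best
reference (the p-distance proxies the long-branch criterion a tree would
give; "more than one single-nucleotide indel" is read as ≥ 2 runs of
exactly length 1, and rule (i) as a single run > 20, not a sum across
runs). The synthetic fixture generator plants exactly these signatures
(substitutions capped at 1.5% for biological OTUs; deletions of 21–40
bases; paired single-base deletions ≥ 60 bases apart inside the window;
3.5% divergence) so screening sensitivity and specificity are measurable
and equal 1 by construction.

## Costs (`costcalc`)

hours = extractions/10 + PCRs/40; PCRs = extractions × markers (default
3 amplicons per sample); chemical units per extraction and per PCR;
library units per processed sample. Soil pooling reduces extractions to
one per top-level composite; DNA pooling still extracts every core and
saves only PCR and downstream steps. For flat designs the chemical saving
is exactly 100·(N−1)/N — 88.9% for nine subsamples, 80% for five. The
model is deliberately minimal and fully stated; it contains no fixed
overheads, so its absolute person-hour figures are comparable only within
the model.

## Experiment battery and problem sizes (`experiments`)

The canned experiments run scaled-down analogues of the published
geometries: plots of a few metres, 10-cm cores, the same subsample
numbers. The pooling-effect experiment uses a 300-species pool with tight
clusters (σ = 0.15 m) dense enough for ~300–400 propagules per core, and
sequences pools deep enough to rarefy to 100% summary depth; the area
experiment uses a quasi-homogeneous community (dense wide clusters) where
the true area effect is zero; the artefact experiment equalises pooled
and unpooled sequencing depth at an elevated artefact rate so per-PCR
counts are informative. These sizes keep the full battery (20-seed PE
directions, 50-seed area nulls, 20-seed artefact directions, 1000-sim
PERMANOVA null, 50-vector rarefaction oracle) under about a minute.

## What the simulations do and do not show

Passing the battery shows the *mechanisms* behave as modelled: equal-mass
mixing arithmetic, Poisson extraction dilution, depth-unevenness benefits
of pooling under a fixed sequencing budget, per-PCR artefact accumulation,
and the null behaviour of the spatial tests. It does not validate the
magnitudes of any real campaign: real soil communities have environmental
covariate structure, taxon-specific primer chemistry, non-Poisson
extraction efficiency and reference-database effects that the generator
deliberately omits (no niches, no temporal dynamics, no phylogeny, no
per-base error model, no FASTQ layer). Real-data analyses should enter
through `pipeline.read_otu_table` and use the same analytics.

## Numerical conventions

Composition normalisation tolerance 1e-6 on input sums; permutation
p-values (b+1)/(m+1); PCoA eigenvalue cutoff 1e-8; Weiszfeld tolerance
1e-12 with ε = 1e-9 distance floor; alignment scores match 1 / mismatch
−1 / gap open −10 / gap extend −0.5 with Biopython's deterministic
traceback; all stochastic stages consume named RNG substreams and record
their derived seeds in the run manifest.
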