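# Methods

This note documents the statistical procedures, the synthetic-data model and
its calibration, the numerical choices, and what the test suite does and does
not establish about real data.

## Data model

The central object is an integer count matrix (samples × ASVs) joined to
per-sample metadata (subject, site, treatment arm, study day, sex) and
per-ASV annotations (sequence, species, genus). Counts stay integer
end-to-end; relative abundance is the only floating-point representation and
is recomputed from counts wherever needed, never stored alongside them.

The default collection schedule is days (−2, 1, 3, 5, 8, 10, 30, 60), with
day −2 the arrival baseline collected three days before dosing begins on
day 1. Because study designs vary in whether the baseline collection is
labelled "day 0" or "day −2", the schedule is configuration, not a constant.

ASVs lacking a species or genus label collapse into a per-rank
`UNCLASSIFIED_*` bucket rather than being dropped: dropping would break
per-sample count conservation, and every downstream abundance fraction
relies on row totals being preserved under collapse. The default minimum
read depth for retaining a sample is 1,000 reads (configurable); samples
below it are removed with their ids logged, and features are never removed.

## Statistics

**Bray–Curtis** is computed as `1 − 2·Σ min(xᵢ, yᵢ)/(Σxᵢ + Σyᵢ)` on
relative abundances. It is not a metric (the triangle inequality can fail),
which matters for ordination (below).

**permANOVA** uses the distance-based sum-of-squares decomposition with the
pseudo-F statistic and η² = SS_between/SS_total as the effect size. The
p-value uses the add-one estimator `(1 + #{F* ≥ F})/(1 + n_permutations)` so
it can never be exactly zero — the attainable floor with the default 10,000
permutations is ≈ 1.0 × 10⁻⁴. Permutations are free shuffles of the full
label vector (one-way design); stratified or covariate-adjusted permutation
(e.g. by sex) is intentionally out of scope. If SS_within is exactly zero
the pseudo-F is reported as +∞ and the p-value still comes from the
permutation distribution.

**PCoA** double-centers the squared distance matrix (`B = −½ J D² J`) and
eigendecomposes it. Bray–Curtis matrices generally produce negative
eigenvalues; these are excluded from `proportion_explained` and no
Cailliez/Lingoes correction is applied, so proportions are over positive
eigenvalues only (this differs from implementations that normalize by the
trace). Requests for more axes than there are positive eigenvalues return
zero-padded coordinates with a `padded` flag.

**Rank-sum test** uses pooled mid-ranks with the standard tie correction in
the variance and a 0.5 continuity correction, with a two-sided normal
approximation — matching common scientific-Python behaviour rather than
exact enumeration. The test suite checks the approximation against exhaustive
enumeration at small n. When every pooled value is identical, p = 1.

**t tests**: the two-sample form defaults to the classic pooled-variance
Student t (a Welch switch exists but is off by default); the one-sample form
is `t = (x̄ − μ₀)/(s/√n)`. Zero-variance inputs are an error rather than a
silent ±∞.

**Multiple testing** is Bonferroni throughout. In the differential-abundance
screen the family is all taxa tested at the given rank in that screen, not
across ranks.

## Resolution analysis

A taxon is "present" in a group iff it has at least one read pooled across
the group's samples. Non-shared fractions are computed on that presence
relation (symmetric difference over union for taxa; read-weighted for
abundance). The differential screen compares per-sample relative abundances
between groups with the rank-sum test and reports taxa passing both an
adjusted-p cutoff (default 0.05) and a minimum fold change (default 2).
Fold change is the ratio of group mean relative abundances; because taxa can
be entirely absent from one group, zero means are floored at
`1/(2·median sample depth)` before taking the ratio. Computing fold change
on relative abundances rather than raw counts is a deliberate choice: it
removes depth differences between groups from the ratio.

## Transplant tracking

Donor membership is exact sequence identity to an ASV observed in the
sequenced donor inoculum. ASVs are exact sequence variants, and the
scientific question is strain-level displacement, so clustering at a
similarity threshold would blur exactly the signal of interest. An id-based
fallback exists only when *neither* side carries sequences; sequences on one
side only is an error.

A donor ASV counts as "newly introduced" for a (site, treatment) when it
appears in that arm at that site on or after the introduction day (default
day 5, the first collection after the day-4 gavage), never appears in any
control arm (untreated, antibiotics-only) at that site on any day, and never
appears at that site before the introduction day. Absence is evaluated
per site; requiring absence across both sites is a stricter reading and can
be obtained by intersecting the per-site sets.

Cross-site colonization overlap uses the union of the two sites' colonized
donor sets as denominator; a site-centroid variant of the between-site
trajectory is available behind a flag. Engraftment trajectories report, per
subject-day, the fraction of observed ASVs that are donor ASVs and the
summed donor relative abundance, aggregated as mean ± sd (population sd)
per (site, treatment, day).

## ARG categorization

The ASV→genome match table is an input produced upstream by genome-database
search; genome matching is not desk-scale and any such database is
incomplete, so the categorization is deliberately externalized. Categories:
ARG-only (all matching genomes carry ARGs), ambiguous (some do), non-ARG
(none do), unmatched (no genome hits). The four per-sample category
abundance fractions always sum to 1. Species ranking in the ARG trajectory
breaks ties lexicographically for reproducibility.

## Infix edit distance

The anchor filter computes the minimum Levenshtein distance between the
anchor and any contiguous substring of the read: a dynamic program over the
anchor dimension with a free start (first row pinned to zero) and free end
(minimum over final-row values), unit costs, iterated per text character
with a prefix-minimum trick so columns vectorize. Characters outside
{A, C, G, T} mismatch every symbol including themselves — a conservative
treatment of N and ambiguity codes. The anchor sequence and cutoff are
required CLI parameters with no defaults, since they are assay-specific.

## The synthetic-data generator

The generator emulates the study design: two sites, four arms (UNTR, ABX10,
ABX3CMT, CMT), eight collections over 62 calendar days, subjects balanced by
sex, antibiotics dosed on days 1–10 (ABX10) or 1–3 (ABX3CMT), transplant
gavage on day 4, and a single donor inoculum shared by both sites (one
master homogenate), emitted as two deeply sequenced replicate samples.

Latent state is a relative-abundance vector per subject, renormalized after
every intervention:

* **Baselines.** Shared taxa draw one common log-normal abundance
  (μ = 0, σ = 2) and each site multiplies it by an independent log-normal
  jitter (σ = 1.2); site-exclusive taxa draw independently per site. Each
  subject perturbs its site template by Dirichlet resampling with
  concentration 150 × template. These values are calibrated so the two
  baseline communities sit near 0.8 mean between-site Bray–Curtis with
  within-site dissimilarity well below that — strongly differentiated but
  overlapping in membership, the regime the analysis is designed for.
* **Antibiotics** multiply non-resistant taxa by 0.001 and ARG-carrier taxa
  by 0.5 per dosing day and mark the knocked-down taxa as suppressed. With
  multinomial sampling this collapses day-3 richness to roughly the ARG
  remnant (about 10 ASVs against a baseline of 50–90), mirroring the
  near-total alpha-diversity collapse such cocktails produce.
* **Transplant** mixes the donor profile into the recipient's latent profile
  at the engraftment weight (default 0.8) on day 4, then renormalizes.
  Engraftment is single-step: no quantitative engraftment kinetics are
  implied, only the end state.
* **Recolonization.** Each antibiotic-suppressed taxon rebounds
  independently per subject per day with probability 0.01, returning to its
  baseline abundance times a log-normal magnitude (σ = 0.75). Only
  antibiotic-suppressed taxa rebound; taxa diluted by transplant mixing do
  not, which reproduces the observed contrast between stable post-CMT
  profiles and stochastic, site-divergent post-antibiotic recovery.
* **Observation.** Counts are multinomial at Poisson-distributed depth
  (mean 20,000 reads); the donor replicates are sequenced at 5× that depth,
  and the donor template is floored at 2 × 10⁻⁴ relative abundance, so the
  inoculum's membership is fully observed — the ground-truth recovery tests
  require the donor profile to be a faithful reference, not a noisy one.

Taxonomy is constructed so that site-exclusive ASVs pair into species shared
across sites: the sites then differ by *which* strain of a species
dominates, the situation where ASV resolution beats species collapse. A few
donor ASVs are placed into environment species to emulate species containing
both donor and non-donor strains.

All randomness descends from one seed; per-(subject, day) substreams are
derived by BLAKE2 hashing of the identifiers, so outputs are bit-identical
across runs and independent of iteration order. The default scenario used by
the acceptance checks runs 10 subjects per arm and site (640 samples, 220
ASVs) — chosen as a desk-scale size that keeps every per-day group at n = 10
per site, large enough for the permutation tests to resolve p = 10⁻⁴.

**What the generator does not emulate:** ecological interactions
(competition, cross-feeding), sequencing error and chimeras, primer bias,
compositional zero-inflation beyond multinomial sampling, age or sex effects
on composition, and cage effects. Passing tests therefore demonstrate that
the pipeline's computations are correct and well-calibrated under a
plausible compositional model — not that the biological effect sizes in any
particular real study will match.

## Numerical choices and degenerate inputs

* Bray–Curtis on an all-zero vector is an error (undefined), as is
  normalizing a zero-total sample; the depth filter runs first.
* Distance matrices are clipped to [0, 1] after assembly to absorb
  floating-point drift; symmetry holds to 1e-12.
* Collapse at ASV rank is the identity; per-sample totals are conserved at
  every rank by construction.
* The convergence verdict uses strict inequality: a final-day mean of
  exactly 0.5 is not convergent.
* permANOVA p-values are bit-reproducible given a seed.

## Known limitations

* One-way permANOVA only; no interaction or covariate adjustment, no
  PERMDISP companion test for dispersion effects.
* The rank-sum normal approximation is inaccurate below ~n = 5 per group;
  the screen is intended for group sizes of 10+.
* Donor classification requires exact sequence identity; a single
  sequencing-error-induced variant of a donor strain counts as non-donor.
* The generator's antibiotic model is a per-day multiplicative knockdown
  with a binary resistant/sensitive distinction; real susceptibility is
  continuous and drug-specific.
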