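# Methods notes

## Trait space

Traits follow the EltonTraits 1.0 layout: nine diet categories and seven
foraging strata as percent use (each block summing to 100 per species)
plus body mass in grams.  All traits are treated as numeric in the Gower
dissimilarity — percent-use encodings are already interval-scaled, so no
binary/categorical branch is implemented (the `TraitSet` abstraction
leaves a hook for one).  Gower entries are means over usable traits of
|xᵢ − xⱼ| / range, with ranges taken from the supplied table.  Traits
with zero range carry no pairwise information and are excluded from the
average (the convention of the established Gower implementations) with a
warning, rather than entering the denominator as zero-valued terms.

Body mass is range-normalised on its raw scale by default, with a
`log_body_mass` switch; raw grams make the single heaviest species
dominate that trait's axis, which is sometimes wanted (body mass as a
proxy for energy use) and sometimes not — the switch makes the choice
explicit rather than silent.

PCoA retains **all** positive-eigenvalue axes, because FDis is a distance
and truncation would change it.  Gower dissimilarities are frequently
non-Euclidean; the default is no correction with a warning once the
negative eigenvalue mass exceeds 5% of the total (transparency over
silent correction).  `sqrt` and `cailliez` corrections are available;
the Cailliez constant is the largest eigenvalue of the standard 2n × 2n
companion matrix.  Note that `sqrt` is a heuristic: it restores
Euclidean embeddability for mildly non-Euclidean inputs (e.g. squared
distances) but cannot fix strong triangle-inequality violations, which
`cailliez` always can.

The trait space is built once from the full species pool per trait set,
never per site: site FDis values must live in a common space to be
comparable between sites.

Guild tallies collapse the diet categories as invertebrate = {Inv},
plant/seed = {Fruit, Nect, Seed}, vertebrate = {Vend, Vect, Vfish,
Scav}; unidentified vertebrate prey (Vunk) is excluded from the argmax.
A species is an omnivore when no collapsed group reaches 50%
(configurable).  The preferred stratum is the argmax over ground /
understory / mid-high / canopy, excluding water and aerial strata.  Ties
break by fixed category order and are flagged.

## FDis and contributions

FDis uses only species with positive abundance: absent species take no
part in the centroid or the dispersion.  Empty sites propagate as
missing FD (excluded from pairing); single-species sites are 0.

Species contributions are zᵢ = aᵢ · FD(site, year) / N_year with N_year
the total individuals over **all** sites in the year.  Consequently
Σᵢ zᵢ(site) = FD(site) × (site abundance / N_year), i.e. contributions
are a year-level allocation of FD, not a per-site one; the site sum
recovers FD exactly only when a single site holds all of the year's
individuals.  The formula is implemented verbatim and the conservation
identity Σ z = Σ FD × abundance-share is checked to 1e-10 in the tests.
z is invariant to doubling all counts in a year (aᵢ and N_year scale
together and FDis is scale-free).

Rarity compares each species' year total across sites to the mean of
those totals; the boundary (= mean) is common.  Because components are
computed per year but the descriptive tallies span years, a species'
modal class across years is used for summaries (ties → common).

## Price partition

Presence in the partition is z > 0 (equivalently a > 0).  The five
components and the additivity identity are given in the README.  Pairs
are never formed across years or trait sets, since FD and N_year are
year-specific.  The default scheme visits every ordered pair of
non-empty sites (deterministic, exhausts the data); a seeded
`random_pairs` scheme mirrors the random-pair sampling described in the
Price-partition literature.

A structural consequence of exhaustive ordered pairing: the grand means
of the components are exactly antisymmetric (mean RICH_L = −mean RICH_G,
mean COMP_L = −mean COMP_G, mean ABUN = 0), because every pair appears
in both directions.  Non-mirrored summaries such as those reported from
field studies arise from finite random pair samples or directional
baseline conventions.  The informative outputs under exhaustive pairing
are the per-site aggregates and the loss-side magnitudes; both raw means
and means scaled by mean |ΔFD| are emitted, since a "relative
contribution" can reasonably mean either.

The regression response for the driver screen is the mean of each
component per **comparison** site per year: covariates are per-site, and
gains/losses are framed from the comparison site's perspective.  This
mapping is a package decision; pair-level responses with other groupings
are possible via the pairwise CSV.

## Environmental-driver screen

One component, one covariate, per model: a linear mixed model with a
fixed slope and a random intercept per year, fitted by maximum
likelihood so the LRT against the intercept-only null (same random
structure) is valid; p-values come from χ²₁.  Covariates enter
unstandardised, so slopes are per raw covariate unit.  No
multiple-testing correction drives the significance flags (screening
design); a Benjamini–Hochberg column is emitted for reference.

Three random-intercept levels (years) is a known small-group regime.
The response is standardised internally before fitting (the LRT is
invariant; slope, SE and log-likelihoods are mapped back), which avoids
optimizer failures when component values are ~1e-3.  When the year
variance estimate collapses to zero, the model is refitted by OLS and
flagged `ols_fallback` — at a zero variance boundary the ML fits
coincide, so the LRT remains valid.  A constant response short-circuits
to slope 0, χ² 0 (`degenerate`).

Diagnostics for significant fits: a parametric simulation envelope
(default 1000 datasets simulated from the fitted fixed part plus fresh
year intercepts and noise; two-sided rank p for the residual SD) and
mean lag-one residual autocorrelation within years, flagged above 0.15.
The envelope simulates from the fitted model without refitting each
simulation; this matches the spirit of simulation-based residual checks
while staying cheap.

## Synthetic generator

The generator's defaults are the study conditions: 82 sites, 3 years,
61 species.  Species expected abundances λ are log-normal (μ = 0,
σ = 1.2 on the log scale) — a stand-in chosen for its right skew, not an
inference about any real assemblage; a log-series option exists.
Occupancy is Bernoulli per site × species (default p = 0.25, about 15
species per site) with year-level shifts on the logit scale (σ = 0.3),
the source of genuine between-year composition differences.  Occupied
cells draw 1 + Poisson(λ) counts, so **presence carries no information
about abundance**: between-site species losses are random with respect
to z unless deliberately coupled (below).  A single master seed spawns
an independent substream per operation, so generating the environment
never shifts the counts.

`rare_trait_shift` controls the rare-species syndrome as one knob: the
rarest quantile (default 25% by λ) is (a) mixed toward peripheral trait
poles — heavy-bodied vertebrate/fish/carrion diets and water/canopy
strata, corners far from the invertivore mainstream — with weight
1 − exp(−shift), (b) made heavier by exp(0.5 · shift), and (c) made
patchier, with occupancy dropped by 0.75 · shift on the logit scale.
The occupancy coupling is what makes non-random structure visible to
the partition: COMP_L responds to *which species are lost between
sites*, which depends on occupancy, not on trait values directly (z is
abundance × FD).  At shift = 0 traits and occupancy are independent of
abundance rank and mean COMP_L is ~0 over many pairs; at shift > 0
shared species skew common, so COMP_L turns positive.

Planted covariate effects: for a target component, the generator runs
the real pipeline on its own counts, takes the per-site mean component
ȳ_s, and builds the covariate as x = centre + c(ȳ_s − m) + ε with
c = β s_x² / V (V the between-site variance of ȳ_s, s_x the covariate
SD capped at 0.95·√V/|β|), so the component-on-covariate regression
slope is β in expectation, with genuine noise.  Values are clipped into
the covariate's legal range (centres and spreads are chosen so clipping
is rare) and rounded for count-valued covariates.  This is construction,
not estimation — the estimator being validated never enters the
planting.

What the generator does **not** emulate: spatial structure or
autocorrelation among sites, detection error in counts,
phylogenetically correlated traits, temporal trends beyond exchangeable
year effects, and covariate intercorrelations (each covariate draws
independently unless planted).  Passing tests therefore validate the
estimators' algebra and statistical calibration under idealised
sampling, not robustness to those real-data features.

## Validation problem sizes

Chosen to keep the default suite comfortably fast while leaving the
Monte-Carlo contracts well-powered:

- Planted-slope recovery: 200 replicates at the full default size
  (82 × 3 × 61), coverage of the planted slope by ±2 SE asserted ≥ 90%.
- LRT type-I error: 200 replicates at 20 sites × 24 species, 5
  components × 2 covariates; observed rate asserted inside a generous
  binomial band around 0.05 (measured ≈ 0.05–0.07).
- COMP_L interpretation: 100 replicate pairs of runs at 15 × 25,
  one-sided t-statistic > 3 for the rarity-linked signal, and the
  trait-independent mean constrained near zero.
- Generator contracts (skewness, rare-quantile peripherality): 100
  replicates each at reduced sizes, thresholds at 95%.

## Known limitations

- The contribution formula makes site-level z sums depend on the whole
  year's abundance (see above); comparisons of Σz across years with very
  different totals mix FD change with abundance reallocation.
- With three year levels, the mixed model's year variance is weakly
  identified; expect frequent (flagged) OLS fallbacks on data whose
  year effects are weak.  LRT calibration is unaffected.
- Gower + PCoA with `correction="none"` discards negative-eigenvalue
  axes; when the warning reports a large negative mass, FDis values
  underrepresent the non-Euclidean part of trait structure — rerun with
  `cailliez` for sensitivity.
- The dispersion diagnostic is an envelope under the fitted Gaussian
  model, not an omnibus misspecification test.
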