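# fdprice

Partitioning the link between **numerical** and **functional** diversity of
species assemblages.  Built for community ecologists who hold repeated
site × species count matrices (e.g. forest-bird point counts over several
years), a functional trait table, and per-site environmental covariates,
and who want to know *which kind* of species turnover — random losses,
non-random losses, random gains, non-random gains, or abundance shifts of
shared species — drives between-site differences in functional diversity,
and whether the environment (e.g. forest-management intensity) modulates
each kind.

## The method

**Functional dispersion (FDis).**  Species are embedded in a trait space
via a range-normalised Gower dissimilarity on mixed traits (percent diet
use, percent foraging-stratum use, body mass) followed by principal
coordinates analysis.  For an assemblage with abundances *aᵢ* and
coordinates *xᵢ*,

    c    = Σ aᵢ xᵢ / Σ aᵢ
    FDis = Σ aᵢ ‖xᵢ − c‖ / Σ aᵢ

FDis is independent of species richness and of rescaling a site's
abundances.  Three trait sets are used: `diet`, `strata`, and `comb`
(both blocks plus body mass).

**Species contributions.**  The contribution of species *i* at a site in
a year is *zᵢ = aᵢ · FD(site, year) / N_year*, with *N_year* the total
individuals across all sites that year.

**Price partition.**  For an ordered pair of sites (baseline with *s*
species, comparison with *s′*, sharing *s_c*), the difference
ΔFD = Σz′ − Σz decomposes additively into five components:

    RICH_L = (s_c − s)·z̄          random species losses
    COMP_L = s_c·(z̄_c − z̄)        non-random losses
    RICH_G = (s′ − s_c)·z̄′        random species gains
    COMP_G = −s_c·(z̄′_c − z̄′)     non-random gains
    ABUN   = Σ_shared (z′ᵢ − zᵢ)   abundance of shared species

where z̄, z̄′ are site means over present species and z̄_c, z̄′_c the means
over shared species.  The five terms sum to ΔFD exactly, and swapping the
two sites' roles maps losses onto gains with a sign flip.

**Driver screen.**  Each component, aggregated per comparison site and
year, is regressed on one environmental covariate at a time in a linear
mixed model with a random intercept per year (fitted by ML) and compared
against the intercept-only null with a likelihood-ratio test (χ²₁).
Significant fits get simulation-based dispersion and autocorrelation
diagnostics.

A synthetic-assemblage generator emulates the study conditions (82 sites
× 3 years × 61 species, right-skewed abundances, optional rarity-linked
trait divergence, covariates with plantable component effects) so the
whole pipeline can be exercised and validated without any downloads.

## Worked example

```python
import fdprice as fp

# a small simulated assemblage with a planted NDVI effect on random gains
cfg = fp.SimConfig(n_sites=30, n_species=40, seed=7,
                   env_effects={"ndvi": fp.EnvEffect("RICH_G", 0.7)})
traits, counts, env = fp.generate_all(cfg)

spaces = fp.build_trait_spaces(traits)          # Gower + PCoA per trait set
fd = fp.fd_table(counts, spaces)                # FDis per site, year, trait set
print(fd.dropna().groupby("trait_set")["fd"].mean().round(4))

contrib = fp.species_contribution(counts, fd)   # z_i = a_i * FD / N_year
pairs = fp.all_pairs(contrib)                   # five-part Price partition
print(pairs[["rich_l", "comp_l", "rich_g", "comp_g", "abun", "delta_fd"]]
      .iloc[0].round(5))

res = fp.recover_planted_effect(cfg, "ndvi")    # mixed-model driver screen
print(f"slope = {res.slope:.3f} +/- {res.slope_se:.3f}  "
      f"(chi2 = {res.lrt_chi2:.1f}, p = {res.lrt_p:.2g})")
```

prints

```
trait_set
comb      0.1657
diet      0.1714
strata    0.1654
Name: fd, dtype: float64
rich_l     -0.00584
comp_l     -0.00024
rich_g      0.00301
comp_g     -0.00000
abun       -0.00067
delta_fd   -0.00374
Name: 0, dtype: float64
slope = 0.620 +/- 0.085  (chi2 = 41.6, p = 1.1e-10)
```

Mean FDis is similar across the three trait sets, since all three spaces
are built from percent-use blocks with comparable ranges.  The first ordered site
pair loses more contribution through missing species (`rich_l`) than it
regains (`rich_g`); the five components sum to `delta_fd` exactly.  The
mixed-model screen recovers the planted NDVI → random-gains slope (0.7)
well within two standard errors.

There is also a CLI over YAML configs:

```sh
fdprice run --config config.yaml --seed 1 --outdir out/
```

with subcommands `simulate`, `fd`, `price`, `models`, `run`; every
intermediate (trait spaces, FDis table, contributions, pairwise
partition, per-site aggregates, model screen) is written as tidy CSV
next to a run manifest and summary.

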