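"""Synthetic forest-bird assemblage generator.

Emulates the data shapes the pipeline consumes: per-year site x species
maximum-count matrices, an EltonTraits-style functional trait table, and a
per-site environmental covariate table (forest-management intensity and
its components, deadwood, snags, vegetation cover, tree-related
microhabitats, NDVI).  Defaults mirror the study system: 82 one-hectare
sites, 3 years, 61 species, a right-skewed (log-normal) species abundance
distribution thinned to sites by a Bernoulli occupancy process.

``rare_trait_shift`` controls how distinctive the rarest quantile of
species is: their trait profiles are pulled toward heavy-bodied
vertebrate/plant diets and ground/canopy strata, and their site occupancy
drops (rare species become patchily distributed as well as functionally
distinct).  At 0, traits and occupancy are independent of abundance rank,
which makes between-site species losses random with respect to species'
FD contributions.

``env_effects`` plants recoverable linear signals: a covariate is rebuilt
from the per-site aggregated Price component so that regressing the
component on the covariate recovers the requested slope in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .traits import BODY_MASS_COL, DIET_COLS, STRATA_COLS

_STREAMS = {
    "abundance": 11,
    "traits": 12,
    "counts": 13,
    "years": 14,
    "environment": 15,
    "planting": 16,
}

COMPONENT_NAMES = ("RICH_L", "COMP_L", "RICH_G", "COMP_G", "ABUN")

#: covariate name -> (low, high, centre, default between-site SD, integer?)
COVARIATE_RANGES = {
    "formi_harvest": (0.0, 1.0, 0.5, 0.15, False),
    "formi_nonnative": (0.0, 1.0, 0.35, 0.15, False),
    "formi_dwcut": (0.0, 1.0, 0.5, 0.15, False),
    "deadwood_volume": (0.0, np.inf, 22.0, 8.0, False),
    "snags": (0.0, np.inf, 8.0, 3.0, True),
    "veg_cover": (0.0, 100.0, 50.0, 15.0, False),
    "trem_abundance": (0.0, np.inf, 25.0, 8.0, True),
    "trem_richness": (0.0, np.inf, 8.0, 2.5, True),
    "ndvi": (0.0, 1.0, 0.55, 0.12, False),
}


@dataclass(frozen=True)
class EnvEffect:
    """A planted covariate -> Price-component linear signal."""

    component: str
    slope: float
    trait_set: str = "comb"


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic assemblage.

    ``abundance_model`` is ``lognormal`` (params ``mu``, ``sigma`` on the
    log scale of expected individuals per occupied site) or ``log-series``
    (param ``p``).  ``occupancy`` is the per-site presence probability of
    a species before any rarity coupling; ``year_occupancy_sd`` adds a
    year-level shift on the logit-occupancy scale, the source of genuine
    between-year variation in assemblage composition.
    """

    n_sites: int = 82
    n_years: int = 3
    n_species: int = 61
    abundance_model: str = "lognormal"
    abundance_params: dict = field(default_factory=lambda: {"mu": 0.0, "sigma": 1.2})
    occupancy: float = 0.25
    year_occupancy_sd: float = 0.3
    rare_trait_shift: float = 0.0
    rare_quantile: float = 0.25
    env_effects: dict[str, EnvEffect] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sites, self.n_years, self.n_species) < 1:
            raise ValueError("n_sites, n_years and n_species must be positive")
        if self.abundance_model not in ("lognormal", "log-series"):
            raise ValueError(f"unknown abundance model {self.abundance_model!r}")
        if not 0 < self.occupancy < 1:
            raise ValueError("occupancy must be in (0, 1)")
        if self.rare_trait_shift < 0:
            raise ValueError("rare_trait_shift must be >= 0")
        if not 0 < self.rare_quantile < 1:
            raise ValueError("rare_quantile must be in (0, 1)")
        for cov, eff in self.env_effects.items():
            if cov not in COVARIATE_RANGES:
                raise ValueError(f"unknown covariate {cov!r} in env_effects")
            if eff.component not in COMPONENT_NAMES:
                raise ValueError(
                    f"unknown target component {eff.component!r}; "
                    f"expected one of {COMPONENT_NAMES}"
                )

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    # one independent substream per operation: adding one generator call
    # must not shift another operation's draws
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


def species_ids(config: SimConfig) -> list[str]:
    width = len(str(config.n_species))
    return [f"sp{i + 1:0{width}d}" for i in range(config.n_species)]


def site_ids(config: SimConfig) -> list[str]:
    width = len(str(config.n_sites))
    return [f"site{i + 1:0{width}d}" for i in range(config.n_sites)]


def _species_abundance_params(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Expected per-occupied-site abundance and per-site occupancy.

    Drawn from a dedicated substream so that traits, counts and
    environment all see the same species-level rarity structure.
    """
    rng = _rng(config, "abundance")
    if config.abundance_model == "lognormal":
        mu = float(config.abundance_params.get("mu", 0.0))
        sigma = float(config.abundance_params.get("sigma", 1.2))
        lam = rng.lognormal(mu, sigma, size=config.n_species)
    else:  # log-series
        p = float(config.abundance_params.get("p", 0.95))
        lam = stats.logser.rvs(p, size=config.n_species, random_state=rng).astype(float)
    occ = np.full(config.n_species, config.occupancy)
    if config.rare_trait_shift > 0:
        rare = _rare_mask(config, lam)
        occ = np.where(
            rare, expit(logit(occ) - 0.75 * config.rare_trait_shift), occ
        )
    return lam, occ


def _rare_mask(config: SimConfig, lam: np.ndarray) -> np.ndarray:
    cut = np.quantile(lam, config.rare_quantile)
    return lam <= cut


# trait poles the rarest quantile is pulled toward: heavy-bodied species
# taking vertebrate prey and using strata the bulk of the assemblage barely
# touches (waterbirds, raptors) -- corners of trait space far from the
# invertivore ground/canopy mainstream, so shifted species really are
# functionally peripheral
_DIET_POLE = pd.Series(
    {
        "Diet-Inv": 0.0, "Diet-Vend": 50.0, "Diet-Vect": 0.0, "Diet-Vfish": 30.0,
        "Diet-Vunk": 0.0, "Diet-Scav": 20.0, "Diet-Fruit": 0.0, "Diet-Nect": 0.0,
        "Diet-Seed": 0.0,
    }
)[DIET_COLS]
_STRATA_POLE = pd.Series(
    {
        "ForStrat-watbelowsurf": 30.0, "ForStrat-wataroundsurf": 40.0,
        "ForStrat-ground": 0.0, "ForStrat-understory": 0.0,
        "ForStrat-midhigh": 0.0, "ForStrat-canopy": 30.0, "ForStrat-aerial": 0.0,
    }
)[STRATA_COLS]


def generate_traits(config: SimConfig) -> pd.DataFrame:
    """EltonTraits-style table: 9 diet %, 7 strata %, body mass (g).

    Percentage blocks each sum to 100 per species.  Body mass is
    log-normal with median ~25 g, spanning a few grams to near a
    kilogram.  With ``rare_trait_shift > 0`` the rarest-quantile species
    are mixed toward the trait poles and made heavier.
    """
    rng = _rng(config, "traits")
    n = config.n_species

    # diet: a dominant category per species (invertivores most frequent),
    # Dirichlet noise around it
    dom_choices = ["Diet-Inv", "Diet-Seed", "Diet-Fruit", "Diet-Vend", "mixed"]
    dom_probs = [0.45, 0.12, 0.08, 0.10, 0.25]
    diet = np.empty((n, len(DIET_COLS)))
    for i in range(n):
        dom = rng.choice(dom_choices, p=dom_probs)
        alpha = np.full(len(DIET_COLS), 0.35)
        if dom == "mixed":
            alpha[:] = 1.2
        else:
            alpha[DIET_COLS.index(dom)] = 8.0
        diet[i] = rng.dirichlet(alpha)
    diet *= 100.0

    strata_dom = ["ForStrat-ground", "ForStrat-understory", "ForStrat-midhigh",
                  "ForStrat-canopy"]
    strata_probs = [0.40, 0.18, 0.28, 0.14]
    strata = np.empty((n, len(STRATA_COLS)))
    for i in range(n):
        dom = rng.choice(strata_dom, p=strata_probs)
        alpha = np.full(len(STRATA_COLS), 0.25)
        alpha[STRATA_COLS.index("ForStrat-watbelowsurf")] = 0.02
        alpha[STRATA_COLS.index("ForStrat-wataroundsurf")] = 0.02
        alpha[STRATA_COLS.index("ForStrat-aerial")] = 0.1
        alpha[STRATA_COLS.index(dom)] = 6.0
        strata[i] = rng.dirichlet(alpha)
    strata *= 100.0

    mass = rng.lognormal(np.log(25.0), 1.0, size=n)

    if config.rare_trait_shift > 0:
        lam, _ = _species_abundance_params(config)
        rare = _rare_mask(config, lam)
        w = 1.0 - np.exp(-config.rare_trait_shift)
        diet[rare] = (1 - w) * diet[rare] + w * _DIET_POLE.to_numpy()
        strata[rare] = (1 - w) * strata[rare] + w * _STRATA_POLE.to_numpy()
        mass[rare] = mass[rare] * np.exp(0.5 * config.rare_trait_shift)

    # force exact renormalisation of the percentage blocks
    diet = diet / diet.sum(axis=1, keepdims=True) * 100.0
    strata = strata / strata.sum(axis=1, keepdims=True) * 100.0

    out = pd.DataFrame(
        np.hstack([diet, strata, mass[:, None]]),
        index=pd.Index(species_ids(config), name="species"),
        columns=DIET_COLS + STRATA_COLS + [BODY_MASS_COL],
    )
    return out


def generate_counts(
    config: SimConfig, traits: pd.DataFrame | None = None
) -> dict[int, pd.DataFrame]:
    """Per-year site x species maximum-count matrices.

    Presence at a site is a Bernoulli occupancy draw (with year-level
    shifts on the logit scale); occupied cells get a shifted-Poisson count
    1 + Poisson(lambda_k), so presence itself carries no information about
    a species' abundance: between-site species losses are random with
    respect to abundance unless ``rare_trait_shift`` couples occupancy to
    rarity.  Species totals inherit the right skew of the abundance
    distribution.  ``traits`` is accepted for signature symmetry; counts
    depend on species only through the shared abundance-parameter
    substream.
    """
    lam, occ = _species_abundance_params(config)
    rng = _rng(config, "counts")
    year_rng = _rng(config, "years")
    year_shift = year_rng.normal(0.0, config.year_occupancy_sd, size=config.n_years)

    sites = site_ids(config)
    species = species_ids(config)
    out: dict[int, pd.DataFrame] = {}
    for t in range(config.n_years):
        p_t = expit(logit(occ) + year_shift[t])
        present = rng.random((config.n_sites, config.n_species)) < p_t[None, :]
        counts = 1 + rng.poisson(lam[None, :], size=(config.n_sites, config.n_species))
        mat = (present * counts).astype(int)
        out[t + 1] = pd.DataFrame(mat, index=pd.Index(sites, name="site"),
                                  columns=species)
    return out


def _draw_baseline_environment(config: SimConfig) -> pd.DataFrame:
    rng = _rng(config, "environment")
    n = config.n_sites
    env = pd.DataFrame(index=pd.Index(site_ids(config), name="site"))
    env["formi_harvest"] = rng.beta(2.0, 2.0, n)
    env["formi_nonnative"] = rng.beta(1.5, 4.0, n)
    env["formi_dwcut"] = rng.beta(2.0, 2.0, n)
    env["deadwood_volume"] = rng.lognormal(np.log(20.0), 0.6, n)
    env["snags"] = rng.poisson(8.0, n)
    env["veg_cover"] = rng.beta(2.0, 2.0, n) * 100.0
    env["trem_abundance"] = rng.poisson(25.0, n)
    env["trem_richness"] = np.minimum(rng.poisson(8.0, n) + 1, env["trem_abundance"])
    env["ndvi"] = rng.beta(8.0, 2.5, n)
    return env


def _plant_covariate(
    site_mean_component: pd.Series,
    slope: float,
    covariate: str,
    rng: np.random.Generator,
) -> pd.Series:
    """Construct a covariate whose regression slope on the component is
    ``slope`` in expectation.

    With x = c*(ybar_s - m) + eps, the component-on-covariate slope is
    c*V/(c^2*V + var(eps)) where V is the between-site variance of the
    per-site mean component ybar_s; choosing c = slope * s_x^2 / V for a
    covariate SD s_x <= sqrt(V)/|slope| makes it equal the target while
    leaving room for noise.
    """
    low, high, centre, s_x_default, integer = COVARIATE_RANGES[covariate]
    y = site_mean_component.to_numpy(dtype=float)
    V = float(np.var(y, ddof=0))
    if V <= 0:
        raise ValueError(
            f"cannot plant an effect on {covariate}: the target component "
            "has no between-site variation"
        )
    cap = 0.95 * np.sqrt(V) / max(abs(slope), 1e-12)
    s_x = min(s_x_default, cap)
    c = slope * s_x**2 / V
    eps_var = max(s_x**2 - c**2 * V, 0.0)
    x = centre + c * (y - y.mean()) + rng.normal(0.0, np.sqrt(eps_var), len(y))
    x = np.clip(x, low, high)
    if integer:
        x = np.round(x)
    return pd.Series(x, index=site_mean_component.index, name=covariate)


def generate_environment(
    config: SimConfig,
    counts: dict[int, pd.DataFrame] | None = None,
    traits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-site environmental covariate table.

    Without ``env_effects`` all covariates are independent of the counts.
    Each entry of ``env_effects`` rebuilds one covariate from the per-site
    aggregated Price component of the generated assemblage (computed
    through the full pipeline) so that the component-on-covariate slope
    matches the requested value in expectation.  ForMI is the sum of its
    three 0-1 components.
    """
    env = _draw_baseline_environment(config)

    if config.env_effects:
        from .pipeline import site_component_means  # deferred: avoids cycle

        if counts is None:
            counts = generate_counts(config)
        if traits is None:
            traits = generate_traits(config)
        rng = _rng(config, "planting")
        cache: dict[str, pd.DataFrame] = {}
        for cov, eff in config.env_effects.items():
            if eff.trait_set not in cache:
                cache[eff.trait_set] = site_component_means(
                    counts, traits, trait_set=eff.trait_set
                )
            by_site = cache[eff.trait_set]
            col = eff.component.lower()
            ybar = by_site.groupby("site")[col].mean()
            ybar = ybar.reindex(env.index)
            if ybar.isna().any():
                # sites empty in every year carry no component signal;
                # centre them so planting still covers all sites
                ybar = ybar.fillna(ybar.mean())
            env[cov] = _plant_covariate(ybar, eff.slope, cov, rng)

    env["formi"] = (
        env["formi_harvest"] + env["formi_nonnative"] + env["formi_dwcut"]
    )
    cols = ["formi", "formi_harvest", "formi_nonnative", "formi_dwcut",
            "deadwood_volume", "snags", "veg_cover", "trem_abundance",
            "trem_richness", "ndvi"]
    return env[cols]


def generate_all(
    config: SimConfig,
) -> tuple[pd.DataFrame, dict[int, pd.DataFrame], pd.DataFrame]:
    """Traits, counts and environment in one call (shared substreams)."""
    traits = generate_traits(config)
    counts = generate_counts(config, traits)
    env = generate_environment(config, counts, traits)
    return traits, counts, env
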