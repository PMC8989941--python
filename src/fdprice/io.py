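"""Readers, writers and run configuration.

All interchange formats are plain CSV: tidy long counts
(site, year, species, count), an EltonTraits-dialect trait table, and a
site-indexed environment table.  The run configuration is a single YAML
document with either input paths or a ``simulate`` block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from .synthetic import EnvEffect, SimConfig
from .traits import TRAIT_COLS


def read_counts(path: str | Path, *, wide: bool = False) -> dict[int, pd.DataFrame]:
    """Read per-year site x species count matrices.

    Long format (default) expects columns site, year, species, count;
    missing (site, year, species) combinations are zero.  ``wide=True``
    expects site and year columns followed by one column per species.
    Duplicate keys and negative or non-integer counts are errors that name
    the offending rows (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    if wide:
        df = df.melt(id_vars=["site", "year"], var_name="species", value_name="count")
        df = df.dropna(subset=["count"])
    required = {"site", "year", "species", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts file must have columns {sorted(required)}")
    dup = df.duplicated(subset=["site", "year", "species"], keep=False)
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup]]  # +2: header + 1-based
        raise ValueError(f"duplicated (site, year, species) keys at rows {rows}")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts != counts.round())
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad]]
        raise ValueError(f"negative or non-integer counts at rows {rows}")
    df["count"] = counts.astype(int)

    species = sorted(df["species"].astype(str).unique())
    sites = sorted(df["site"].astype(str).unique())
    out: dict[int, pd.DataFrame] = {}
    for year, g in df.groupby("year"):
        mat = (
            g.pivot(index="site", columns="species", values="count")
            .reindex(index=sites, columns=species)
            .fillna(0)
            .astype(int)
        )
        mat.index.name = "site"
        out[year] = mat
    return out


def write_counts(counts: dict[int, pd.DataFrame], path: str | Path) -> None:
    frames = []
    for year, mat in counts.items():
        long = mat.stack().rename("count").reset_index()
        long.columns = ["site", "species", "count"]
        long["year"] = year
        frames.append(long[["site", "year", "species", "count"]])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traits(
    path: str | Path, *, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a trait table; ``column_map`` renames other dialects' columns
    onto the EltonTraits 1.0 names."""
    df = pd.read_csv(path, index_col=0)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in TRAIT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table is missing columns: {missing}")
    df.index = df.index.astype(str)
    df.index.name = "species"
    return df


def read_environment(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "site"
    return df


def check_species_match(
    counts: dict[int, pd.DataFrame], traits: pd.DataFrame
) -> None:
    """Exact-match species identifiers across files; report mismatches
    rather than dropping silently."""
    count_sp = set().union(*(set(m.columns) for m in counts.values()))
    trait_sp = set(traits.index)
    if count_sp != trait_sp:
        raise ValueError(
            "species mismatch between counts and traits: "
            f"counts-only {sorted(count_sp - trait_sp)}, "
            f"traits-only {sorted(trait_sp - count_sp)}"
        )


@dataclass
class RunConfig:
    """Pipeline configuration (YAML-backed).

    Exactly one of the input paths block (``counts``/``traits``[/``environment``])
    or the ``simulate`` block must be present.
    """

    simulate: SimConfig | None = None
    counts_path: str | None = None
    traits_path: str | None = None
    environment_path: str | None = None
    trait_sets: list[str] = field(default_factory=lambda: ["diet", "strata", "comb"])
    pcoa_correction: str = "none"
    log_body_mass: bool = False
    percent_tol: float = 1e-6
    renormalize: bool = True
    pairing_scheme: str = "all_ordered"
    n_pairs: int | None = None
    rarity_level: str = "year_total"
    covariates: list[str] | None = None
    alpha: float = 0.05
    n_dispersion_sims: int = 1000
    output_dir: str = "fdprice_out"
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = self.counts_path is not None or self.traits_path is not None
        if self.simulate is not None and has_paths:
            raise ValueError("config must have either input paths or a simulate block, not both")
        if self.simulate is None:
            if self.counts_path is None or self.traits_path is None:
                raise ValueError("config needs counts and traits paths (or a simulate block)")

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if self.simulate is not None:
            sim = {
                f.name: getattr(self.simulate, f.name) for f in fields(SimConfig)
            }
            sim["env_effects"] = {
                k: {"component": v.component, "slope": v.slope, "trait_set": v.trait_set}
                for k, v in self.simulate.env_effects.items()
            }
            d["simulate"] = sim
        return d


def load_config(path: str | Path, *, seed: int | None = None) -> RunConfig:
    """Parse a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw, seed=seed)


def config_from_dict(raw: dict, *, seed: int | None = None) -> RunConfig:
    raw = dict(raw)
    known = {f.name for f in fields(RunConfig)} | {"inputs"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    inputs = raw.pop("inputs", None)
    if inputs is not None:
        extra = set(inputs) - {"counts", "traits", "environment"}
        if extra:
            raise ValueError(f"unknown input keys: {sorted(extra)}")
        raw["counts_path"] = inputs.get("counts")
        raw["traits_path"] = inputs.get("traits")
        raw["environment_path"] = inputs.get("environment")

    sim = raw.pop("simulate", None)
    if sim is not None:
        sim = dict(sim)
        known_sim = {f.name for f in fields(SimConfig)}
        unknown_sim = set(sim) - known_sim
        if unknown_sim:
            raise ValueError(f"unknown simulate keys: {sorted(unknown_sim)}")
        effects = {
            k: EnvEffect(
                component=v["component"],
                slope=float(v["slope"]),
                trait_set=v.get("trait_set", "comb"),
            )
            for k, v in (sim.pop("env_effects", {}) or {}).items()
        }
        if seed is not None:
            sim["seed"] = seed
        raw["simulate"] = SimConfig(env_effects=effects, **sim)
    if seed is not None:
        raw["seed"] = seed
    return RunConfig(**raw)
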