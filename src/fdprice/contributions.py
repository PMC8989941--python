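"""Per-species contributions to functional diversity, and rarity classes.

The contribution of species i at a site in a year is

    z_i = a_i * FD(site, year) / N_year

where a_i is the species' abundance at that site and N_year the total
number of individuals counted across ALL sites in that year.  Summed over
the species of a site, z recovers FD(site) * (site abundance / N_year) —
the contributions are shares of a site's FD weighted by the site's share of
the year's individuals, not the site FD itself.  z is invariant to scaling
a whole year's counts (a_i and N_year scale together and FDis is
scale-free).

Species are classed rare/common per year against the mean species
abundance: common means abundance >= mean, rare means abundance < mean.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ContributionMatrix:
    """z_i per (year, trait set), as site x species matrices.

    ``z[(year, trait_set)]`` is a DataFrame aligned with the abundance
    matrix of that year; ``n_year[year]`` is the total individual count
    across sites used as the denominator.
    """

    z: dict = field(default_factory=dict)
    n_year: dict = field(default_factory=dict)

    def years(self):
        return sorted({y for (y, _) in self.z})

    def trait_sets(self):
        return sorted({t for (_, t) in self.z})

    def to_long(self) -> pd.DataFrame:
        frames = []
        for (year, ts), mat in self.z.items():
            long = mat.stack().rename("z").reset_index()
            long.columns = ["site", "species", "z"]
            long["year"] = year
            long["trait_set"] = ts
            frames.append(long[["species", "site", "year", "trait_set", "z"]])
        return pd.concat(frames, ignore_index=True)


def species_contribution(
    counts: Mapping[object, pd.DataFrame],
    fd: pd.DataFrame,
) -> ContributionMatrix:
    """Compute z_i = a_i * FD / N_year for every species, site, year, trait set.

    ``fd`` is the long table from :func:`fdprice.dispersion.fd_table`.
    Sites with missing FD (empty sites) get z = 0 everywhere, consistent
    with their all-zero abundance rows.
    """
    out = ContributionMatrix()
    for year, mat in counts.items():
        n_year = float(mat.to_numpy().sum())
        if n_year == 0:
            raise ValueError(f"year {year} has no individuals (N_year = 0)")
        out.n_year[year] = n_year
        fd_y = fd[fd["year"] == year]
        for ts, fd_ts in fd_y.groupby("trait_set"):
            fd_site = fd_ts.set_index("site")["fd"].reindex(mat.index)
            missing = fd_site.index[fd_site.isna() & (mat.sum(axis=1) > 0)]
            if len(missing):
                raise ValueError(
                    f"FD missing for non-empty sites {list(missing)} "
                    f"(year {year}, trait set {ts})"
                )
            z = mat.mul(fd_site.fillna(0.0), axis=0) / n_year
            out.z[(year, ts)] = z.astype(float)
    return out


def classify_rarity(
    counts: Mapping[object, pd.DataFrame],
    *,
    level: str = "year_total",
) -> pd.DataFrame:
    """Rare/common classification per species and year.

    ``level='year_total'`` (default) compares each species' total abundance
    across sites in a year to the mean of those totals; ``level='site_mean'``
    uses the mean per-site abundance instead (same classification, since
    both divide by the same site count — offered for explicitness with
    unequal site sets).  The boundary (abundance exactly equal to the mean)
    is classed common.
    """
    if level not in ("year_total", "site_mean"):
        raise ValueError(f"unknown rarity level {level!r}")
    records = []
    for year, mat in counts.items():
        totals = mat.sum(axis=0).astype(float)
        if level == "site_mean":
            totals = totals / len(mat.index)
        if not (totals > 0).any():
            raise ValueError(f"year {year} has no species with positive abundance")
        mean = totals.mean()
        for sp, ab in totals.items():
            records.append(
                {
                    "species": sp,
                    "year": year,
                    "abundance": ab,
                    "rarity": "common" if ab >= mean else "rare",
                }
            )
    return pd.DataFrame.from_records(records)


def modal_rarity(rarity: pd.DataFrame) -> pd.Series:
    """Modal rare/common class per species across years (ties -> common)."""
    def mode(g: pd.Series) -> str:
        n_common = (g == "common").sum()
        return "common" if n_common >= len(g) - n_common else "rare"

    return rarity.groupby("species")["rarity"].agg(mode)
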