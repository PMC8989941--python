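"""Five-part Price-equation partition of pairwise FD differences.

For an ordered pair of sites — a baseline with s species (those with
z_i > 0) and a comparison with s' species, sharing s_c species — the
difference in total contribution DeltaFD = sum(z') - sum(z) decomposes
additively into five components (Fox & Kerr form):

    RICH_L = (s_c - s)  * zbar        random species losses   (<= 0)
    COMP_L = s_c * (zbar_c  - zbar)   non-random losses
    RICH_G = (s' - s_c) * zbar'       random species gains    (>= 0)
    COMP_G = -s_c * (zbar'_c - zbar') non-random gains
    ABUN   = sum over shared species of (z'_i - z_i)

where zbar / zbar' are site means of z over present species and zbar_c /
zbar'_c the means over the shared species only.  RICH terms carry the
effect of richness change were species exchangeable; COMP terms measure
how far lost (gained) species depart from an average species; ABUN is the
context-dependence effect of shared species changing their contribution.
The five terms sum to DeltaFD exactly; swapping the roles of the two sites
negates DeltaFD and maps losses onto gains.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contributions import ContributionMatrix

COMPONENTS = ("RICH_L", "COMP_L", "RICH_G", "COMP_G", "ABUN")
COMPONENT_COLS = ("rich_l", "comp_l", "rich_g", "comp_g", "abun")


@dataclass
class PriceComponents:
    """The five components of one ordered site comparison."""

    rich_l: float
    comp_l: float
    rich_g: float
    comp_g: float
    abun: float
    delta_fd: float
    s: int
    s_prime: int
    s_c: int

    @property
    def rich_l_comp_l(self) -> float:
        """Cumulative contribution of losses (random + non-random)."""
        return self.rich_l + self.comp_l

    @property
    def rich_g_comp_g(self) -> float:
        """Cumulative contribution of gains (random + non-random)."""
        return self.rich_g + self.comp_g

    @property
    def total(self) -> float:
        return self.rich_l + self.comp_l + self.rich_g + self.comp_g + self.abun


def price_components(
    z_baseline: Mapping[object, float],
    z_comparison: Mapping[object, float],
) -> PriceComponents:
    """Partition DeltaFD between one baseline and one comparison site.

    Presence is defined by z > 0.  Each site must hold at least one
    present species (empty sites are filtered upstream).
    """
    base = {sp: float(v) for sp, v in z_baseline.items() if v > 0}
    comp = {sp: float(v) for sp, v in z_comparison.items() if v > 0}
    if not base or not comp:
        raise ValueError("empty site passed to price_components")
    shared = sorted(set(base) & set(comp), key=str)
    s, s_p, s_c = len(base), len(comp), len(shared)

    zbar = float(np.mean(list(base.values())))
    zbar_p = float(np.mean(list(comp.values())))
    rich_l = (s_c - s) * zbar
    rich_g = (s_p - s_c) * zbar_p
    if s_c:
        zbar_c = float(np.mean([base[sp] for sp in shared]))
        zbar_pc = float(np.mean([comp[sp] for sp in shared]))
        comp_l = s_c * (zbar_c - zbar)
        comp_g = -s_c * (zbar_pc - zbar_p)
        abun = float(sum(comp[sp] - base[sp] for sp in shared))
    else:
        comp_l = comp_g = abun = 0.0
    delta = float(sum(comp.values()) - sum(base.values()))
    return PriceComponents(rich_l, comp_l, rich_g, comp_g, abun, delta, s, s_p, s_c)


def _pairwise_component_matrices(Z: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised five-part partition for every ordered site pair.

    ``Z`` is a site x species matrix of contributions.  Returns n x n
    matrices indexed [baseline, comparison]; entries involving an empty
    site are NaN.  Diagonal entries are the (all-zero) self-comparisons.
    """
    Z = np.asarray(Z, dtype=float)
    P = (Z > 0).astype(float)
    rich = P.sum(axis=1)                      # s per site
    tot = Z.sum(axis=1)                       # sum of z per site
    nonempty = rich > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        zbar = np.where(nonempty, tot / np.where(rich > 0, rich, 1), np.nan)
    SC = P @ P.T                              # shared species counts
    ZP = Z @ P.T                              # [i,j] = sum over shared of z_i
    # shared-species means; terms with s_c = 0 vanish (s_c multiplies them)
    with np.errstate(invalid="ignore", divide="ignore"):
        zbar_c = np.where(SC > 0, ZP / np.where(SC > 0, SC, 1), 0.0)
        zbar_pc = np.where(SC > 0, ZP.T / np.where(SC > 0, SC, 1), 0.0)
    rich_l = (SC - rich[:, None]) * zbar[:, None]
    comp_l = np.where(SC > 0, SC * (zbar_c - zbar[:, None]), 0.0)
    rich_g = (rich[None, :] - SC) * zbar[None, :]
    comp_g = np.where(SC > 0, -SC * (zbar_pc - zbar[None, :]), 0.0)
    abun = ZP.T - ZP                          # sum over shared of (z'_j - z_i)
    delta = tot[None, :] - tot[:, None]
    bad = ~(nonempty[:, None] & nonempty[None, :])
    out = {
        "rich_l": rich_l,
        "comp_l": comp_l,
        "rich_g": rich_g,
        "comp_g": comp_g,
        "abun": abun,
        "delta_fd": delta,
        "s": np.broadcast_to(rich[:, None], SC.shape).copy(),
        "s_prime": np.broadcast_to(rich[None, :], SC.shape).copy(),
        "s_c": SC,
    }
    for k in ("rich_l", "comp_l", "rich_g", "comp_g", "abun", "delta_fd"):
        out[k] = np.where(bad, np.nan, out[k])
    return out


def all_pairs(
    z: ContributionMatrix,
    scheme: str = "all_ordered",
    *,
    n_pairs: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Price components for ordered site pairs, within year and trait set.

    ``scheme='all_ordered'`` visits every ordered pair of non-empty sites
    (baseline != comparison); ``scheme='random_pairs'`` draws ``n_pairs``
    ordered pairs uniformly without replacement using ``seed``.  Pairs are
    never formed across years or trait sets.
    """
    if scheme not in ("all_ordered", "random_pairs"):
        raise ValueError(f"unknown pairing scheme {scheme!r}")
    if scheme == "random_pairs" and n_pairs is None:
        raise ValueError("random_pairs needs n_pairs")
    rng = np.random.default_rng(seed)
    frames = []
    for (year, ts), mat in sorted(z.z.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])):
        Z = mat.to_numpy(dtype=float)
        sites = mat.index.to_numpy()
        nonempty = np.flatnonzero((Z > 0).any(axis=1))
        m = len(nonempty)
        if m < 2:
            raise ValueError(
                f"need at least two non-empty sites in year {year} (found {m})"
            )
        comps = _pairwise_component_matrices(Z[nonempty])
        ii, jj = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
        off = ii != jj
        ii, jj = ii[off], jj[off]
        if scheme == "random_pairs":
            if n_pairs > len(ii):
                raise ValueError(
                    f"n_pairs={n_pairs} exceeds the {len(ii)} ordered pairs "
                    f"available in year {year}"
                )
            pick = rng.choice(len(ii), size=n_pairs, replace=False)
            ii, jj = ii[pick], jj[pick]
        rec = {
            "year": year,
            "trait_set": ts,
            "baseline": sites[nonempty][ii],
            "comparison": sites[nonempty][jj],
        }
        for k in ("s", "s_prime", "s_c"):
            rec[k] = comps[k][ii, jj].astype(int)
        for k in ("rich_l", "comp_l", "rich_g", "comp_g", "abun", "delta_fd"):
            rec[k] = comps[k][ii, jj]
        df = pd.DataFrame(rec)
        df["rich_l_comp_l"] = df["rich_l"] + df["comp_l"]
        df["rich_g_comp_g"] = df["rich_g"] + df["comp_g"]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


AGG_COLS = list(COMPONENT_COLS) + ["delta_fd", "rich_l_comp_l", "rich_g_comp_g"]


def aggregate(pairs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summaries of the pairwise partition records.

    Returns
    -------
    summary : per trait set, mean / sd / median of each component, plus the
        mean scaled by the mean |DeltaFD| (a relative-contribution view).
    by_site : per (year, trait_set, comparison site), mean of each
        component over baselines — the per-site responses used by the
        environmental-driver models (gains and losses read from the
        comparison site's perspective).
    """
    if pairs.empty:
        raise ValueError("no pairwise records to aggregate")
    rows = []
    for ts, g in pairs.groupby("trait_set"):
        mean_abs_delta = g["delta_fd"].abs().mean()
        for col in AGG_COLS:
            rows.append(
                {
                    "trait_set": ts,
                    "component": col,
                    "mean": g[col].mean(),
                    "sd": g[col].std(ddof=1),
                    "median": g[col].median(),
                    "mean_over_mean_abs_delta": (
                        g[col].mean() / mean_abs_delta if mean_abs_delta > 0 else np.nan
                    ),
                    "n_pairs": len(g),
                }
            )
    summary = pd.DataFrame(rows)
    by_site = (
        pairs.groupby(["year", "trait_set", "comparison"])[AGG_COLS]
        .mean()
        .reset_index()
        .rename(columns={"comparison": "site"})
    )
    return summary, by_site
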