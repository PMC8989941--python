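"""Abundance-weighted functional dispersion (FDis).

FDis of an assemblage is the abundance-weighted mean Euclidean distance of
its species to the abundance-weighted centroid in PCoA trait space:

    c = sum_i a_i x_i / sum_i a_i
    FDis = sum_i a_i ||x_i - c|| / sum_i a_i

over the species with positive abundance a_i.  FDis is independent of
species richness and invariant to rescaling a site's abundances by a
positive constant.  The trait space is built once from the full species
pool per trait set, so site values are comparable between sites.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

from .traits import TraitSpace


def fdis(weights: np.ndarray, coords: np.ndarray) -> float:
    """Functional dispersion of one assemblage.

    Parameters
    ----------
    weights : array of non-negative abundances, one per species.
    coords : species x axes coordinate matrix aligned with ``weights``.

    Species with zero weight take no part in either the centroid or the
    dispersion.  A single present species has FDis 0.  All-zero weights are
    an error (an empty assemblage has no dispersion; record it as missing
    upstream).
    """
    w = np.asarray(weights, dtype=float)
    x = np.atleast_2d(np.asarray(coords, dtype=float))
    if x.shape[0] != w.shape[0]:
        raise ValueError(
            f"weights ({w.shape[0]}) and coordinates ({x.shape[0]}) disagree in length"
        )
    if (w < 0).any():
        raise ValueError("abundance weights must be non-negative")
    present = w > 0
    if not present.any():
        raise ValueError("all weights are zero: empty assemblage has no FDis")
    w = w[present]
    x = x[present]
    wsum = w.sum()
    centroid = (w @ x) / wsum
    dist = np.linalg.norm(x - centroid, axis=1)
    return float((w * dist).sum() / wsum)


def _check_alignment(counts: pd.DataFrame, space: TraitSpace, trait_set: str) -> None:
    count_sp = set(counts.columns)
    space_sp = set(space.species)
    if count_sp != space_sp:
        only_counts = sorted(count_sp - space_sp)
        only_space = sorted(space_sp - count_sp)
        raise ValueError(
            f"species mismatch between counts and {trait_set!r} trait space: "
            f"in counts only {only_counts}; in trait space only {only_space}"
        )


def fd_table(
    counts: Mapping[object, pd.DataFrame],
    spaces: Mapping[str, TraitSpace],
) -> pd.DataFrame:
    """FDis per (site, year, trait set), long format.

    Parameters
    ----------
    counts : mapping year -> site x species abundance matrix.
    spaces : mapping trait-set name -> TraitSpace.

    Returns
    -------
    DataFrame with columns site, year, trait_set, fd.  Empty sites get
    ``fd = NaN`` (missing, excluded from pairwise comparisons downstream);
    single-species sites get 0.
    """
    records = []
    for year, mat in counts.items():
        if (mat.to_numpy() < 0).any():
            raise ValueError(f"negative abundances in year {year}")
        for name, space in spaces.items():
            _check_alignment(mat, space, name)
            X = space.coordinates.reindex(mat.columns).to_numpy()
            W = mat.to_numpy(dtype=float)
            for site, w in zip(mat.index, W):
                fd = np.nan if not (w > 0).any() else fdis(w, X)
                records.append(
                    {"site": site, "year": year, "trait_set": name, "fd": fd}
                )
    return pd.DataFrame.from_records(records)
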