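"""Functional trait space for bird assemblages.

Traits follow the EltonTraits 1.0 layout: percent use of nine diet
categories, percent use of seven foraging strata, and body mass in grams.
The trait space used by downstream diversity indices is built from a
range-normalised (numeric) Gower dissimilarity matrix followed by a
principal coordinates analysis (PCoA); species coordinates on the retained
positive-eigenvalue axes act as the synthetic traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIET_COLS = [
    "Diet-Inv",
    "Diet-Vend",
    "Diet-Vect",
    "Diet-Vfish",
    "Diet-Vunk",
    "Diet-Scav",
    "Diet-Fruit",
    "Diet-Nect",
    "Diet-Seed",
]

STRATA_COLS = [
    "ForStrat-watbelowsurf",
    "ForStrat-wataroundsurf",
    "ForStrat-ground",
    "ForStrat-understory",
    "ForStrat-midhigh",
    "ForStrat-canopy",
    "ForStrat-aerial",
]

BODY_MASS_COL = "BodyMass-Value"

TRAIT_COLS = DIET_COLS + STRATA_COLS + [BODY_MASS_COL]

#: Collapsed diet groups used for descriptive guild tallies.  The database
#: splits vertebrate prey into endotherm/ectotherm/fish plus scavenged items;
#: those are pooled, as are the plant-derived food categories.  "Diet-Vunk"
#: (unidentified vertebrate prey) is excluded from the argmax.
DIET_GROUPS = {
    "invertebrate": ["Diet-Inv"],
    "plant/seed": ["Diet-Fruit", "Diet-Nect", "Diet-Seed"],
    "vertebrate": ["Diet-Vend", "Diet-Vect", "Diet-Vfish", "Diet-Scav"],
}
DIET_GROUP_ORDER = ["invertebrate", "plant/seed", "vertebrate"]

#: Strata considered for the preferred-stratum tally; water and aerial
#: foraging are excluded from the argmax (forest assemblage).
STRATUM_GROUPS = {
    "ground": "ForStrat-ground",
    "understory": "ForStrat-understory",
    "mid-high": "ForStrat-midhigh",
    "canopy": "ForStrat-canopy",
}
STRATUM_ORDER = ["ground", "understory", "mid-high", "canopy"]


@dataclass(frozen=True)
class TraitSet:
    """A named selection of trait columns.

    The three standard sets are ``diet`` (nine diet percentages), ``strata``
    (seven foraging-stratum percentages) and ``comb`` (both blocks plus body
    mass).
    """

    name: str
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.columns:
            raise ValueError("TraitSet needs at least one column")

    @classmethod
    def diet(cls) -> "TraitSet":
        return cls("diet", tuple(DIET_COLS))

    @classmethod
    def strata(cls) -> "TraitSet":
        return cls("strata", tuple(STRATA_COLS))

    @classmethod
    def comb(cls) -> "TraitSet":
        return cls("comb", tuple(DIET_COLS + STRATA_COLS + [BODY_MASS_COL]))

    @classmethod
    def named(cls, name: str) -> "TraitSet":
        try:
            return {"diet": cls.diet, "strata": cls.strata, "comb": cls.comb}[name]()
        except KeyError:
            raise ValueError(f"unknown trait set {name!r}; expected diet|strata|comb")


STANDARD_TRAIT_SETS = ("diet", "strata", "comb")


@dataclass
class TraitSpace:
    """PCoA coordinates of species in a Gower trait space.

    Attributes
    ----------
    coordinates : DataFrame
        Species x axes; axes ordered by descending eigenvalue; only axes
        with eigenvalue above tolerance are retained.
    eigenvalues : ndarray
        Full eigenvalue spectrum (descending), including any negative part.
    correction_applied : str
        ``none``, ``sqrt`` or ``cailliez``.
    negative_eigenvalue_mass : float
        Sum of |negative eigenvalues| over the total absolute eigenvalue
        mass; a diagnostic for how non-Euclidean the dissimilarity was.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    correction_applied: str = "none"
    negative_eigenvalue_mass: float = 0.0
    dropped_traits: tuple[str, ...] = field(default_factory=tuple)

    @property
    def species(self) -> pd.Index:
        return self.coordinates.index


def validate_trait_table(
    traits: pd.DataFrame,
    *,
    tol: float = 1e-6,
    renormalize: bool = False,
) -> pd.DataFrame:
    """Check (and optionally renormalize) a trait table.

    Each percentage block must sum to 100 per species within ``tol``; body
    mass must be present and strictly positive.
    """
    missing = [c for c in TRAIT_COLS if c not in traits.columns]
    if missing:
        raise ValueError(f"trait table is missing columns: {missing}")
    out = traits.copy()
    for name, cols in (("diet", DIET_COLS), ("strata", STRATA_COLS)):
        sums = out[cols].sum(axis=1)
        bad = ~np.isclose(sums, 100.0, atol=tol, rtol=0)
        if bad.any():
            if not renormalize:
                raise ValueError(
                    f"{name} percentages do not sum to 100 for species "
                    f"{list(out.index[bad])}"
                )
            if (sums[bad] <= 0).any():
                raise ValueError(
                    f"cannot renormalize all-zero {name} block for species "
                    f"{list(out.index[bad][sums[bad] <= 0])}"
                )
            out.loc[:, cols] = out[cols].div(sums, axis=0) * 100.0
    mass = out[BODY_MASS_COL]
    if mass.isna().any() or (mass <= 0).any():
        bad = out.index[mass.isna() | (mass <= 0)]
        raise ValueError(f"missing or non-positive body mass for species {list(bad)}")
    return out


def gower(
    traits: pd.DataFrame,
    trait_set: TraitSet | str,
    *,
    log_body_mass: bool = False,
) -> pd.DataFrame:
    """Numeric Gower dissimilarity among species on a trait set.

    d(i, j) is the mean over usable traits of |x_i - x_j| / range, with the
    range taken from the supplied table.  Traits with zero range carry no
    information about pairwise differences; they are dropped from the
    average with a warning.  Values lie in [0, 1]; the matrix is symmetric
    with a zero diagonal.  Gower dissimilarity need not satisfy the
    triangle inequality, so no metric property is claimed.

    Parameters
    ----------
    log_body_mass : bool
        Range-normalise log10(body mass) instead of raw grams.
    """
    if isinstance(trait_set, str):
        trait_set = TraitSet.named(trait_set)
    cols = list(trait_set.columns)
    missing = [c for c in cols if c not in traits.columns]
    if missing:
        raise ValueError(f"trait table is missing columns: {missing}")
    if len(traits) < 2:
        raise ValueError("Gower dissimilarity needs at least two species")

    X = traits[cols].to_numpy(dtype=float).copy()
    if log_body_mass and BODY_MASS_COL in cols:
        j = cols.index(BODY_MASS_COL)
        X[:, j] = np.log10(X[:, j])

    rng_ = X.max(axis=0) - X.min(axis=0)
    usable = rng_ > 0
    if not usable.any():
        raise ValueError("all selected traits are constant across species")
    dropped = tuple(c for c, u in zip(cols, usable) if not u)
    if dropped:
        warnings.warn(
            f"zero-range traits excluded from Gower average: {dropped}",
            UserWarning,
            stacklevel=2,
        )
    Xn = X[:, usable] / rng_[usable]
    # mean over usable traits of the range-normalised absolute difference
    D = np.abs(Xn[:, None, :] - Xn[None, :, :]).mean(axis=2)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return pd.DataFrame(D, index=traits.index, columns=traits.index)


def _cailliez_constant(D: np.ndarray) -> float:
    """Smallest additive constant making D + c (off-diagonal) Euclidean."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    delta1 = J @ (-0.5 * D**2) @ J
    delta2 = J @ (-0.5 * D) @ J
    top = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    bottom = np.hstack([-np.eye(n), -4.0 * delta2])
    eigs = np.linalg.eigvals(np.vstack([top, bottom]))
    return float(np.max(eigs.real))


def pcoa(
    d: pd.DataFrame | np.ndarray,
    correction: str = "none",
    *,
    eig_tol: float = 1e-9,
    warn_negative_mass: float = 0.05,
) -> TraitSpace:
    """Principal coordinates analysis of a dissimilarity matrix.

    The matrix is double-centred and eigen-decomposed; all axes with
    eigenvalue above ``eig_tol`` (relative to the largest) are retained, so
    Euclidean distances among coordinates reproduce the input exactly when
    it is Euclidean-embeddable.  Negative eigenvalues signal a
    non-Euclidean input; ``sqrt`` takes the square root of the
    dissimilarities first, ``cailliez`` adds the smallest off-diagonal
    constant that makes the input Euclidean.  With ``correction='none'`` a
    warning is raised when the negative eigenvalue mass exceeds
    ``warn_negative_mass`` of the total.
    """
    if correction not in ("none", "sqrt", "cailliez"):
        raise ValueError(f"unknown correction {correction!r}")
    if isinstance(d, pd.DataFrame):
        labels = d.index
        D = d.to_numpy(dtype=float)
    else:
        D = np.asarray(d, dtype=float)
        labels = pd.RangeIndex(D.shape[0])
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("dissimilarities must be non-negative")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("dissimilarity matrix must have a zero diagonal")

    if correction == "sqrt":
        D = np.sqrt(D)
    elif correction == "cailliez":
        c = _cailliez_constant(D)
        if c > 0:
            D = D + c
            np.fill_diagonal(D, 0.0)

    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    total_abs = np.abs(evals).sum()
    neg_mass = float(np.abs(evals[evals < 0]).sum() / total_abs) if total_abs > 0 else 0.0
    if correction == "none" and neg_mass > warn_negative_mass:
        warnings.warn(
            f"negative eigenvalues carry {neg_mass:.1%} of the absolute "
            "eigenvalue mass; the dissimilarity is markedly non-Euclidean "
            "(consider correction='sqrt' or 'cailliez')",
            UserWarning,
            stacklevel=2,
        )

    scale = max(evals.max(initial=0.0), 0.0)
    keep = evals > eig_tol * max(scale, 1e-300)
    coords = evecs[:, keep] * np.sqrt(evals[keep])
    coordinates = pd.DataFrame(
        coords, index=labels, columns=[f"axis{i + 1}" for i in range(int(keep.sum()))]
    )
    return TraitSpace(
        coordinates=coordinates,
        eigenvalues=evals,
        correction_applied=correction,
        negative_eigenvalue_mass=neg_mass,
    )


def build_trait_spaces(
    traits: pd.DataFrame,
    trait_sets: tuple[str, ...] = STANDARD_TRAIT_SETS,
    *,
    correction: str = "none",
    log_body_mass: bool = False,
) -> dict[str, TraitSpace]:
    """Gower + PCoA for each requested trait set, from the full species pool."""
    spaces: dict[str, TraitSpace] = {}
    for name in trait_sets:
        D = gower(traits, name, log_body_mass=log_body_mass)
        spaces[name] = pcoa(D, correction=correction)
    return spaces


def derive_guilds(
    traits: pd.DataFrame,
    *,
    omnivore_threshold: float = 50.0,
) -> pd.DataFrame:
    """Descriptive guild classification per species.

    ``main_diet`` is the collapsed diet group (invertebrate, plant/seed,
    vertebrate) with the largest summed percentage, or ``omnivore`` when no
    group reaches ``omnivore_threshold`` percent.  ``main_stratum`` is the
    argmax over ground/understory/mid-high/canopy (water and aerial strata
    excluded).  Ties are broken by the fixed category order and flagged.
    """
    records = []
    for sp, row in traits.iterrows():
        sums = {g: float(row[cols].sum()) for g, cols in DIET_GROUPS.items()}
        best = max(sums.values())
        winners = [g for g in DIET_GROUP_ORDER if sums[g] == best]
        if best < omnivore_threshold:
            main_diet, diet_tie = "omnivore", False
        else:
            main_diet, diet_tie = winners[0], len(winners) > 1

        svals = {g: float(row[col]) for g, col in STRATUM_GROUPS.items()}
        sbest = max(svals.values())
        swinners = [g for g in STRATUM_ORDER if svals[g] == sbest]
        records.append(
            {
                "species": sp,
                "main_diet": main_diet,
                "diet_tie": diet_tie,
                "main_stratum": swinners[0],
                "stratum_tie": len(swinners) > 1,
            }
        )
    return pd.DataFrame.from_records(records).set_index("species")
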