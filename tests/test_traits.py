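"""Gower dissimilarity, PCoA and guild classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from fdprice import SimConfig, generate_traits, gower, pcoa
from fdprice.traits import (
    BODY_MASS_COL,
    DIET_COLS,
    STRATA_COLS,
    TraitSet,
    derive_guilds,
    validate_trait_table,
)

from conftest import make_traits


def brute_force_gower(X):
    """Direct per-pair, per-trait evaluation of range-normalised Gower."""
    n, p = X.shape
    rng_ = X.max(axis=0) - X.min(axis=0)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            vals = [abs(X[i, k] - X[j, k]) / rng_[k] for k in range(p) if rng_[k] > 0]
            D[i, j] = np.mean(vals)
    return D


class TestGower:
    def test_matches_elementwise_oracle_on_3x2(self):
        # 3 species x 2 traits with hand-set values
        df = pd.DataFrame(
            {"t1": [0.0, 5.0, 10.0], "t2": [2.0, 2.0, 6.0]},
            index=["a", "b", "c"],
        )
        ts = TraitSet("custom", ("t1", "t2"))
        D = gower(df, ts)
        expected = brute_force_gower(df.to_numpy())
        np.testing.assert_allclose(D.to_numpy(), expected, atol=1e-12)
        # spot value: d(a,b) = (5/10 + 0/4)/2 = 0.25
        assert D.loc["a", "b"] == pytest.approx(0.25)

    def test_identical_rows_have_zero_dissimilarity(self):
        df = pd.DataFrame({"t1": [3.0, 3.0, 9.0], "t2": [1.0, 1.0, 4.0]},
                          index=list("abc"))
        D = gower(df, TraitSet("custom", ("t1", "t2")))
        assert D.loc["a", "b"] == 0.0

    def test_observed_extremes_give_dissimilarity_one(self):
        df = pd.DataFrame({"t1": [0.0, 7.0]}, index=["a", "b"])
        D = gower(df, TraitSet("custom", ("t1",)))
        assert D.loc["a", "b"] == pytest.approx(1.0)

    def test_single_species_and_constant_traits_error(self):
        one = pd.DataFrame({"t1": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="two species"):
            gower(one, TraitSet("custom", ("t1",)))
        const = pd.DataFrame({"t1": [1.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="constant"):
            gower(const, TraitSet("custom", ("t1",)))

    def test_zero_range_trait_excluded_with_warning(self):
        df = pd.DataFrame({"t1": [0.0, 4.0], "t2": [1.0, 1.0]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="zero-range"):
            D = gower(df, TraitSet("custom", ("t1", "t2")))
        assert D.loc["a", "b"] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounds_symmetry_zero_diagonal(self, seed):
        traits = generate_traits(SimConfig(n_species=10, seed=seed))
        D = gower(traits, "comb").to_numpy()
        assert ((D >= -1e-12) & (D <= 1 + 1e-12)).all()
        np.testing.assert_allclose(D, D.T, atol=1e-14)
        np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-14)


class TestPcoa:
    def test_collinear_points_one_axis_distances_reproduced(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        D = squareform(pdist(pts))
        space = pcoa(D)
        assert space.coordinates.shape[1] == 1
        got = squareform(pdist(space.coordinates.to_numpy()))
        np.testing.assert_allclose(got, D, atol=1e-10)

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 3))
        D = squareform(pdist(pts))
        space = pcoa(D)
        got = squareform(pdist(space.coordinates.to_numpy()))
        np.testing.assert_allclose(got, D, atol=1e-8)

    def test_permutation_equivariance(self):
        traits = generate_traits(SimConfig(n_species=12, seed=5))
        D = gower(traits, "diet")
        perm = np.random.default_rng(1).permutation(len(D))
        Dp = D.iloc[perm, perm]
        s1, s2 = pcoa(D), pcoa(Dp)
        np.testing.assert_allclose(s1.eigenvalues, s2.eigenvalues, atol=1e-9)
        d1 = squareform(pdist(s1.coordinates.to_numpy()))
        d2 = squareform(pdist(s2.coordinates.reindex(D.index).to_numpy()))
        np.testing.assert_allclose(d1, d2, atol=1e-8)

    @pytest.mark.parametrize("correction", ["sqrt", "cailliez"])
    def test_corrections_remove_negative_eigenvalues(self, correction):
        # squared distances of collinear points: a classic non-Euclidean
        # dissimilarity (sqrt restores the exact line embedding)
        x = np.array([0.0, 1.0, 2.0, 3.0])
        D = (x[:, None] - x[None, :]) ** 2
        assert pcoa(D).eigenvalues.min() < -1e-6  # genuinely non-Euclidean
        space = pcoa(D, correction=correction)
        assert space.eigenvalues.min() >= -1e-10
        assert space.correction_applied == correction

    def test_cailliez_fixes_strong_triangle_violations(self):
        D = np.array(
            [
                [0.0, 1.0, 0.1, 0.1],
                [1.0, 0.0, 0.1, 0.1],
                [0.1, 0.1, 0.0, 0.1],
                [0.1, 0.1, 0.1, 0.0],
            ]
        )
        space = pcoa(D, correction="cailliez")
        assert space.eigenvalues.min() >= -1e-10

    def test_warns_on_large_negative_mass(self):
        D = np.array(
            [
                [0.0, 1.0, 0.05, 0.05],
                [1.0, 0.0, 0.05, 0.05],
                [0.05, 0.05, 0.0, 0.05],
                [0.05, 0.05, 0.05, 0.0],
            ]
        )
        with pytest.warns(UserWarning, match="non-Euclidean"):
            pcoa(D)

    def test_non_symmetric_rejected(self):
        D = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(D)

    def test_agrees_with_skbio(self):
        """Independent cross-check against scikit-bio's PCoA."""
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        from skbio import DistanceMatrix

        traits = generate_traits(SimConfig(n_species=10, seed=3))
        D = gower(traits, "strata")
        ours = pcoa(D)
        ref = skbio_ord.pcoa(DistanceMatrix(D.to_numpy(), ids=list(D.index)))
        k = ours.coordinates.shape[1]
        np.testing.assert_allclose(
            ours.eigenvalues[:k], ref.eigvals.to_numpy()[:k], atol=1e-8
        )
        d_ours = squareform(pdist(ours.coordinates.to_numpy()))
        ref_coords = ref.samples.to_numpy()[:, : (ref.eigvals.to_numpy() > 1e-9).sum()]
        d_ref = squareform(pdist(ref_coords))
        np.testing.assert_allclose(d_ours, d_ref, atol=1e-6)


class TestGuilds:
    def test_pure_invertivore(self):
        t = make_traits(
            diet=[{"Diet-Inv": 100.0}],
            strata=[{"ForStrat-ground": 100.0}],
            mass=[10.0],
        )
        g = derive_guilds(t)
        assert g["main_diet"].iloc[0] == "invertebrate"
        assert g["main_stratum"].iloc[0] == "ground"

    def test_stratum_argmax_excludes_water_and_aerial(self):
        t = make_traits(
            diet=[{"Diet-Inv": 100.0}],
            strata=[{"ForStrat-aerial": 60.0, "ForStrat-ground": 25.0,
                     "ForStrat-understory": 15.0}],
            mass=[12.0],
        )
        assert derive_guilds(t)["main_stratum"].iloc[0] == "ground"

    def test_omnivore_below_threshold(self):
        t = make_traits(
            diet=[{"Diet-Inv": 40.0, "Diet-Seed": 30.0, "Diet-Vend": 30.0}],
            strata=[{"ForStrat-canopy": 100.0}],
            mass=[20.0],
        )
        assert derive_guilds(t)["main_diet"].iloc[0] == "omnivore"

    def test_tie_takes_first_group_in_fixed_order_and_flags(self):
        # plant/seed and vertebrate tie at 50 each: plant/seed comes first
        t = make_traits(
            diet=[{"Diet-Seed": 50.0, "Diet-Vend": 50.0}],
            strata=[{"ForStrat-ground": 50.0, "ForStrat-canopy": 50.0}],
            mass=[30.0],
        )
        g = derive_guilds(t)
        assert g["main_diet"].iloc[0] == "plant/seed"
        assert bool(g["diet_tie"].iloc[0])
        assert g["main_stratum"].iloc[0] == "ground"
        assert bool(g["stratum_tie"].iloc[0])


class TestValidation:
    def test_renormalizes_near_miss_blocks(self):
        t = make_traits(
            diet=[{"Diet-Inv": 60.0, "Diet-Seed": 41.0}],
            strata=[{"ForStrat-ground": 100.0}],
            mass=[5.0],
        )
        with pytest.raises(ValueError, match="diet"):
            validate_trait_table(t)
        fixed = validate_trait_table(t, renormalize=True)
        assert fixed[DIET_COLS].sum(axis=1).iloc[0] == pytest.approx(100.0)

    def test_rejects_missing_body_mass(self):
        t = make_traits(
            diet=[{"Diet-Inv": 100.0}],
            strata=[{"ForStrat-ground": 100.0}],
            mass=[np.nan],
        )
        with pytest.raises(ValueError, match="body mass"):
            validate_trait_table(t)
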