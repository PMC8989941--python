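"""Five-part Price partition: identities, symmetry, aggregation."""

import numpy as np
import pandas as pd
import pytest

from fdprice import (
    SimConfig,
    aggregate,
    all_pairs,
    build_trait_spaces,
    fd_table,
    generate_counts,
    generate_traits,
    price_components,
    species_contribution,
)


def contributions_for(config):
    traits = generate_traits(config)
    counts = generate_counts(config)
    spaces = build_trait_spaces(traits)
    fd = fd_table(counts, spaces)
    return species_contribution(counts, fd)


@pytest.fixture(scope="module")
def synthetic_contrib():
    return contributions_for(SimConfig(n_sites=10, n_years=2, n_species=12, seed=11))


class TestPriceComponents:
    def test_worked_three_vs_three_pair(self):
        pc = price_components(
            {"A": 0.1, "B": 0.2, "C": 0.3}, {"B": 0.25, "C": 0.35, "D": 0.4}
        )
        assert pc.rich_l == pytest.approx(-0.2)
        assert pc.comp_l == pytest.approx(0.1)
        assert pc.rich_g == pytest.approx(1 / 3)
        assert pc.comp_g == pytest.approx(1 / 15)
        assert pc.abun == pytest.approx(0.1)
        assert pc.delta_fd == pytest.approx(0.4)
        # independent oracle: the components must sum to sum(z') - sum(z)
        assert pc.total == pytest.approx(1.0 - 0.6, abs=1e-12)
        assert pc.rich_l_comp_l == pytest.approx(pc.rich_l + pc.comp_l)
        assert pc.rich_g_comp_g == pytest.approx(pc.rich_g + pc.comp_g)

    def test_identical_sites_all_zero(self):
        z = {"A": 0.2, "B": 0.4}
        pc = price_components(z, z)
        for v in (pc.rich_l, pc.comp_l, pc.rich_g, pc.comp_g, pc.abun, pc.delta_fd):
            assert v == pytest.approx(0.0, abs=1e-15)

    def test_equal_contribution_loss_is_purely_random(self):
        # all z equal: losing a species is exactly the richness effect
        base = {"A": 0.3, "B": 0.3, "C": 0.3}
        comp = {"A": 0.3, "B": 0.3}
        pc = price_components(base, comp)
        assert pc.rich_l == pytest.approx(-0.3)
        assert pc.comp_l == pytest.approx(0.0, abs=1e-15)
        assert pc.rich_g == pytest.approx(0.0, abs=1e-15)
        assert pc.comp_g == pytest.approx(0.0, abs=1e-15)
        assert pc.abun == pytest.approx(0.0, abs=1e-15)

    def test_disjoint_sites(self):
        pc = price_components({"A": 0.2}, {"B": 0.5})
        assert pc.s_c == 0
        assert pc.rich_l == pytest.approx(-0.2)
        assert pc.rich_g == pytest.approx(0.5)
        assert pc.total == pytest.approx(pc.delta_fd, abs=1e-15)

    def test_all_species_shared_reduces_to_abun(self):
        base = {"A": 0.1, "B": 0.2}
        comp = {"A": 0.3, "B": 0.1}
        pc = price_components(base, comp)
        assert pc.rich_l == pytest.approx(0.0, abs=1e-15)
        assert pc.rich_g == pytest.approx(0.0, abs=1e-15)
        # shared mean equals the site mean when every species is shared
        assert pc.comp_l == pytest.approx(0.0, abs=1e-15)
        assert pc.comp_g == pytest.approx(0.0, abs=1e-15)
        assert pc.abun == pytest.approx(pc.delta_fd, abs=1e-15)

    def test_empty_site_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            price_components({}, {"A": 0.1})


class TestAllPairs:
    def test_three_sites_yield_six_ordered_records(self):
        contrib = contributions_for(
            SimConfig(n_sites=3, n_years=2, n_species=8, occupancy=0.9, seed=2)
        )
        pairs = all_pairs(contrib)
        counts = pairs.groupby(["year", "trait_set"]).size()
        assert (counts == 6).all()

    def test_matches_scalar_oracle(self, synthetic_contrib):
        """Vectorised records equal a per-pair loop over price_components."""
        pairs = all_pairs(synthetic_contrib)
        z = synthetic_contrib.z
        rng = np.random.default_rng(0)
        sample = pairs.sample(n=min(len(pairs), 120), random_state=7)
        for _, row in sample.iterrows():
            mat = z[(row["year"], row["trait_set"])]
            pc = price_components(
                mat.loc[row["baseline"]].to_dict(),
                mat.loc[row["comparison"]].to_dict(),
            )
            for col in ("rich_l", "comp_l", "rich_g", "comp_g", "abun", "delta_fd"):
                assert row[col] == pytest.approx(getattr(pc, col), abs=1e-12)
            assert row["s"] == pc.s and row["s_prime"] == pc.s_prime
            assert row["s_c"] == pc.s_c

    def test_additivity_identity_every_pair(self, synthetic_contrib):
        pairs = all_pairs(synthetic_contrib)
        total = pairs[["rich_l", "comp_l", "rich_g", "comp_g", "abun"]].sum(axis=1)
        np.testing.assert_allclose(total, pairs["delta_fd"], atol=1e-10)

    def test_role_swap_antisymmetry(self, synthetic_contrib):
        pairs = all_pairs(synthetic_contrib).set_index(
            ["year", "trait_set", "baseline", "comparison"]
        )
        for (year, ts, a, b), row in pairs.head(200).iterrows():
            rev = pairs.loc[(year, ts, b, a)]
            assert row["delta_fd"] == pytest.approx(-rev["delta_fd"], abs=1e-12)
            assert row["rich_l"] == pytest.approx(-rev["rich_g"], abs=1e-12)
            assert row["comp_l"] == pytest.approx(-rev["comp_g"], abs=1e-12)
            assert row["abun"] == pytest.approx(-rev["abun"], abs=1e-12)

    def test_richness_terms_signed(self, synthetic_contrib):
        pairs = all_pairs(synthetic_contrib)
        assert (pairs["rich_l"] <= 1e-12).all()
        assert (pairs["rich_g"] >= -1e-12).all()
        assert (pairs["s_c"] <= np.minimum(pairs["s"], pairs["s_prime"])).all()

    def test_random_pairs_seeded_and_bounded(self, synthetic_contrib):
        p1 = all_pairs(synthetic_contrib, "random_pairs", n_pairs=10, seed=5)
        p2 = all_pairs(synthetic_contrib, "random_pairs", n_pairs=10, seed=5)
        pd.testing.assert_frame_equal(p1, p2)
        assert (p1.groupby(["year", "trait_set"]).size() == 10).all()
        with pytest.raises(ValueError, match="exceeds"):
            all_pairs(synthetic_contrib, "random_pairs", n_pairs=10_000, seed=5)

    def test_unknown_scheme_rejected(self, synthetic_contrib):
        with pytest.raises(ValueError, match="scheme"):
            all_pairs(synthetic_contrib, "bootstrap")


class TestAggregate:
    def test_single_pair_aggregate_equals_that_pair(self, synthetic_contrib):
        pairs = all_pairs(synthetic_contrib).iloc[:1]
        summary, by_site = aggregate(pairs)
        row = pairs.iloc[0]
        mean_rich_l = summary.query(
            "component == 'rich_l' and trait_set == @row.trait_set"
        )["mean"].iloc[0]
        assert mean_rich_l == pytest.approx(row["rich_l"])
        assert len(by_site) == 1

    def test_duplicated_records_leave_means_unchanged(self, synthetic_contrib):
        pairs = all_pairs(synthetic_contrib)
        s1, _ = aggregate(pairs)
        s2, _ = aggregate(pd.concat([pairs, pairs], ignore_index=True))
        np.testing.assert_allclose(s1["mean"], s2["mean"], atol=1e-12)

    def test_per_site_means_match_naive_groupby(self, synthetic_contrib):
        pairs = all_pairs(synthetic_contrib)
        _, by_site = aggregate(pairs)
        for _, row in by_site.head(20).iterrows():
            sub = pairs[
                (pairs["year"] == row["year"])
                & (pairs["trait_set"] == row["trait_set"])
                & (pairs["comparison"] == row["site"])
            ]
            assert row["rich_g"] == pytest.approx(sub["rich_g"].mean(), abs=1e-12)
            assert row["abun"] == pytest.approx(sub["abun"].mean(), abs=1e-12)
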