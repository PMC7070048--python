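"""Landscape container, distances and intervening opportunities."""

import numpy as np
import pytest

from uniopp import Landscape, intervening_opportunities, pairwise_distances

from conftest import brute_force_sij


def make_landscape(coords, m, **kw):
    coords = np.asarray(coords, dtype=float)
    return Landscape(
        zone_ids=np.array([f"z{k}" for k in range(len(coords))]),
        coords=coords,
        m=np.asarray(m, dtype=float),
        **kw,
    )


class TestLandscapeValidation:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Landscape(
                zone_ids=np.array(["a", "a"]),
                coords=np.zeros((2, 2)),
                m=np.ones(2),
            )

    def test_single_zone_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            Landscape(zone_ids=np.array(["a"]), coords=np.zeros((1, 2)), m=np.ones(1))

    @pytest.mark.parametrize("bad_m", [[-1.0, 1.0], [np.nan, 1.0]])
    def test_bad_opportunities_rejected(self, bad_m):
        with pytest.raises(ValueError, match="m"):
            make_landscape([[0, 0], [1, 0]], bad_m)

    def test_negative_outflow_rejected(self):
        with pytest.raises(ValueError, match="outflow"):
            make_landscape([[0, 0], [1, 0]], [1, 1], outflow=[-5.0, 1.0])

    def test_nonfinite_coords_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            make_landscape([[0, 0], [np.inf, 0]], [1, 1])

    def test_dataframe_round_trip(self, random_landscape):
        land = random_landscape(8, seed=3, with_outflow=True)
        back = Landscape.from_dataframe(land.to_dataframe())
        np.testing.assert_array_equal(back.zone_ids, land.zone_ids)
        np.testing.assert_allclose(back.coords, land.coords)
        np.testing.assert_allclose(back.m, land.m)
        np.testing.assert_allclose(back.outflow, land.outflow)


class TestPairwiseDistances:
    def test_euclidean_pythagorean(self):
        land = make_landscape([[0, 0], [3, 4]], [1, 1])
        d = pairwise_distances(land)
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 0] == 0.0 and d[1, 1] == 0.0
        np.testing.assert_allclose(d, d.T)

    def test_haversine_quarter_great_circle(self):
        # (0, 0) to (0, 90) lon/lat spans a quarter great circle: pi*R/2
        land = make_landscape([[0.0, 0.0], [0.0, 90.0]], [1, 1])
        d = pairwise_distances(land, metric="haversine")
        assert d[0, 1] == pytest.approx(np.pi * 6371.0 / 2, rel=1e-9)

    def test_haversine_latitude_out_of_range(self):
        land = make_landscape([[0.0, 0.0], [0.0, 95.0]], [1, 1])
        with pytest.raises(ValueError, match="lat"):
            pairwise_distances(land, metric="haversine")

    def test_unknown_metric(self, collinear3):
        with pytest.raises(ValueError, match="metric"):
            pairwise_distances(collinear3, metric="manhattan")


class TestInterveningOpportunities:
    def test_collinear_forced_values(self, collinear3):
        d = pairwise_distances(collinear3)
        s = intervening_opportunities(collinear3, d)
        # from zone A (x=0): B is nearest (nothing between), C has B between
        assert s[0, 1] == 0.0
        assert s[0, 2] == 7.0
        assert s[2, 0] == 7.0
        assert np.all(np.diagonal(s) == 0.0)

    def test_equidistant_destinations_strict(self):
        # origin at centre, two destinations mirrored: neither intervenes
        land = make_landscape([[0, 0], [1, 0], [-1, 0]], [3, 5, 7])
        d = pairwise_distances(land)
        s = intervening_opportunities(land, d, tie_policy="strict")
        assert s[0, 1] == 0.0 and s[0, 2] == 0.0

    def test_equidistant_third_zone_half_policy(self):
        # zones 1 and 2 equidistant from 0; zone 3 farther out
        land = make_landscape([[0, 0], [1, 0], [-1, 0], [2, 0]], [3, 5, 7, 11])
        d = pairwise_distances(land)
        strict = intervening_opportunities(land, d, "strict")
        half = intervening_opportunities(land, d, "half")
        # towards zone 3, both 1 and 2 are strictly closer under each policy
        assert strict[0, 3] == 12.0 and half[0, 3] == 12.0
        # towards zone 1, zone 2 ties at distance 1: half its mass counts
        assert strict[0, 1] == 0.0
        assert half[0, 1] == 3.5
        assert half[0, 2] == 2.5

    @pytest.mark.parametrize("tie_policy", ["strict", "half"])
    def test_matches_brute_force(self, random_landscape, tie_policy):
        land = random_landscape(10, seed=42)
        d = pairwise_distances(land)
        s = intervening_opportunities(land, d, tie_policy)
        np.testing.assert_allclose(s, brute_force_sij(land, d, tie_policy))

    def test_shape_mismatch(self, collinear3):
        with pytest.raises(ValueError, match="shape"):
            intervening_opportunities(collinear3, np.zeros((4, 4)))

    def test_never_counts_endpoints(self, random_landscape):
        land = random_landscape(12, seed=7)
        d = pairwise_distances(land)
        s = intervening_opportunities(land, d)
        total = land.m.sum()
        bound = total - land.m[:, None] - land.m[None, :]
        off = ~np.eye(land.n_zones, dtype=bool)
        assert np.all(s[off] >= 0)
        assert np.all(s[off] <= bound[off] + 1e-12)

    def test_monotone_in_distance(self, random_landscape):
        land = random_landscape(15, seed=11)
        d = pairwise_distances(land)
        s = intervening_opportunities(land, d)
        for i in range(land.n_zones):
            order = np.argsort(d[i])
            ranked = s[i, order[1:]]  # drop self
            assert np.all(np.diff(ranked) >= 0)

    def test_permutation_invariance(self, random_landscape):
        land = random_landscape(9, seed=5)
        d = pairwise_distances(land)
        s = intervening_opportunities(land, d)
        perm = np.random.default_rng(1).permutation(land.n_zones)
        shuffled = Landscape(
            zone_ids=land.zone_ids[perm], coords=land.coords[perm], m=land.m[perm]
        )
        s2 = intervening_opportunities(shuffled, pairwise_distances(shuffled))
        np.testing.assert_allclose(s2, s[np.ix_(perm, perm)])

    def test_zero_opportunity_zone_is_transparent(self, random_landscape):
        land = random_landscape(8, seed=13)
        with_ghost = Landscape(
            zone_ids=np.append(land.zone_ids, "ghost"),
            coords=np.vstack([land.coords, [[17.0, 23.0]]]),
            m=np.append(land.m, 0.0),
        )
        s_base = intervening_opportunities(land, pairwise_distances(land))
        s_ghost = intervening_opportunities(
            with_ghost, pairwise_distances(with_ghost)
        )
        np.testing.assert_allclose(s_ghost[:-1, :-1], s_base)
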