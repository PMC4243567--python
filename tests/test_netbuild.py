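import numpy as np
import pytest
from scipy.spatial.distance import cdist

from striatnet.morphology import placement_zone
from striatnet.netbuild import (
    KIND_CORTICAL_GABA,
    KIND_CORTICAL_GLUT,
    KIND_FEEDFORWARD,
    KIND_LATERAL,
    Network,
    PlacementParams,
    TopologyParams,
    build_network,
    n_fsi_for,
    network_summary,
    place_fsis,
    place_msns,
)


class TestPlacement:
    @pytest.mark.parametrize("n,expected", [(14, 2744), (8, 512), (2, 8)])
    def test_lattice_size(self, n, expected):
        pos = place_msns(PlacementParams(n_per_side=n))
        assert len(pos) == expected

    def test_two_per_side_is_cube_corners(self):
        pos = place_msns(PlacementParams(n_per_side=2, spacing=20.0))
        d = cdist(pos, pos)
        nn = np.where(d > 0, d, np.inf).min()
        assert nn == pytest.approx(20.0)
        assert d.max() == pytest.approx(20.0 * np.sqrt(3))

    @pytest.mark.parametrize("n_msn,expected", [(2744, 121), (512, 22), (90, 4)])
    def test_fsi_count_rule(self, n_msn, expected):
        assert n_fsi_for(n_msn) == expected
        pos = place_fsis(n_msn, PlacementParams(), rng_seed=3)
        assert len(pos) == expected

    def test_fsis_inside_lattice_cube(self):
        params = PlacementParams(n_per_side=8, spacing=20.0)
        pos = place_fsis(512, params, rng_seed=5)
        assert pos.min() >= 0.0 and pos.max() <= 140.0

    def test_fsi_placement_reproducible(self):
        a = place_fsis(512, PlacementParams(), rng_seed=5)
        b = place_fsis(512, PlacementParams(), rng_seed=5)
        assert np.array_equal(a, b)


class TestLateralWiring:
    def test_no_self_connections(self, medium_network):
        lat = medium_network.connections.select(KIND_LATERAL)
        assert np.all(lat.source != lat.target)

    def test_distance_cutoff_respected(self, medium_network):
        lat = medium_network.connections.select(KIND_LATERAL)
        pos = medium_network.msn_positions
        d = np.linalg.norm(pos[lat.source] - pos[lat.target], axis=1)
        assert np.all(d <= medium_network.topology.r_lateral)

    def test_out_of_range_pair_never_connects(self):
        # cube corners 260*sqrt(3) ~ 450 um apart exceed the 380 um cutoff
        net = build_network(
            PlacementParams(n_per_side=2, spacing=260.0, seed=0), seed=0,
            feedforward=False,
        )
        lat = net.connections.select(KIND_LATERAL)
        # opposite corners (cells 0 and 7) are out of range, always
        assert not np.any((lat.source == 0) & (lat.target == 7))
        assert not np.any((lat.source == 7) & (lat.target == 0))
        # with all pairs out of range, no connections at all
        far = build_network(
            PlacementParams(n_per_side=2, spacing=400.0, seed=0), seed=0,
            feedforward=False,
        )
        assert len(far.connections.select(KIND_LATERAL)) == 0

    def test_realized_probability_within_binomial_bounds(self, medium_network):
        s = network_summary(medium_network)["lateral"]
        n, p = s["n_in_range_ordered_pairs"], 0.155
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(s["realized_p"] - p) < 3 * sigma

    def test_contact_counts_follow_pmf(self, medium_network):
        lat = medium_network.connections.select(KIND_LATERAL)
        counts = lat.n_contacts()
        assert counts.min() >= 1 and counts.max() <= 3
        frac1 = np.mean(counts == 1)
        sigma = np.sqrt(0.83 * 0.17 / len(counts))
        assert abs(frac1 - 0.83) < 4 * sigma

    def test_contacts_land_in_distal_zone(self, medium_network):
        lat = medium_network.connections.select(KIND_LATERAL)
        zone = set(placement_zone(medium_network.msn_scaffold, "lateral_target").tolist())
        assert set(lat.contact_comp.tolist()) <= zone

    def test_reciprocal_rate_near_p_squared(self, medium_network):
        lat = medium_network.connections.select(KIND_LATERAL)
        pairs = set(zip(lat.source.tolist(), lat.target.tolist()))
        recip = sum((b, a) in pairs for a, b in pairs) / 2
        s = network_summary(medium_network)["lateral"]
        n_inrange = s["n_in_range_ordered_pairs"] / 2  # unordered
        p2 = 0.155**2
        sigma = np.sqrt(p2 * (1 - p2) / n_inrange)
        assert abs(recip / n_inrange - p2) < 4 * sigma


class TestFeedforwardWiring:
    def test_contact_count_range(self, medium_network):
        ff = medium_network.connections.select(KIND_FEEDFORWARD)
        counts = ff.n_contacts()
        assert counts.min() >= 7 and counts.max() <= 12

    def test_mean_contact_count_near_uniform_mean(self):
        # aggregate over several seeds for a stable estimate of E=9.5
        counts = []
        for seed in range(5):
            net = build_network(PlacementParams(n_per_side=5, seed=seed), seed=seed)
            counts.append(net.connections.select(KIND_FEEDFORWARD).n_contacts())
        counts = np.concatenate(counts)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 9.5) < 4 * se

    def test_contacts_land_in_proximal_zone(self, medium_network):
        ff = medium_network.connections.select(KIND_FEEDFORWARD)
        zone = set(placement_zone(medium_network.msn_scaffold, "feedforward_target").tolist())
        assert set(ff.contact_comp.tolist()) <= zone

    def test_distance_cutoff_respected(self, medium_network):
        ff = medium_network.connections.select(KIND_FEEDFORWARD)
        d = np.linalg.norm(
            medium_network.fsi_positions[ff.source]
            - medium_network.msn_positions[ff.target], axis=1)
        assert np.all(d <= medium_network.topology.r_feedforward)


class TestCorticalInputs:
    def test_fsi_receives_84_plus_84(self, small_network):
        n_msn = small_network.n_msn
        for kind in (KIND_CORTICAL_GLUT, KIND_CORTICAL_GABA):
            sub = small_network.connections.select(kind)
            fsi_targets = sub.target[sub.target >= n_msn]
            counts = np.bincount(fsi_targets - n_msn, minlength=small_network.n_fsi)
            assert np.all(counts == 84)

    def test_fsi_glut_gaba_ratio_is_one(self, small_network):
        n_msn = small_network.n_msn
        glut = small_network.connections.select(KIND_CORTICAL_GLUT)
        gaba = small_network.connections.select(KIND_CORTICAL_GABA)
        n_glut = int((glut.target >= n_msn).sum())
        n_gaba = int((gaba.target >= n_msn).sum())
        assert n_glut == n_gaba

    def test_msn_cortical_never_on_soma(self, small_network):
        glut = small_network.connections.select(KIND_CORTICAL_GLUT)
        msn_rows = glut.target < small_network.n_msn
        comps = np.concatenate([
            glut.contact_comp[glut.contact_offsets[i]:glut.contact_offsets[i + 1]]
            for i in np.nonzero(msn_rows)[0]
        ])
        assert 0 not in comps


class TestDeterminismAndSummary:
    def test_same_seed_bit_identical(self):
        a = build_network(PlacementParams(n_per_side=4, seed=3), seed=3, cortical=True)
        b = build_network(PlacementParams(n_per_side=4, seed=3), seed=3, cortical=True)
        assert a.to_json() == b.to_json()

    def test_different_seed_differs(self):
        a = build_network(PlacementParams(n_per_side=4, seed=3), seed=3)
        b = build_network(PlacementParams(n_per_side=4, seed=4), seed=4)
        assert a.to_json() != b.to_json()

    def test_empty_network_summary(self):
        net = build_network(
            PlacementParams(n_per_side=3, seed=0), seed=0,
            lateral=False, feedforward=False,
        )
        s = network_summary(net)
        assert s["lateral"]["n_contacts"] == 0
        assert s["feedforward"]["mean_afferent_cells_per_msn"] == 0.0

    def test_unique_delay_is_2_4_ms(self, medium_network):
        assert network_summary(medium_network)["delays_ms"] == [2.4]

    def test_peripheral_cells_have_fewer_afferents(self):
        # the cube must be wider than the 380 um radius for the boundary
        # (no wrap-around) to bite
        net = build_network(
            PlacementParams(n_per_side=6, spacing=80.0, seed=7), seed=7,
            feedforward=False,
        )
        lat = net.connections.select(KIND_LATERAL)
        contacts = np.bincount(lat.target, weights=lat.n_contacts(),
                               minlength=net.n_msn)
        pos = net.msn_positions
        center = pos.mean(axis=0)
        r = np.linalg.norm(pos - center, axis=1)
        corner = r >= np.percentile(r, 90)
        central = r <= np.percentile(r, 10)
        assert contacts[corner].mean() < contacts[central].mean()

    def test_json_round_trip(self, small_network):
        clone = Network.from_json(small_network.to_json())
        assert clone.to_json() == small_network.to_json()
        assert clone.n_msn == small_network.n_msn

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PlacementParams(n_per_side=1)
        with pytest.raises(ValueError):
            TopologyParams(p_lateral=1.5)
        with pytest.raises(ValueError):
            TopologyParams(lateral_contact_pmf=(0.5, 0.5, 0.5))
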