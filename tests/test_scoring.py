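import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_residue_energy, make_random_system
from cosolvmap.errors import ScoringError
from cosolvmap.geometry import SphereQueryConfig
from cosolvmap.scoring import (
    COULOMB_CONSTANT,
    DepthStats,
    EnergySeries,
    OccupancySeries,
    SoftcoreConfig,
    combine_lj,
    frame_residue_energy,
    s_depth,
    s_interaction,
    s_stability,
    score_all,
    softcore_pair_energy,
)


class TestSoftcorePairEnergy:
    def test_lj_zero_crossing_at_sigma(self):
        # effective distance r + delta equals sigma
        e = softcore_pair_energy(3.0 - 1.0, 0.1, 3.0, 0.0, 0.0)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_lj_minimum_depth_is_minus_epsilon(self):
        sigma, eps = 3.4, 0.15
        r = 2 ** (1 / 6) * sigma - 1.0
        assert softcore_pair_energy(r, eps, sigma, 0.0, 0.0) == pytest.approx(-eps)

    def test_unit_charges_at_unit_distance(self):
        e = softcore_pair_energy(1.0, 0.0, 3.0, 1.0, 1.0)
        assert e == pytest.approx(COULOMB_CONSTANT / 2.0)

    def test_finite_at_contact_with_unit_deltas(self):
        eps, sigma, qi, qj = 0.12, 3.3, 0.1, -0.05
        e = softcore_pair_energy(0.0, eps, sigma, qi, qj)
        expected = 4 * eps * (sigma**12 - sigma**6) + COULOMB_CONSTANT * qi * qj
        assert math.isfinite(e)
        assert e == pytest.approx(expected, rel=1e-12)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ScoringError):
            softcore_pair_energy(0.0, 0.1, 3.0, 0.0, 0.0, SoftcoreConfig(delta_lj=0.0))

    @pytest.mark.parametrize("r", [0.5, 1.0, 2.0, 3.5, 8.0])
    def test_converges_to_plain_potential_as_deltas_vanish(self, r):
        eps, sigma, qi, qj = 0.15, 3.2, 0.2, -0.3
        cfg = SoftcoreConfig(delta_lj=1e-6, delta_elec=1e-6)
        plain = (
            4 * eps * ((sigma / r) ** 12 - (sigma / r) ** 6)
            + COULOMB_CONSTANT * qi * qj / r
        )
        soft = softcore_pair_energy(r, eps, sigma, qi, qj, cfg)
        assert soft == pytest.approx(plain, rel=1e-4)


class TestCombineLJ:
    def test_self_combination_is_identity(self):
        assert combine_lj((0.1, 3.0), (0.1, 3.0)) == pytest.approx((0.1, 3.0))

    def test_zero_epsilon_annihilates(self):
        eps, _ = combine_lj((0.0, 1.0), (0.5, 3.4))
        assert eps == 0.0

    def test_lorentz_berthelot_mixing(self):
        assert combine_lj((0.04, 2.0), (0.09, 4.0)) == pytest.approx((0.06, 3.0))


class TestFrameResidueEnergy:
    def test_no_probes_in_sphere_gives_zero_energy(self):
        rng = np.random.default_rng(1)
        topology, frame, params = make_random_system(rng, n_residues=3, n_probes=0)
        e, m, j = frame_residue_energy(0, frame, topology, params)
        assert (e, m) == (0.0, 0)
        _, _, bj = brute_residue_energy(0, frame, topology, params)
        assert j == bj

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            topology, frame, params = make_random_system(rng)
            for rid in range(3):
                e, m, j = frame_residue_energy(rid, frame, topology, params)
                be, bm, bj = brute_residue_energy(rid, frame, topology, params)
                assert (m, j) == (bm, bj)
                assert e == pytest.approx(be, abs=1e-10)

    def test_unknown_residue_id_rejected(self):
        rng = np.random.default_rng(3)
        topology, frame, params = make_random_system(rng, n_residues=2)
        with pytest.raises(ScoringError):
            frame_residue_energy(5, frame, topology, params)


class TestScoreComponents:
    def test_interaction_normalizes_by_mean_occupancy(self):
        occ = OccupancySeries(0, np.full(10, 2))
        eng = EnergySeries(0, np.full(10, -10.0))
        assert s_interaction(eng, occ) == pytest.approx(-5.0)

    def test_interaction_zero_when_never_occupied(self):
        occ = OccupancySeries(0, np.zeros(10, dtype=int))
        eng = EnergySeries(0, np.zeros(10))
        assert s_interaction(eng, occ) == 0.0

    def test_interaction_requires_frames(self):
        with pytest.raises(ScoringError):
            s_interaction(EnergySeries(0, np.array([])), OccupancySeries(0, np.array([])))

    @pytest.mark.parametrize(
        "counts, expected",
        [
            (np.full(20, 1), 1.0),  # perfectly retained single molecule
            (np.full(20, 4), 0.25),  # zero variance but higher occupancy
            (np.array([0, 2] * 10), 0.0),  # mean 1, std 1: divergent denominator
        ],
    )
    def test_stability_known_series(self, counts, expected):
        assert s_stability(OccupancySeries(0, counts)) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.integers(0, 20), min_size=1, max_size=100))
    def test_stability_bounded_for_any_integer_series(self, counts):
        value = s_stability(OccupancySeries(0, np.array(counts)))
        assert 0.0 <= value <= 1.0

    def test_depth_normalized_by_maximum(self):
        depths = [DepthStats(0, np.full(4, 50)), DepthStats(1, np.full(4, 25))]
        assert s_depth(depths[0], depths) == 1.0
        assert s_depth(depths[1], depths) == pytest.approx(0.5)

    def test_depth_all_zero_rejected(self):
        depths = [DepthStats(0, np.zeros(4, dtype=int))]
        with pytest.raises(ScoringError, match="empty protein"):
            s_depth(depths[0], depths)


class TestScoreAll:
    def test_composite_is_product_of_terms(self, planted_system):
        topology, frames, params, _ = planted_system
        scores = score_all(topology, frames, params)
        for s in scores:
            assert s.s_residue == pytest.approx(
                s.s_interaction * s.s_stability * s.s_depth, abs=1e-12
            )
            assert 0.0 <= s.s_stability <= 1.0
            assert 0.0 <= s.s_depth <= 1.0
        assert max(s.s_depth for s in scores) == 1.0

    def test_frame_order_does_not_matter(self):
        rng = np.random.default_rng(8)
        topology, frame, params = make_random_system(rng, n_residues=4, n_probes=6)
        frames = []
        for t in range(6):
            coords = frame.coordinates + 0.0
            n_prot = sum(1 for a in topology.atoms if a.role.value == "protein")
            coords[n_prot:] = rng.uniform(0, 30, size=coords[n_prot:].shape)
            from cosolvmap.io_structures import Frame

            frames.append(Frame(coords, box=frame.box, frame_index=t))
        forward = score_all(topology, frames, params)
        backward = score_all(topology, frames[::-1], params)
        for f, b in zip(forward, backward):
            assert f.s_residue == pytest.approx(b.s_residue, abs=1e-12)

    def test_duplicated_trajectory_gives_identical_scores(self, planted_system):
        topology, frames, params, _ = planted_system
        once = score_all(topology, frames[:15], params)
        twice = score_all(topology, frames[:15] * 2, params)
        for a, b in zip(once, twice):
            assert a.s_residue == pytest.approx(b.s_residue, abs=1e-12)

    def test_consistent_with_single_frame_operation(self, planted_system):
        topology, frames, params, _ = planted_system
        e, m, j = frame_residue_energy(9, frames[0], topology, params)
        scores = score_all(topology, frames[:1], params)
        s = scores[9]
        if m > 0:
            assert s.s_interaction == pytest.approx(e / m, rel=1e-12)
        else:
            assert s.s_interaction == 0.0

    def test_empty_trajectory_rejected(self, planted_system):
        topology, _, params, _ = planted_system
        with pytest.raises(ScoringError, match="no frames"):
            score_all(topology, [], params)

    def test_sphere_larger_than_half_box_rejected(self, planted_system):
        topology, frames, params, _ = planted_system
        from cosolvmap.errors import GeometryError

        with pytest.raises((GeometryError, ScoringError)):
            score_all(topology, frames[:1], params, spheres=SphereQueryConfig(r_residue=25.0))
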