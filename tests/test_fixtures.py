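import numpy as np
import pytest

from cosolvmap.errors import FixtureError
from cosolvmap.fixtures import (
    FixtureConfig,
    PlantedSiteSpec,
    add_ring_dummy,
    assign_toy_params,
    build_toy_protein,
    compute_probe_count,
    plant_probe_trajectory,
    write_bundle,
)
from cosolvmap.geometry import probes_within
from cosolvmap.io_structures import Role, read_structure, read_trajectory
from cosolvmap.scoring import combine_lj, softcore_pair_energy


def _site_occupancy(topology, frames, site_residues, radius=8.0):
    """Mean per-frame probe count in the sphere of the central site residue."""
    residues = {r.index: r for r in topology.protein_residues()}
    central = residues[sorted(site_residues)[len(site_residues) // 2]]
    counts = []
    for frame in frames:
        cog = frame.coordinates[np.asarray(central.atom_ids)].mean(axis=0)
        counts.append(len(probes_within(cog, radius, frame, topology)))
    return float(np.mean(counts))


class TestBuildToyProtein:
    def test_helix_construction(self):
        cfg = FixtureConfig(n_residues=10)
        topology, frame = build_toy_protein(cfg)
        assert topology.n_atoms == 40
        assert len(topology.residues) == 10
        ca = [
            i
            for r in topology.residues
            for i in r.atom_ids
            if topology.atoms[i].name == "CA"
        ]
        rises = np.diff(frame.coordinates[ca][:, 2])
        np.testing.assert_allclose(rises, 1.5, atol=1e-9)

    def test_deterministic(self):
        cfg = FixtureConfig()
        _, f1 = build_toy_protein(cfg)
        _, f2 = build_toy_protein(cfg)
        assert np.array_equal(f1.coordinates, f2.coordinates)

    def test_protein_must_fit_the_box(self):
        with pytest.raises(FixtureError):
            build_toy_protein(FixtureConfig(n_residues=100, box_length=10.0))


class TestPlantProbeTrajectory:
    def test_full_residence_keeps_bound_probes_in_site(self):
        cfg = FixtureConfig(n_frames=40, n_probes=3, seed=2)
        spec = PlantedSiteSpec(n_bound_probes=3, residence_fraction=1.0)
        topology, frames = plant_probe_trajectory(build_toy_protein(cfg), spec, cfg)
        occ = _site_occupancy(topology, frames, spec.site_residues)
        assert occ >= spec.n_bound_probes

    def test_partial_residence_matches_binomial_expectation(self):
        cfg = FixtureConfig(n_frames=200, n_probes=2, seed=5)
        spec = PlantedSiteSpec(n_bound_probes=2, residence_fraction=0.5)
        topology, frames = plant_probe_trajectory(build_toy_protein(cfg), spec, cfg)
        occ = _site_occupancy(topology, frames, spec.site_residues)
        # per-frame count ~ Binomial(2, 0.5): mean 1, var 0.5
        se = np.sqrt(2 * 0.5 * 0.5 / cfg.n_frames)
        assert abs(occ - 1.0) <= 3 * se + 0.05  # small allowance for bulk drift-in

    def test_seed_changes_coordinates_but_not_sizes(self):
        cfg_a, cfg_b = FixtureConfig(n_frames=5, seed=1), FixtureConfig(n_frames=5, seed=2)
        spec = PlantedSiteSpec()
        top_a, frames_a = plant_probe_trajectory(build_toy_protein(cfg_a), spec, cfg_a)
        top_b, frames_b = plant_probe_trajectory(build_toy_protein(cfg_b), spec, cfg_b)
        assert top_a.n_atoms == top_b.n_atoms
        assert not np.array_equal(frames_a[0].coordinates, frames_b[0].coordinates)

    def test_reproducible_for_fixed_seed(self):
        cfg = FixtureConfig(n_frames=5, seed=9)
        spec = PlantedSiteSpec()
        _, frames_a = plant_probe_trajectory(build_toy_protein(cfg), spec, cfg)
        _, frames_b = plant_probe_trajectory(build_toy_protein(cfg), spec, cfg)
        for fa, fb in zip(frames_a, frames_b):
            assert np.array_equal(fa.coordinates, fb.coordinates)

    def test_no_probe_atom_clashes_with_protein(self):
        cfg = FixtureConfig(n_frames=10, seed=3)
        spec = PlantedSiteSpec()
        topology, frames = plant_probe_trajectory(build_toy_protein(cfg), spec, cfg)
        n_prot = len(topology.atom_ids_with_role(Role.PROTEIN))
        box = frames[0].box
        for frame in frames:
            delta = frame.coordinates[n_prot:, None, :] - frame.coordinates[None, :n_prot, :]
            delta -= box * np.round(delta / box)
            assert np.sqrt((delta**2).sum(-1)).min() >= 2.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(FixtureError):
            PlantedSiteSpec(residence_fraction=1.5)


class TestRingDummy:
    @pytest.fixture
    def system(self):
        cfg = FixtureConfig(n_frames=3, n_probes=2, seed=0)
        spec = PlantedSiteSpec(n_bound_probes=1)
        return plant_probe_trajectory(build_toy_protein(cfg), spec, cfg)

    def test_dummy_at_ring_centroid_with_standard_charge(self, system):
        topology, frames = system
        top2, frames2 = add_ring_dummy(topology, frames, molecule=0)
        assert top2.n_atoms == topology.n_atoms + 1
        dummy_id = top2.n_atoms - 1
        assert top2.atoms[dummy_id].role is Role.DUMMY
        ring = topology.probe_molecules[0]
        for f_old, f_new in zip(frames, frames2):
            centroid = f_old.coordinates[np.asarray(ring)].mean(axis=0)
            np.testing.assert_allclose(f_new.coordinates[dummy_id], centroid)
        params = assign_toy_params(top2)
        eps, sigma, charge = params.lookup("BNZ", "DU")
        assert charge == -0.01
        assert eps == 0.0

    def test_dummy_excluded_from_cog_but_kept_in_molecule(self, system):
        topology, frames = system
        top2, frames2 = add_ring_dummy(topology, frames, molecule=0)
        assert top2.n_atoms - 1 in top2.probe_molecules[0]
        nondummy = top2.probe_molecule_nondummy()[0]
        assert top2.n_atoms - 1 not in nondummy

    def test_dummy_lj_contribution_is_zero(self, system):
        topology, frames = system
        top2, _ = add_ring_dummy(topology, frames, molecule=0)
        params = assign_toy_params(top2)
        eps_ij, sigma_ij = combine_lj(params.lookup("BNZ", "DU"), params.lookup("ALA", "CA"))
        assert eps_ij == 0.0
        # pure-Coulomb interaction at any distance
        e = softcore_pair_energy(2.0, eps_ij, sigma_ij, -0.01, 0.1)
        assert e == pytest.approx(332.0636 * -0.01 * 0.1 / 3.0)

    def test_missing_ring_atoms_rejected(self, system):
        topology, frames = system
        with pytest.raises(FixtureError, match="ring"):
            add_ring_dummy(topology, frames, molecule=0, ring_atom_names=tuple(f"X{i}" for i in range(6)))


class TestComputeProbeCount:
    def test_benzene_worked_example(self):
        assert compute_probe_count(1000, 78.11, 0.10) == 26

    def test_no_waters_needs_no_probes(self):
        assert compute_probe_count(0, 78.11, 0.10) == 0

    def test_minimality_on_random_inputs(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n_w = int(rng.integers(10, 5000))
            m_p = float(rng.uniform(40.0, 200.0))
            n = compute_probe_count(n_w, m_p, 0.10)

            def fraction(k):
                return k * m_p / (k * m_p + n_w * 18.015)

            assert fraction(n) >= 0.10
            if n > 0:
                assert fraction(n - 1) < 0.10

    def test_invalid_fraction_rejected(self):
        with pytest.raises(FixtureError):
            compute_probe_count(100, 78.11, 1.0)


class TestToyParamsAndBundle:
    def test_every_atom_resolves(self, planted_system):
        topology, _, params, _ = planted_system
        eps, sigma, q = params.as_arrays(topology)
        assert np.all(np.isfinite(eps)) and np.all(sigma > 0)

    def test_bundle_roundtrips_through_readers(self, tmp_path):
        cfg = FixtureConfig(n_frames=8, seed=4)
        bundle = write_bundle(tmp_path / "bundle", cfg, PlantedSiteSpec())
        assert all(p.exists() for p in bundle.paths())
        topology, frame = read_structure(bundle.topology_path)
        frames = list(read_trajectory(topology, bundle.trajectory_path))
        assert len(frames) == 8
        # regenerate in memory and compare at PDB precision
        spec = PlantedSiteSpec()
        top_mem, frames_mem = plant_probe_trajectory(
            build_toy_protein(cfg), spec, cfg
        )
        np.testing.assert_allclose(
            frames[3].coordinates, frames_mem[3].coordinates, atol=1.5e-3
        )
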