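"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use plain Python loops and re-derive every
formula from scratch so they stay independent of the vectorized
implementation they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from cosolvmap.fixtures import (
    FixtureConfig,
    PlantedSiteSpec,
    assign_toy_params,
    build_toy_protein,
    plant_probe_trajectory,
)
from cosolvmap.io_structures import (
    AtomRecord,
    Frame,
    NonbondedParams,
    Residue,
    Topology,
    classify_atoms,
)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def brute_min_image_distance(a, b, box):
    d2 = 0.0
    for k in range(3):
        d = float(a[k]) - float(b[k])
        if box is not None:
            d -= float(box[k]) * round(d / float(box[k]))
        d2 += d * d
    return math.sqrt(d2)


def brute_softcore(r, eps, sigma, qi, qj, d_lj=1.0, d_el=1.0, k_coul=332.0636):
    lj = 4.0 * eps * ((sigma / (r + d_lj)) ** 12 - (sigma / (r + d_lj)) ** 6)
    return lj + k_coul * qi * qj / (r + d_el)


def brute_residue_energy(residue_id, frame, topology, params, r_sphere=8.0,
                         d_lj=1.0, d_el=1.0, k_coul=332.0636):
    """Double-loop re-derivation of the per-frame (E, M, J) triple."""
    box = frame.box
    residues = topology.protein_residues()
    res = residues[residue_id]
    cog = frame.coordinates[np.asarray(res.atom_ids)].mean(axis=0)

    protein_ids = [
        i for i, a in enumerate(topology.atoms) if a.role.value == "protein"
    ]
    in_prot = [
        i
        for i in protein_ids
        if brute_min_image_distance(frame.coordinates[i], cog, box) < r_sphere
    ]

    in_mols = []
    for m, mol in enumerate(topology.probe_molecules):
        nondummy = [i for i in mol if topology.atoms[i].role.value != "dummy"]
        mcog = frame.coordinates[np.asarray(nondummy or mol)].mean(axis=0)
        if brute_min_image_distance(mcog, cog, box) < r_sphere:
            in_mols.append(m)

    energy = 0.0
    for m in in_mols:
        for i in topology.probe_molecules[m]:
            ei, si, qi = params.lookup(
                topology.atoms[i].residue_name, topology.atoms[i].name
            )
            for j in in_prot:
                ej, sj, qj = params.lookup(
                    topology.atoms[j].residue_name, topology.atoms[j].name
                )
                r = brute_min_image_distance(
                    frame.coordinates[i], frame.coordinates[j], box
                )
                energy += brute_softcore(
                    r,
                    math.sqrt(ei * ej),
                    (si + sj) / 2.0,
                    qi,
                    qj,
                    d_lj,
                    d_el,
                    k_coul,
                )
    return energy, len(in_mols), len(in_prot)


# ---------------------------------------------------------------------------
# random toy system builder
# ---------------------------------------------------------------------------


def make_random_system(
    rng: np.random.Generator,
    n_residues: int = 10,
    atoms_per_residue: int = 3,
    n_probes: int = 8,
    atoms_per_probe: int = 3,
    box_length: float | None = 30.0,
):
    """A fully random protein + probe system with random parameters."""
    atoms: list[AtomRecord] = []
    residues: list[Residue] = []
    params = NonbondedParams()
    serial = 0
    extent = box_length if box_length is not None else 30.0

    for i in range(n_residues):
        res = Residue("A", i + 1, "RES", [])
        for k in range(atoms_per_residue):
            serial += 1
            res.atom_ids.append(len(atoms))
            atoms.append(AtomRecord(serial, f"A{k}", "C", "RES", i + 1, "A"))
        residues.append(res)
    for p in range(n_probes):
        res = Residue("B", n_residues + p + 1, "PRB", [])
        for k in range(atoms_per_probe):
            serial += 1
            res.atom_ids.append(len(atoms))
            atoms.append(
                AtomRecord(serial, f"P{k}", "C", "PRB", n_residues + p + 1, "B")
            )
        residues.append(res)

    for rn, n_atoms, prefix in (("RES", atoms_per_residue, "A"), ("PRB", atoms_per_probe, "P")):
        for k in range(n_atoms):
            params.add(
                rn,
                f"{prefix}{k}",
                float(rng.uniform(0.05, 0.2)),
                float(rng.uniform(2.5, 3.5)),
                float(rng.uniform(-0.3, 0.3)),
            )

    topology = Topology(atoms=atoms, residues=residues)
    classify_atoms(topology, probe_resnames={"PRB"})
    coords = rng.uniform(0.0, extent, size=(len(atoms), 3))
    box = None if box_length is None else np.full(3, float(box_length))
    return topology, Frame(coords, box=box), params


# ---------------------------------------------------------------------------
# shared planted-site system
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def planted_system():
    """A modest planted-site trajectory reused by several test modules."""
    cfg = FixtureConfig(n_frames=60, seed=7)
    spec = PlantedSiteSpec()
    topology, frames = plant_probe_trajectory(build_toy_protein(cfg), spec, cfg)
    params = assign_toy_params(topology)
    return topology, frames, params, spec
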