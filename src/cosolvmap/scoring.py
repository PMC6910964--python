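"""Softcore per-residue scoring of cosolvent trajectories.

The composite residue score is the product of three terms computed over a
sphere of radius ``r_residue`` around each residue's per-frame center of
geometry:

* ``S_interaction`` — the per-molecule time-averaged softcore interaction
  energy between in-sphere probe molecules and in-sphere protein atoms,
  ``(sum_t E_t / N) / <M>`` (kcal/mol, negative = favorable);
* ``S_stability`` — ``(1 - rms(dM)) / (<M> - rms(dM))`` where ``rms(dM)``
  is the population standard deviation of the per-frame probe count,
  clamped to [0, 1] and defined as 0 for empty or divergent cases —
  rewarding probes retained with low fluctuation;
* ``S_depth`` — the mean in-sphere protein-atom count normalized by the
  maximum over all residues, a [0, 1] burial/concavity proxy.

Pair energies use a softcore Lennard-Jones + Coulomb form with distance
offsets ``delta_lj`` and ``delta_elec`` (1 A by default) in the
denominators, keeping the energy finite through transient atomic clashes:

    E = 4 eps [ (sigma/(r+d_lj))^12 - (sigma/(r+d_lj))^6 ]
        + K q_i q_j / (r + d_elec)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import GeometryError, ScoringError
from .geometry import SphereQueryConfig, min_image_distance_matrix
from .io_structures import Frame, NonbondedParams, Role, Topology

log = logging.getLogger(__name__)

#: Electrostatic conversion constant in kcal*A/(mol*e^2).
COULOMB_CONSTANT = 332.0636


@dataclass
class SoftcoreConfig:
    delta_lj: float = 1.0
    delta_elec: float = 1.0
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self) -> None:
        if self.delta_lj < 0 or self.delta_elec < 0:
            raise ScoringError("softcore deltas must be non-negative")
        if self.coulomb_constant <= 0:
            raise ScoringError("Coulomb constant must be positive")


@dataclass
class OccupancySeries:
    """Per-frame probe-molecule counts inside a residue sphere."""

    residue_id: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)

    @property
    def mean_occupancy(self) -> float:
        return float(self.counts.mean())

    @property
    def occupancy_rmsd(self) -> float:
        """Population standard deviation of the counts about their mean."""
        return float(self.counts.std())


@dataclass
class EnergySeries:
    residue_id: int
    energies: np.ndarray

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)


@dataclass
class DepthStats:
    residue_id: int
    contacts: np.ndarray

    def __post_init__(self) -> None:
        self.contacts = np.asarray(self.contacts)

    @property
    def mean_contacts(self) -> float:
        return float(self.contacts.mean())


@dataclass
class ResidueScore:
    residue_id: int  # position in topology.protein_residues()
    residue_index: int  # 1-based index from the source file
    residue_name: str
    center: np.ndarray  # trajectory-average residue COG
    s_interaction: float
    s_stability: float
    s_depth: float
    s_residue: float


def softcore_pair_energy(r, eps_ij, sigma_ij, q_i, q_j, cfg: SoftcoreConfig | None = None):
    """Softcore LJ + Coulomb pair energy (kcal/mol); vectorizes over inputs."""
    cfg = cfg or SoftcoreConfig()
    r = np.asarray(r, dtype=float)
    r_lj = r + cfg.delta_lj
    r_el = r + cfg.delta_elec
    if np.any(r_lj == 0) or np.any(r_el == 0):
        raise ScoringError("softcore denominator is zero (r + delta = 0)")
    sr6 = (np.asarray(sigma_ij) / r_lj) ** 6
    lj = 4.0 * np.asarray(eps_ij) * (sr6**2 - sr6)
    coul = cfg.coulomb_constant * np.asarray(q_i) * np.asarray(q_j) / r_el
    out = lj + coul
    return float(out) if out.ndim == 0 else out


def combine_lj(params_i: Sequence[float], params_j: Sequence[float]) -> tuple[float, float]:
    """Lorentz-Berthelot mixing: geometric-mean epsilon, arithmetic-mean sigma."""
    eps_i, sigma_i = params_i[0], params_i[1]
    eps_j, sigma_j = params_j[0], params_j[1]
    return float(np.sqrt(eps_i * eps_j)), float((sigma_i + sigma_j) / 2.0)


class _System:
    """Precomputed per-atom arrays shared by all frame evaluations."""

    def __init__(self, topology: Topology, params: NonbondedParams):
        self.topology = topology
        self.eps, self.sigma, self.charge = params.as_arrays(topology)
        self.protein_atoms = topology.atom_ids_with_role(Role.PROTEIN)
        if self.protein_atoms.size == 0:
            raise ScoringError("empty protein: no protein-role atoms")
        self.residues = topology.protein_residues()
        if not self.residues:
            raise ScoringError("empty protein: no protein residues")
        self.residue_atom_ids = [np.asarray(r.atom_ids, dtype=int) for r in self.residues]
        self.probe_atom_ids = [np.asarray(m, dtype=int) for m in topology.probe_molecules]
        self.probe_nondummy = topology.probe_molecule_nondummy()

    def residue_cogs(self, frame: Frame) -> np.ndarray:
        return np.stack([frame.coordinates[ids].mean(axis=0) for ids in self.residue_atom_ids])

    def probe_cogs(self, frame: Frame) -> np.ndarray:
        if not self.probe_nondummy:
            return np.zeros((0, 3))
        return np.stack([frame.coordinates[ids].mean(axis=0) for ids in self.probe_nondummy])


def _frame_terms(
    system: _System,
    frame: Frame,
    cfg: SoftcoreConfig,
    spheres: SphereQueryConfig,
    res_cogs: np.ndarray | None = None,
    probe_cogs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-residue (E, M, J) for a single frame."""
    box = frame.box
    r = spheres.r_residue
    if box is not None and r > float(box.min()) / 2:
        raise GeometryError(
            f"r_residue {r} exceeds half the smallest box length; minimum image invalid"
        )
    X = frame.coordinates
    if res_cogs is None:
        res_cogs = system.residue_cogs(frame)
    if probe_cogs is None:
        probe_cogs = system.probe_cogs(frame)

    prot_xyz = X[system.protein_atoms]
    d_prot = min_image_distance_matrix(res_cogs, prot_xyz, box)
    in_sphere_prot = d_prot < r
    contacts = in_sphere_prot.sum(axis=1)

    n_res = len(system.residues)
    counts = np.zeros(n_res, dtype=int)
    energies = np.zeros(n_res, dtype=float)
    if probe_cogs.shape[0]:
        d_probe = min_image_distance_matrix(res_cogs, probe_cogs, box)
        in_sphere_probe = d_probe < r
        counts = in_sphere_probe.sum(axis=1)
        for j in range(n_res):
            mols = np.nonzero(in_sphere_probe[j])[0]
            if mols.size == 0:
                continue
            prot_ids = system.protein_atoms[in_sphere_prot[j]]
            if prot_ids.size == 0:
                continue
            probe_ids = np.concatenate([system.probe_atom_ids[m] for m in mols])
            dist = min_image_distance_matrix(X[probe_ids], X[prot_ids], box)
            eij = np.sqrt(np.outer(system.eps[probe_ids], system.eps[prot_ids]))
            sij = 0.5 * (system.sigma[probe_ids][:, None] + system.sigma[prot_ids][None, :])
            energies[j] = float(
                np.sum(
                    softcore_pair_energy(
                        dist,
                        eij,
                        sij,
                        system.charge[probe_ids][:, None],
                        system.charge[prot_ids][None, :],
                        cfg,
                    )
                )
            )
    return energies, counts, contacts


def frame_residue_energy(
    residue_id: int,
    frame: Frame,
    topology: Topology,
    params: NonbondedParams,
    cfg: SoftcoreConfig | None = None,
    spheres: SphereQueryConfig | None = None,
) -> tuple[float, int, int]:
    """Single-frame (E, M, J) for one protein residue.

    The sphere is centered at the residue's COG this frame; ``M`` counts
    probe molecules whose dummy-excluded COG lies strictly inside, ``J``
    counts in-sphere protein atoms (the residue's own included), and ``E``
    sums softcore pair energies between all atoms of in-sphere probe
    molecules and in-sphere protein atoms under minimum-image distances.
    """
    cfg = cfg or SoftcoreConfig()
    spheres = spheres or SphereQueryConfig()
    system = _System(topology, params)
    if not 0 <= residue_id < len(system.residues):
        raise ScoringError(f"no protein residue with id {residue_id}")
    energies, counts, contacts = _frame_terms(system, frame, cfg, spheres)
    return float(energies[residue_id]), int(counts[residue_id]), int(contacts[residue_id])


def s_interaction(energy: EnergySeries, occupancy: OccupancySeries) -> float:
    """Mean per-frame energy divided by the mean occupancy; 0 when <M> = 0."""
    n = len(energy.energies)
    if n == 0 or len(occupancy.counts) == 0:
        raise ScoringError("empty series: no frames")
    if n != len(occupancy.counts):
        raise ScoringError("energy and occupancy series lengths differ")
    mean_m = occupancy.mean_occupancy
    if mean_m == 0:
        return 0.0
    return float(energy.energies.sum() / n / mean_m)


def s_stability(occupancy: OccupancySeries) -> float:
    """(1 - rms(dM)) / (<M> - rms(dM)), clamped to [0, 1].

    Returns 0 when the sphere is never occupied or when the denominator is
    non-positive (fluctuation at least as large as the mean occupancy).
    """
    if len(occupancy.counts) == 0:
        raise ScoringError("empty occupancy series")
    mean_m = occupancy.mean_occupancy
    if mean_m == 0:
        return 0.0
    rmsd = occupancy.occupancy_rmsd
    denom = mean_m - rmsd
    if denom <= 0:
        return 0.0
    return float(min(max((1.0 - rmsd) / denom, 0.0), 1.0))


def s_depth(depth: DepthStats, all_depths: Iterable[DepthStats]) -> float:
    """Mean contact count normalized by the maximum over all residues."""
    max_j = max(d.mean_contacts for d in all_depths)
    if max_j <= 0:
        raise ScoringError("empty protein: all mean contact counts are zero")
    return float(depth.mean_contacts / max_j)


def score_all(
    topology: Topology,
    trajectory: Iterable[Frame],
    params: NonbondedParams,
    cfg: SoftcoreConfig | None = None,
    spheres: SphereQueryConfig | None = None,
) -> list[ResidueScore]:
    """Score every protein residue over a trajectory.

    Residue sphere centers are recomputed each frame (the protein moves);
    the reported residue center is the trajectory average of the per-frame
    COG.  Deterministic for fixed input.
    """
    cfg = cfg or SoftcoreConfig()
    spheres = spheres or SphereQueryConfig()
    system = _System(topology, params)
    n_res = len(system.residues)

    energy_rows: list[np.ndarray] = []
    count_rows: list[np.ndarray] = []
    contact_rows: list[np.ndarray] = []
    center_sum = np.zeros((n_res, 3))
    n_frames = 0
    for frame in trajectory:
        res_cogs = system.residue_cogs(frame)
        e, m, j = _frame_terms(system, frame, cfg, spheres, res_cogs=res_cogs)
        energy_rows.append(e)
        count_rows.append(m)
        contact_rows.append(j)
        center_sum += res_cogs
        n_frames += 1
    if n_frames == 0:
        raise ScoringError("no frames in trajectory")

    energies = np.stack(energy_rows, axis=1)  # (n_res, n_frames)
    counts = np.stack(count_rows, axis=1)
    contacts = np.stack(contact_rows, axis=1)
    centers = center_sum / n_frames

    occ = [OccupancySeries(i, counts[i]) for i in range(n_res)]
    eng = [EnergySeries(i, energies[i]) for i in range(n_res)]
    dep = [DepthStats(i, contacts[i]) for i in range(n_res)]

    scores: list[ResidueScore] = []
    for i, res in enumerate(system.residues):
        s_int = s_interaction(eng[i], occ[i])
        s_stab = s_stability(occ[i])
        s_dep = s_depth(dep[i], dep)
        scores.append(
            ResidueScore(
                residue_id=i,
                residue_index=res.index,
                residue_name=res.name,
                center=centers[i],
                s_interaction=s_int,
                s_stability=s_stab,
                s_depth=s_dep,
                s_residue=s_int * s_stab * s_dep,
            )
        )
    log.info("scored %d residues over %d frames", n_res, n_frames)
    return scores
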