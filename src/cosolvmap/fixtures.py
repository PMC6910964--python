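"""Synthetic toy systems with planted binding sites.

The generator scripts probe occupancy rather than simulating dynamics: a
rigid helical pseudo-protein sits in a cubic periodic box, a configurable
number of "bound" benzene-like probes revisit a planted surface site for a
chosen fraction of frames, and the remaining probes are re-inserted
uniformly each frame (rejecting clashes with the protein).  Everything is
reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FixtureError, SitesError
from .io_structures import (
    AtomRecord,
    Frame,
    NonbondedParams,
    Residue,
    Role,
    Topology,
    classify_atoms,
    write_nonbonded_params,
    write_pdb,
)

log = logging.getLogger(__name__)

_HELIX_RISE = 1.5  # A per residue
_HELIX_TWIST = np.deg2rad(100.0)
_HELIX_RADIUS = 2.3  # A, CA distance from the helix axis
_RING_RADIUS = 1.39  # A, benzene C-C ring radius
_PROBE_RESNAME = "BNZ"
_CLASH_DISTANCE = 2.0  # A, probe-atom / protein-atom insertion clash limit
_BOUND_ANCHOR_OFFSET = 4.5  # A, radially outward from the anchor residue CA

#: Local offsets of backbone-like atoms from the CA position, expressed in
#: the (radial, tangential, axial) frame of the helix at that residue.
_LOCAL_OFFSETS = {
    "N": (-0.8, 1.0, -0.5),
    "CA": (0.0, 0.0, 0.0),
    "C": (0.7, -1.1, 0.5),
    "O": (1.3, -0.2, 1.3),
}
_ATOM_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}


@dataclass
class FixtureConfig:
    n_residues: int = 20
    atoms_per_residue: int = 4
    box_length: float = 40.0
    n_probes: int = 13
    n_frames: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_residues, self.atoms_per_residue, self.n_probes, self.n_frames) < 1:
            raise FixtureError("all fixture sizes must be positive")
        if self.box_length <= 0:
            raise FixtureError("box length must be positive")
        if self.atoms_per_residue > 4:
            raise FixtureError("at most 4 atoms per pseudo-residue (N, CA, C, O)")


@dataclass
class PlantedSiteSpec:
    site_residues: tuple[int, ...] = (10, 11, 12)
    n_bound_probes: int = 3
    residence_fraction: float = 0.9
    jitter: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.residence_fraction <= 1.0:
            raise FixtureError("residence_fraction must lie in [0, 1]")
        if self.n_bound_probes < 0 or self.jitter < 0:
            raise FixtureError("n_bound_probes and jitter must be non-negative")
        if not self.site_residues:
            raise SitesError("planted site has no residues")


def build_toy_protein(cfg: FixtureConfig) -> tuple[Topology, Frame]:
    """An ideal helix-like chain of pseudo-residues centered in the box.

    Each residue carries up to four backbone-like atoms (N, CA, C, O) at a
    fixed internal geometry, with 1.5 A rise and 100 degree twist per
    residue.  Fully deterministic.
    """
    names = list(_LOCAL_OFFSETS)[: cfg.atoms_per_residue]
    coords: list[np.ndarray] = []
    atoms: list[AtomRecord] = []
    residues: list[Residue] = []
    serial = 0
    for i in range(cfg.n_residues):
        theta = i * _HELIX_TWIST
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        tangential = np.array([-np.sin(theta), np.cos(theta), 0.0])
        axial = np.array([0.0, 0.0, 1.0])
        ca = _HELIX_RADIUS * radial + np.array([0.0, 0.0, i * _HELIX_RISE])
        res = Residue(chain_id="A", index=i + 1, name="ALA", atom_ids=[])
        for name in names:
            u, v, w = _LOCAL_OFFSETS[name]
            serial += 1
            res.atom_ids.append(len(atoms))
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=_ATOM_ELEMENTS[name],
                    residue_name="ALA",
                    residue_index=i + 1,
                    chain_id="A",
                    role=Role.PROTEIN,
                )
            )
            coords.append(ca + u * radial + v * tangential + w * axial)
        residues.append(res)
    xyz = np.asarray(coords)
    span = xyz.max(axis=0) - xyz.min(axis=0)
    if np.any(span + 2.0 > cfg.box_length):
        raise FixtureError(
            f"protein span {span} does not fit a box of {cfg.box_length} A"
        )
    center = np.full(3, cfg.box_length / 2.0)
    xyz = xyz - xyz.mean(axis=0) + center
    topology = Topology(atoms=atoms, residues=residues)
    frame = Frame(xyz, box=np.full(3, cfg.box_length), frame_index=0)
    return topology, frame


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _ring_template() -> np.ndarray:
    angles = np.arange(6) * np.pi / 3.0
    return _RING_RADIUS * np.stack(
        [np.cos(angles), np.sin(angles), np.zeros(6)], axis=1
    )


def _min_dist_to(points: np.ndarray, targets: np.ndarray, box: np.ndarray) -> float:
    delta = points[:, None, :] - targets[None, :, :]
    delta -= box * np.round(delta / box)
    return float(np.sqrt((delta**2).sum(axis=-1)).min())


def plant_probe_trajectory(
    protein: tuple[Topology, Frame],
    spec: PlantedSiteSpec,
    cfg: FixtureConfig,
) -> tuple[Topology, list[Frame]]:
    """Add probe molecules and script their motion over ``cfg.n_frames``.

    Bound probes occupy per-probe anchors on the protein surface near the
    planted site for a Bernoulli(residence_fraction) subset of frames
    (with Gaussian jitter of ``spec.jitter`` A), and are placed uniformly
    in the box otherwise; the remaining probes are uniform every frame.
    All insertions reject configurations placing any probe atom within
    2 A of a protein atom.
    """
    prot_top, prot_frame = protein
    if spec.n_bound_probes > cfg.n_probes:
        raise FixtureError("n_bound_probes exceeds the total probe count")
    res_by_index = {r.index: r for r in prot_top.residues}
    for rid in spec.site_residues:
        if rid not in res_by_index:
            raise SitesError(f"planted site residue {rid} not in the toy protein")

    box = np.full(3, cfg.box_length)
    prot_xyz = prot_frame.coordinates
    rng = np.random.default_rng(cfg.seed)
    ring = _ring_template()

    # combined topology: protein residues followed by one BNZ residue per probe
    atoms = [
        AtomRecord(a.serial, a.name, a.element, a.residue_name, a.residue_index, a.chain_id)
        for a in prot_top.atoms
    ]
    residues = [
        Residue(r.chain_id, r.index, r.name, list(r.atom_ids)) for r in prot_top.residues
    ]
    serial = max((a.serial for a in atoms), default=0)
    next_resid = max(r.index for r in residues) + 1
    for p in range(cfg.n_probes):
        res = Residue(chain_id="B", index=next_resid + p, name=_PROBE_RESNAME, atom_ids=[])
        for k in range(6):
            serial += 1
            res.atom_ids.append(len(atoms))
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=f"C{k + 1}",
                    element="C",
                    residue_name=_PROBE_RESNAME,
                    residue_index=res.index,
                    chain_id="B",
                )
            )
        residues.append(res)
    topology = Topology(atoms=atoms, residues=residues)
    classify_atoms(topology, probe_resnames={_PROBE_RESNAME})

    # anchors: central site residue CA, displaced radially outward from the
    # helix axis, one axial slot per bound probe
    sorted_site = sorted(spec.site_residues)
    central = res_by_index[sorted_site[len(sorted_site) // 2]]
    ca_id = next(
        (i for i in central.atom_ids if prot_top.atoms[i].name == "CA"),
        central.atom_ids[0],
    )
    ca = prot_xyz[ca_id]
    axis_xy = prot_xyz.mean(axis=0)
    outward = np.array([ca[0] - axis_xy[0], ca[1] - axis_xy[1], 0.0])
    norm = np.linalg.norm(outward)
    outward = outward / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
    anchors = [
        ca
        + _BOUND_ANCHOR_OFFSET * outward
        + np.array([0.0, 0.0, (k - (spec.n_bound_probes - 1) / 2.0) * 1.5])
        for k in range(spec.n_bound_probes)
    ]
    for anchor in anchors:
        if _min_dist_to(anchor[None, :], prot_xyz, box) < _CLASH_DISTANCE + 1.0:
            raise FixtureError("bound-probe anchor too close to the protein")

    def place(center_sampler) -> np.ndarray:
        for _ in range(1000):
            center = center_sampler()
            atoms_xyz = center + ring @ _random_rotation(rng).T
            if _min_dist_to(atoms_xyz, prot_xyz, box) >= _CLASH_DISTANCE:
                return atoms_xyz
        raise FixtureError("probe insertion failed 1000 times: system too dense")

    frames: list[Frame] = []
    for t in range(cfg.n_frames):
        probe_xyz = np.empty((cfg.n_probes * 6, 3))
        for p in range(cfg.n_probes):
            bound = p < spec.n_bound_probes and rng.random() < spec.residence_fraction
            if bound:
                anchor = anchors[p]
                sampler = lambda: anchor + rng.normal(0.0, spec.jitter, size=3)
            else:
                sampler = lambda: rng.uniform(0.0, cfg.box_length, size=3)
            probe_xyz[p * 6 : (p + 1) * 6] = place(sampler)
        coords = np.vstack([prot_xyz, probe_xyz])
        frames.append(Frame(coords, box=box.copy(), frame_index=t))
    return topology, frames


def add_ring_dummy(
    topology: Topology,
    frames: list[Frame],
    molecule: int,
    ring_atom_names: tuple[str, ...] = ("C1", "C2", "C3", "C4", "C5", "C6"),
) -> tuple[Topology, list[Frame]]:
    """Append a ring-centroid dummy atom to one probe molecule.

    The dummy sits at the centroid of the six ring atoms in every frame,
    carries role ``dummy`` (zero LJ well depth, charge -0.01 e via the
    parameter table) and stays a member of its molecule for occupancy
    counting while being excluded from the molecule's COG.
    """
    if not 0 <= molecule < len(topology.probe_molecules):
        raise FixtureError(f"no probe molecule with index {molecule}")
    mol_ids = topology.probe_molecules[molecule]
    by_name = {topology.atoms[i].name: i for i in mol_ids}
    try:
        ring_ids = [by_name[n] for n in ring_atom_names]
    except KeyError as exc:
        raise FixtureError(f"ring atoms not found in molecule {molecule}: {exc}") from None
    if len(ring_atom_names) != 6:
        raise FixtureError("a 6-membered ring is required")

    template = topology.atoms[mol_ids[0]]
    new_top = Topology(
        atoms=[
            AtomRecord(a.serial, a.name, a.element, a.residue_name, a.residue_index, a.chain_id, a.role)
            for a in topology.atoms
        ],
        residues=[Residue(r.chain_id, r.index, r.name, list(r.atom_ids)) for r in topology.residues],
        probe_molecules=[list(m) for m in topology.probe_molecules],
        source_path=topology.source_path,
    )
    dummy_id = len(new_top.atoms)
    new_top.atoms.append(
        AtomRecord(
            serial=max(a.serial for a in new_top.atoms) + 1,
            name="DU",
            element="",
            residue_name=template.residue_name,
            residue_index=template.residue_index,
            chain_id=template.chain_id,
            role=Role.DUMMY,
        )
    )
    for res in new_top.residues:
        if res.key == (template.chain_id, template.residue_index, template.residue_name):
            res.atom_ids.append(dummy_id)
            break
    new_top.probe_molecules[molecule].append(dummy_id)

    new_frames = []
    for frame in frames:
        centroid = frame.coordinates[ring_ids].mean(axis=0)
        new_frames.append(
            Frame(
                np.vstack([frame.coordinates, centroid[None, :]]),
                box=None if frame.box is None else frame.box.copy(),
                frame_index=frame.frame_index,
            )
        )
    return new_top, new_frames


def compute_probe_count(
    n_waters: int,
    probe_molar_mass: float,
    mass_fraction: float,
    water_molar_mass: float = 18.015,
) -> int:
    """Smallest probe count reaching the target mass-per-mass fraction.

    Solves n*m_p / (n*m_p + W*m_w) >= f for integer n (ceiling, so the
    stated concentration is reached, never undershot).
    """
    if probe_molar_mass <= 0 or water_molar_mass <= 0:
        raise FixtureError("molar masses must be positive")
    if not 0 < mass_fraction < 1:
        raise FixtureError("mass fraction must lie strictly between 0 and 1")
    if n_waters < 0:
        raise FixtureError("water count must be non-negative")
    if n_waters == 0:
        return 0
    needed = mass_fraction * n_waters * water_molar_mass / (
        (1.0 - mass_fraction) * probe_molar_mass
    )
    return math.ceil(needed - 1e-12)


def assign_toy_params(topology: Topology) -> NonbondedParams:
    """Deterministic toy nonbonded parameters covering every atom.

    Protein atoms: eps 0.1 kcal/mol, sigma 3.2 A, charges alternating
    +/-0.1 e along each residue; probe atoms: eps 0.15, sigma 3.4,
    q -0.05; dummies: eps 0, q -0.01.
    """
    params = NonbondedParams()
    seen: set[tuple[str, str]] = set()
    for res in topology.residues:
        for pos, i in enumerate(res.atom_ids):
            atom = topology.atoms[i]
            key = (atom.residue_name, atom.name)
            if key in seen:
                continue
            seen.add(key)
            if atom.role is Role.DUMMY:
                params.add(*key, 0.0, 1.0, -0.01)
            elif atom.role is Role.PROBE:
                params.add(*key, 0.15, 3.4, -0.05)
            elif atom.role in (Role.SOLVENT, Role.ION):
                params.add(*key, 0.15, 3.2, 0.0)
            else:
                params.add(*key, 0.1, 3.2, 0.1 if pos % 2 == 0 else -0.1)
    return params


@dataclass
class FixtureBundle:
    topology_path: Path
    trajectory_path: Path
    params_path: Path
    sites_path: Path
    config_path: Path
    site_residues: tuple[int, ...] = ()

    def paths(self) -> list[Path]:
        return [
            self.topology_path,
            self.trajectory_path,
            self.params_path,
            self.sites_path,
            self.config_path,
        ]


def write_bundle(
    outdir: str | Path,
    cfg: FixtureConfig | None = None,
    spec: PlantedSiteSpec | None = None,
    with_dummies: bool = False,
) -> FixtureBundle:
    """Generate and write a complete analysis-ready fixture bundle.

    Emits topology PDB, multi-model trajectory PDB, parameter table,
    planted-site file and a ready-to-run analysis config.
    """
    import yaml

    cfg = cfg or FixtureConfig()
    spec = spec or PlantedSiteSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    protein = build_toy_protein(cfg)
    topology, frames = plant_probe_trajectory(protein, spec, cfg)
    if with_dummies:
        for m in range(len(topology.probe_molecules)):
            topology, frames = add_ring_dummy(topology, frames, m)
    params = assign_toy_params(topology)

    bundle = FixtureBundle(
        topology_path=outdir / "topology.pdb",
        trajectory_path=outdir / "trajectory.pdb",
        params_path=outdir / "params.tsv",
        sites_path=outdir / "sites.txt",
        config_path=outdir / "config.yaml",
        site_residues=tuple(spec.site_residues),
    )
    write_pdb(topology, frames[0], bundle.topology_path)
    write_pdb(topology, frames, bundle.trajectory_path)
    write_nonbonded_params(params, bundle.params_path)
    with open(bundle.sites_path, "w") as fh:
        fh.write("planted: " + ",".join(str(r) for r in spec.site_residues) + "\n")
    config = {
        "topology": "topology.pdb",
        "trajectory": "trajectory.pdb",
        "params": "params.tsv",
        "sites": "sites.txt",
        "probe_resnames": [_PROBE_RESNAME],
        "solvent_resnames": [],
        "ion_resnames": [],
        "seed": cfg.seed,
    }
    with open(bundle.config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    log.info("fixture bundle written to %s", outdir)
    return bundle
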