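"""Structure, trajectory and parameter-table I/O.

Coordinates are handled internally in Angstrom, energies in kcal/mol and
charges in units of the elementary charge.  PDB and GRO structures and
XTC/DCD/multi-model-PDB trajectories are read through MDAnalysis (which
performs the nm -> Angstrom conversion for GROMACS formats); writing of the
small fixed-column PDB outputs produced by the pipeline is done locally so
the column contract (B-factor scores, clamping, dummy HETATM records) is
fully under our control.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import (
    ParameterError,
    StructureParseError,
    TopologyError,
    UnsupportedFormatError,
)

log = logging.getLogger(__name__)

#: Atom names treated as massless dummy sites (aromatic ring centroids).
DUMMY_ATOM_NAMES = {"DU"}

#: Clamp range of the PDB B-factor column (columns 61-66, %6.2f).
BFACTOR_MIN = -99.99
BFACTOR_MAX = 999.99


class Role(str, Enum):
    """Role of an atom in the scoring pipeline."""

    PROTEIN = "protein"
    PROBE = "probe"
    SOLVENT = "solvent"
    ION = "ion"
    DUMMY = "dummy"


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int  # 1-based, as in the source file
    chain_id: str
    role: Role = Role.PROTEIN


@dataclass
class Residue:
    """A residue; identity is (chain_id, residue_index, residue_name)."""

    chain_id: str
    index: int
    name: str
    atom_ids: list[int]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.index, self.name)


@dataclass
class Topology:
    atoms: list[AtomRecord]
    residues: list[Residue]
    #: One entry per cosolvent molecule: atom ids (dummies included).
    probe_molecules: list[list[int]] = field(default_factory=list)
    #: Path of the structure file this topology was read from, if any.
    source_path: str | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_ids_with_role(self, role: Role) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.role is role], dtype=int
        )

    def protein_residues(self) -> list[Residue]:
        """Residues whose atoms are all protein-role."""
        return [
            r
            for r in self.residues
            if all(self.atoms[i].role is Role.PROTEIN for i in r.atom_ids)
        ]

    def probe_molecule_nondummy(self) -> list[np.ndarray]:
        """Per probe molecule, the atom ids excluding dummy sites.

        Dummy ring atoms carry charge for electrostatics but are excluded
        from the molecule's center of geometry.
        """
        out = []
        for mol in self.probe_molecules:
            ids = [i for i in mol if self.atoms[i].role is not Role.DUMMY]
            out.append(np.array(ids if ids else mol, dtype=int))
        return out


@dataclass
class Frame:
    coordinates: np.ndarray  # (n_atoms, 3) Angstrom
    box: np.ndarray | None = None  # orthorhombic box lengths (3,) Angstrom
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or not np.all(self.box > 0):
                raise StructureParseError(f"invalid box: {self.box}")


class NonbondedParams:
    """Per-atom Lennard-Jones and charge parameters.

    Entries are keyed by ``(residue_name, atom_name)``; a residue name of
    ``'*'`` acts as a wildcard fallback that exact keys shadow.
    """

    def __init__(self) -> None:
        self._exact: dict[tuple[str, str], tuple[float, float, float]] = {}
        self._wildcard: dict[str, tuple[float, float, float]] = {}

    def add(
        self, residue_name: str, atom_name: str, epsilon: float, sigma: float, charge: float
    ) -> None:
        for v in (epsilon, sigma, charge):
            if not math.isfinite(v):
                raise ParameterError(
                    f"non-finite parameter for ({residue_name}, {atom_name})"
                )
        if epsilon < 0:
            raise ParameterError(f"negative epsilon for ({residue_name}, {atom_name})")
        if sigma <= 0:
            raise ParameterError(f"non-positive sigma for ({residue_name}, {atom_name})")
        entry = (float(epsilon), float(sigma), float(charge))
        if residue_name == "*":
            if atom_name in self._wildcard:
                raise ParameterError(f"duplicate wildcard entry for atom {atom_name}")
            self._wildcard[atom_name] = entry
        else:
            key = (residue_name, atom_name)
            if key in self._exact:
                raise ParameterError(f"duplicate entry for {key}")
            self._exact[key] = entry

    def lookup(self, residue_name: str, atom_name: str) -> tuple[float, float, float]:
        """Return ``(epsilon, sigma, charge)``; exact keys shadow wildcards."""
        try:
            return self._exact[(residue_name, atom_name)]
        except KeyError:
            pass
        try:
            return self._wildcard[atom_name]
        except KeyError:
            raise ParameterError(
                f"no nonbonded parameters for ({residue_name}, {atom_name})"
            ) from None

    def __len__(self) -> int:
        return len(self._exact) + len(self._wildcard)

    def as_arrays(self, topology: Topology) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Resolve parameters for every atom of *topology*.

        Dummy atoms missing from the table default to (eps=0, sigma=1,
        q=-0.01), the standard aromatic ring-centroid treatment.
        """
        n = topology.n_atoms
        eps = np.empty(n)
        sig = np.empty(n)
        q = np.empty(n)
        for i, atom in enumerate(topology.atoms):
            try:
                eps[i], sig[i], q[i] = self.lookup(atom.residue_name, atom.name)
            except ParameterError:
                if atom.role is Role.DUMMY:
                    eps[i], sig[i], q[i] = 0.0, 1.0, -0.01
                else:
                    raise ParameterError(
                        f"no nonbonded parameters for atom {atom.serial} "
                        f"({atom.residue_name} {atom.residue_index} {atom.name})"
                    ) from None
        return eps, sig, q

    def entries(self) -> Iterator[tuple[str, str, float, float, float]]:
        for (rn, an), (e, s, c) in sorted(self._exact.items()):
            yield rn, an, e, s, c
        for an, (e, s, c) in sorted(self._wildcard.items()):
            yield "*", an, e, s, c


def read_nonbonded_params(path: str | Path) -> NonbondedParams:
    """Read a whitespace-delimited parameter table.

    Columns: residue_name atom_name epsilon(kcal/mol) sigma(A) charge(e).
    ``#`` starts a comment; residue_name ``*`` is a wildcard fallback.
    """
    params = NonbondedParams()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 5:
                raise ParameterError(
                    f"{path}:{lineno}: expected 5 columns, got {len(fields)}"
                )
            rn, an = fields[0], fields[1]
            try:
                e, s, c = (float(x) for x in fields[2:5])
            except ValueError as exc:
                raise ParameterError(f"{path}:{lineno}: {exc}") from None
            params.add(rn, an, e, s, c)
    return params


def write_nonbonded_params(params: NonbondedParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# residue_name atom_name epsilon(kcal/mol) sigma(A) charge(e)\n")
        for rn, an, e, s, c in params.entries():
            fh.write(f"{rn}\t{an}\t{e!r}\t{s!r}\t{c!r}\n")


# ---------------------------------------------------------------------------
# structure / trajectory reading (MDAnalysis backend)
# ---------------------------------------------------------------------------


def _guess_element(name: str) -> str:
    stripped = name.lstrip("0123456789")
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def _universe(*paths: str, **kwargs):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(*paths, **kwargs)


def _box_from_dimensions(dims) -> np.ndarray | None:
    if dims is None:
        return None
    dims = np.asarray(dims, dtype=float)
    if np.allclose(dims[:3], 0):
        return None
    if not np.allclose(dims[3:], 90.0, atol=1e-3):
        raise UnsupportedFormatError(
            f"triclinic box (angles {dims[3:]}) is not supported; only "
            "orthorhombic boxes are handled"
        )
    return dims[:3].copy()


def _topology_from_universe(u, source_path: str | None) -> Topology:
    n = len(u.atoms)
    try:
        elements = [str(e) for e in u.atoms.elements]
    except Exception:
        elements = [_guess_element(str(nm)) for nm in u.atoms.names]
    try:
        chains = [str(c) if str(c).strip() else "A" for c in u.atoms.chainIDs]
    except Exception:
        chains = ["A"] * n
    try:
        serials = [int(s) for s in u.atoms.ids]
    except Exception:
        serials = list(range(1, n + 1))

    atoms: list[AtomRecord] = []
    residues: list[Residue] = []
    current_key: tuple[str, int, str] | None = None
    for i, atom in enumerate(u.atoms):
        rec = AtomRecord(
            serial=serials[i],
            name=str(atom.name),
            element=elements[i] or _guess_element(str(atom.name)),
            residue_name=str(atom.resname),
            residue_index=int(atom.resid),
            chain_id=chains[i],
            role=Role.PROTEIN,
        )
        atoms.append(rec)
        key = (rec.chain_id, rec.residue_index, rec.residue_name)
        if key != current_key:
            residues.append(Residue(rec.chain_id, rec.residue_index, rec.residue_name, []))
            current_key = key
        residues[-1].atom_ids.append(i)
    return Topology(atoms=atoms, residues=residues, source_path=source_path)


def read_structure(
    path: str | Path, format_hint: str = "auto"
) -> tuple[Topology, Frame]:
    """Read a PDB or GRO structure into a Topology and its first Frame.

    Coordinates are returned in Angstrom (GRO nm values are converted by
    the MDAnalysis backend); residue indices are kept 1-based as in the
    file.  The box is taken from CRYST1 / the GRO box line when present.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    if format_hint == "auto":
        suffix = path.suffix.lower().lstrip(".")
        format_hint = suffix if suffix in ("pdb", "gro") else "auto"
    if format_hint not in ("pdb", "gro", "auto"):
        raise UnsupportedFormatError(f"unknown format hint: {format_hint}")
    try:
        u = _universe(str(path))
    except UnsupportedFormatError:
        raise
    except Exception as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    topology = _topology_from_universe(u, str(path))
    box = _box_from_dimensions(u.dimensions)
    frame = Frame(np.array(u.atoms.positions, dtype=float), box=box, frame_index=0)
    return topology, frame


def read_trajectory(topology: Topology, path: str | Path) -> Iterator[Frame]:
    """Yield trajectory frames in file order with increasing frame_index.

    Multi-model PDB files are self-contained; XTC/DCD files are opened
    against the structure file the topology was read from.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix == ".pdb" or topology.source_path is None:
            u = _universe(str(path))
        else:
            u = _universe(topology.source_path, str(path))
    except Exception as exc:
        raise StructureParseError(f"cannot open trajectory {path}: {exc}") from exc
    if len(u.atoms) != topology.n_atoms:
        raise TopologyError(
            f"trajectory has {len(u.atoms)} atoms, topology has {topology.n_atoms}"
        )
    for i, ts in enumerate(u.trajectory):
        box = _box_from_dimensions(ts.dimensions)
        yield Frame(np.array(u.atoms.positions, dtype=float), box=box, frame_index=i)


# ---------------------------------------------------------------------------
# atom classification
# ---------------------------------------------------------------------------


def classify_atoms(
    topology: Topology,
    probe_resnames: set[str] | Sequence[str],
    solvent_resnames: set[str] | Sequence[str] = (),
    ion_resnames: set[str] | Sequence[str] = (),
) -> Topology:
    """Assign a role to every atom and group probe molecules.

    Atoms in probe residues become ``probe`` (grouped one molecule per
    residue), solvent and ion residues likewise; atoms named like dummy
    sites become ``dummy`` but remain members of their probe molecule;
    everything else is ``protein``.  Idempotent.
    """
    probe = set(probe_resnames)
    solvent = set(solvent_resnames)
    ions = set(ion_resnames)
    if not probe:
        raise TopologyError("no cosolvent defined: probe residue-name set is empty")
    if probe & solvent or probe & ions or solvent & ions:
        raise TopologyError(
            "probe, solvent and ion residue-name sets must be disjoint"
        )

    topology.probe_molecules = []
    for res in topology.residues:
        if res.name in probe:
            mol: list[int] = []
            for i in res.atom_ids:
                atom = topology.atoms[i]
                atom.role = Role.DUMMY if atom.name in DUMMY_ATOM_NAMES else Role.PROBE
                mol.append(i)
            topology.probe_molecules.append(mol)
        elif res.name in solvent:
            for i in res.atom_ids:
                topology.atoms[i].role = Role.SOLVENT
        elif res.name in ions:
            for i in res.atom_ids:
                topology.atoms[i].role = Role.ION
        else:
            for i in res.atom_ids:
                atom = topology.atoms[i]
                atom.role = Role.DUMMY if atom.name in DUMMY_ATOM_NAMES else Role.PROTEIN
    return topology


# ---------------------------------------------------------------------------
# PDB writing (local fixed-column writer)
# ---------------------------------------------------------------------------


def _fmt_atom_name(name: str) -> str:
    # standard PDB convention: names shorter than 4 chars start in column 14
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def _pdb_atom_line(
    record: str,
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resid: int,
    xyz: np.ndarray,
    occupancy: float,
    bfactor: float,
    element: str,
) -> str:
    return (
        f"{record:<6s}{serial % 100000:5d} {_fmt_atom_name(name)} {resname:>3.3s} "
        f"{chain[:1]}{resid % 10000:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occupancy:6.2f}{bfactor:6.2f}"
        f"          {element[:2]:>2s}\n"
    )


def write_pdb(
    topology: Topology, frames: Frame | Iterable[Frame], path: str | Path
) -> None:
    """Write a (possibly multi-model) PDB file for a topology."""
    if isinstance(frames, Frame):
        frames = [frames]
    frames = list(frames)
    if not frames:
        raise StructureParseError("no frames to write")
    with open(path, "w") as fh:
        if frames[0].box is not None:
            b = frames[0].box
            fh.write(
                f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}"
                f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
        multi = len(frames) > 1
        for m, frame in enumerate(frames, start=1):
            if frame.coordinates.shape[0] != topology.n_atoms:
                raise TopologyError("frame atom count does not match topology")
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            for i, atom in enumerate(topology.atoms):
                record = "ATOM" if atom.role is Role.PROTEIN else "HETATM"
                fh.write(
                    _pdb_atom_line(
                        record,
                        atom.serial,
                        atom.name,
                        atom.residue_name,
                        atom.chain_id,
                        atom.residue_index,
                        frame.coordinates[i],
                        1.0,
                        0.0,
                        atom.element,
                    )
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def _clamp_bfactor(value: float) -> float:
    if value < BFACTOR_MIN or value > BFACTOR_MAX:
        log.warning(
            "score %.4f outside PDB B-factor range, clamped to [%s, %s]",
            value,
            BFACTOR_MIN,
            BFACTOR_MAX,
        )
        return min(max(value, BFACTOR_MIN), BFACTOR_MAX)
    return value


def write_hotspot_pdb(residue_scores, regions, path: str | Path) -> None:
    """Write the viewer-facing hotspot PDB.

    One dummy HETATM per residue center (resname CAT, chain R, B-factor =
    the composite residue score) followed by one per ranked region center
    (resname REG, chain C, residue number = rank, B-factor = the region
    score).  Scores are clamped to the B-factor field range and written
    with two decimals.
    """
    with open(path, "w") as fh:
        serial = 0
        for score in residue_scores:
            serial += 1
            fh.write(
                _pdb_atom_line(
                    "HETATM",
                    serial,
                    "DU",
                    "CAT",
                    "R",
                    score.residue_index,
                    np.asarray(score.center, dtype=float),
                    1.0,
                    _clamp_bfactor(score.s_residue),
                    "X",
                )
            )
        for region in regions:
            serial += 1
            fh.write(
                _pdb_atom_line(
                    "HETATM",
                    serial,
                    "DU",
                    "REG",
                    "C",
                    region.rank,
                    np.asarray(region.scan_center, dtype=float),
                    1.0,
                    _clamp_bfactor(region.s_region),
                    "X",
                )
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------

_RESIDUE_HEADER = "residue_index\tresidue_name\ts_interaction\ts_stability\ts_depth\ts_residue"
_REGION_HEADER = "rank\tmembers\ts_region"


def write_score_table(residue_scores, regions, path: str | Path) -> None:
    """Write residue scores and ranked regions as tab-separated text.

    Values are written at full floating precision (repr round-trip);
    region members are joined with ``+``.
    """
    with open(path, "w") as fh:
        fh.write(_RESIDUE_HEADER + "\n")
        for s in residue_scores:
            fh.write(
                f"{s.residue_index}\t{s.residue_name}\t{s.s_interaction!r}\t"
                f"{s.s_stability!r}\t{s.s_depth!r}\t{s.s_residue!r}\n"
            )
        fh.write("\n" + _REGION_HEADER + "\n")
        for r in regions:
            members = "+".join(str(m) for m in sorted(r.member_residues))
            fh.write(f"{r.rank}\t{members}\t{r.s_region!r}\n")


def read_score_table(path: str | Path):
    """Parse a table written by :func:`write_score_table`.

    Returns ``(residue_rows, region_rows)`` where residue rows are
    ``(index, name, s_int, s_stab, s_depth, s_residue)`` tuples and region
    rows are ``(rank, member_id_set, s_region)``.
    """
    residues = []
    regions = []
    section = None
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line == _RESIDUE_HEADER:
                section = "residues"
                continue
            if line == _REGION_HEADER:
                section = "regions"
                continue
            fields = line.split("\t")
            if section == "residues":
                residues.append(
                    (
                        int(fields[0]),
                        fields[1],
                        float(fields[2]),
                        float(fields[3]),
                        float(fields[4]),
                        float(fields[5]),
                    )
                )
            elif section == "regions":
                members = frozenset(int(m) for m in fields[1].split("+"))
                regions.append((int(fields[0]), members, float(fields[2])))
            else:
                raise StructureParseError(f"unrecognized score-table line: {line!r}")
    return residues, regions
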