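"""Centers of geometry, minimum-image distances and neighbor queries.

All sphere-membership tests use *strict* inequality at the boundary (a
measure-zero tie, fixed for reproducibility).  Periodic wrapping under an
orthorhombic box is applied whenever the frame carries one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError
from .io_structures import Frame, Topology


@dataclass
class SphereQueryConfig:
    """Radii of the two sphere queries of the scoring scheme.

    ``r_residue`` (8 A) spans roughly three solvation shells around a
    residue center; ``r_cluster`` (5 A) matches inter-CA distances across
    secondary-structure elements.
    """

    r_residue: float = 8.0
    r_cluster: float = 5.0

    def __post_init__(self) -> None:
        if self.r_residue <= 0 or self.r_cluster <= 0:
            raise GeometryError("sphere radii must be positive")


def center_of_geometry(atom_ids, frame: Frame) -> np.ndarray:
    """Unweighted mean coordinate of the given atoms."""
    ids = np.asarray(sorted(atom_ids) if isinstance(atom_ids, (set, frozenset)) else atom_ids, dtype=int)
    if ids.size == 0:
        raise GeometryError("center of geometry of an empty atom set")
    return frame.coordinates[ids].mean(axis=0)


def min_image_delta(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Displacement a-b wrapped into [-L/2, L/2] per component (broadcasts)."""
    delta = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if box is not None:
        delta -= box * np.round(delta / box)
    return delta


def minimum_image_distance(a, b, box=None) -> float:
    """Euclidean distance under the minimum-image convention."""
    if box is not None:
        box = np.asarray(box, dtype=float)
        if not np.all(box > 0):
            raise GeometryError("box lengths must be positive")
    return float(np.linalg.norm(min_image_delta(a, b, box)))


def min_image_distance_matrix(
    a: np.ndarray, b: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """Pairwise minimum-image distances between two coordinate sets."""
    delta = min_image_delta(a[:, None, :], b[None, :, :], box)
    return np.sqrt((delta**2).sum(axis=-1))


def _wrap_points(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    wrapped = np.mod(coords, box)
    # guard against float round-up to exactly L, which cKDTree rejects
    wrapped = np.where(wrapped >= box, wrapped - box, wrapped)
    return wrapped


@dataclass
class NeighborIndex:
    """KD-tree over a subset of frame atoms, periodic when a box is present."""

    frame: Frame
    atom_ids: np.ndarray
    cutoff: float
    tree: cKDTree

    @property
    def box(self) -> np.ndarray | None:
        return self.frame.box


def build_neighbor_index(frame: Frame, atom_ids, cutoff: float) -> NeighborIndex:
    """Index atoms for within-cutoff queries.

    In periodic mode the cutoff must not exceed half the smallest box
    length, the validity limit of the minimum-image convention.
    """
    if cutoff <= 0:
        raise GeometryError("cutoff must be positive")
    ids = np.asarray(sorted(atom_ids) if isinstance(atom_ids, (set, frozenset)) else atom_ids, dtype=int)
    coords = frame.coordinates[ids]
    if frame.box is not None:
        if cutoff > float(frame.box.min()) / 2:
            raise GeometryError(
                f"cutoff {cutoff} exceeds half the smallest box length "
                f"({frame.box.min() / 2:.3f}): minimum image invalid"
            )
        tree = cKDTree(_wrap_points(coords, frame.box), boxsize=frame.box)
    else:
        tree = cKDTree(np.atleast_2d(coords))
    return NeighborIndex(frame=frame, atom_ids=ids, cutoff=float(cutoff), tree=tree)


def atoms_within(center, radius: float, index: NeighborIndex) -> set[int]:
    """Atom ids strictly within *radius* of *center* (minimum image)."""
    if radius > index.cutoff:
        raise GeometryError(f"query radius {radius} exceeds index cutoff {index.cutoff}")
    center = np.asarray(center, dtype=float)
    if index.box is not None:
        query_pt = _wrap_points(center, index.box)[0]
    else:
        query_pt = center
    candidates = index.tree.query_ball_point(query_pt, radius)
    out = set()
    for local in candidates:
        atom_id = int(index.atom_ids[local])
        d = minimum_image_distance(
            index.frame.coordinates[atom_id], center, index.box
        )
        if d < radius:
            out.add(atom_id)
    return out


def probe_centers(topology: Topology, frame: Frame) -> np.ndarray:
    """Dummy-excluded center of geometry of every probe molecule, (n, 3)."""
    groups = topology.probe_molecule_nondummy()
    if not groups:
        return np.zeros((0, 3))
    return np.stack([frame.coordinates[ids].mean(axis=0) for ids in groups])


def probes_within(center, radius: float, frame: Frame, topology: Topology) -> set[int]:
    """Probe-molecule ids whose (dummy-excluded) COG lies strictly within radius."""
    centers = probe_centers(topology, frame)
    if centers.shape[0] == 0:
        return set()
    d = np.linalg.norm(min_image_delta(centers, np.asarray(center, float), frame.box), axis=1)
    return set(np.nonzero(d < radius)[0].astype(int).tolist())
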