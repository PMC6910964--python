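"""Region clustering and ranking of residue hotspot scores.

One dummy point per protein residue (at its trajectory-average center of
geometry, carrying the composite residue score) is swept by clustering
spheres of radius ``r_cluster`` placed along the protein backbone; each
sphere averages the scores of the residue points it captures into a
region score, overlapping candidates are suppressed greedily, and the
surviving regions are ranked most-negative-first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import ScoringError
from .io_structures import Frame, Topology
from .scoring import ResidueScore

log = logging.getLogger(__name__)

_BACKBONE_NAMES = ("N", "CA", "C", "O")


class DummyAtom(NamedTuple):
    position: np.ndarray
    s_residue: float
    residue_index: int


@dataclass
class RegionCluster:
    scan_center: np.ndarray
    member_residues: frozenset[int]  # 1-based residue indices
    s_region: float
    rank: int | None = None


def make_dummy_atoms(residue_scores: Sequence[ResidueScore]) -> list[DummyAtom]:
    """One dummy point per residue at its stored center, carrying s_residue.

    Residues with non-negative scores still produce a point; they are
    filtered at the region level, not here.
    """
    return [
        DummyAtom(np.asarray(s.center, dtype=float), float(s.s_residue), s.residue_index)
        for s in residue_scores
    ]


def backbone_scan_points(topology: Topology, frames: Iterable[Frame]) -> np.ndarray:
    """Trajectory-average CA position per protein residue.

    Residues lacking a CA fall back to the COG of their backbone atoms,
    or of all their atoms if none of N/CA/C/O are present.  Distances here
    are plain Euclidean: scan geometry assumes a whole (unwrapped) protein.
    """
    residues = topology.protein_residues()
    if not residues:
        raise ScoringError("empty protein: no residues to scan")
    picks: list[np.ndarray] = []
    for res in residues:
        names = {topology.atoms[i].name: i for i in res.atom_ids}
        if "CA" in names:
            ids = [names["CA"]]
        else:
            ids = [names[n] for n in _BACKBONE_NAMES if n in names] or list(res.atom_ids)
        picks.append(np.asarray(ids, dtype=int))
    total = None
    n = 0
    for frame in frames:
        pts = np.stack([frame.coordinates[ids].mean(axis=0) for ids in picks])
        total = pts if total is None else total + pts
        n += 1
    if n == 0:
        raise ScoringError("no frames to scan")
    return total / n


def scan_regions(
    dummies: Sequence[DummyAtom],
    scan_points: Sequence[np.ndarray] | np.ndarray,
    r_cluster: float = 5.0,
) -> list[RegionCluster]:
    """Candidate regions: one clustering sphere per scan point.

    A sphere's members are all residue points strictly within
    ``r_cluster``; a candidate is emitted only if at least one member has
    a negative residue score (regions of pure background are dropped).
    The region score is the plain mean of all member residue scores.
    """
    if r_cluster <= 0:
        raise ScoringError("r_cluster must be positive")
    candidates: list[RegionCluster] = []
    if not dummies:
        return candidates
    positions = np.stack([d.position for d in dummies])
    scores = np.array([d.s_residue for d in dummies])
    indices = np.array([d.residue_index for d in dummies])
    for point in np.atleast_2d(np.asarray(scan_points, dtype=float)):
        dist = np.linalg.norm(positions - point, axis=1)
        inside = dist < r_cluster
        if not inside.any() or not (scores[inside] < 0).any():
            continue
        candidates.append(
            RegionCluster(
                scan_center=point.copy(),
                member_residues=frozenset(int(i) for i in indices[inside]),
                s_region=float(scores[inside].mean()),
            )
        )
    return candidates


def _sort_key(region: RegionCluster) -> tuple[float, int]:
    return (region.s_region, min(region.member_residues))


def deduplicate_regions(
    candidates: Sequence[RegionCluster], overlap_threshold: float = 0.5
) -> list[RegionCluster]:
    """Greedy non-maximum suppression on member-set Jaccard overlap.

    Candidates are visited by ascending region score (ties by smallest
    member residue index), so the output is independent of input order; a
    candidate survives only if its Jaccard overlap with every already
    accepted region is at most *overlap_threshold*.
    """
    if not 0 <= overlap_threshold <= 1:
        raise ScoringError("overlap threshold must lie in [0, 1]")
    accepted: list[RegionCluster] = []
    for cand in sorted(candidates, key=_sort_key):
        ok = True
        for reg in accepted:
            inter = len(cand.member_residues & reg.member_residues)
            union = len(cand.member_residues | reg.member_residues)
            if union and inter / union > overlap_threshold:
                ok = False
                break
        if ok:
            accepted.append(cand)
    return accepted


def rank_regions(regions: Sequence[RegionCluster]) -> list[RegionCluster]:
    """Sort ascending by region score (most favorable first), assign ranks 1..K."""
    ordered = sorted(regions, key=_sort_key)
    return [replace(r, rank=i) for i, r in enumerate(ordered, start=1)]


def cluster_and_rank(
    residue_scores: Sequence[ResidueScore],
    scan_points: np.ndarray,
    r_cluster: float = 5.0,
    overlap_threshold: float = 0.5,
) -> list[RegionCluster]:
    """Full region pipeline: dummies -> scan -> dedup -> rank."""
    dummies = make_dummy_atoms(residue_scores)
    candidates = scan_regions(dummies, scan_points, r_cluster)
    unique = deduplicate_regions(candidates, overlap_threshold)
    ranked = rank_regions(unique)
    log.info(
        "regions: %d candidates -> %d after deduplication", len(candidates), len(ranked)
    )
    return ranked
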