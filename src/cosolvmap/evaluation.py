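"""Binding-site recovery: which ranked regions touch known site residues.

A region "hits" a site when its member residues intersect the site's
residue set (identity overlap, single-residue overlap accepted); the
report lists all hitting ranks up to ``top_k`` per site.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .clustering import RegionCluster
from .errors import SitesError
from .io_structures import Topology

log = logging.getLogger(__name__)


@dataclass
class KnownSite:
    name: str
    residues: frozenset[int]
    note: str = ""

    def __post_init__(self) -> None:
        self.residues = frozenset(int(r) for r in self.residues)
        if not self.residues:
            raise SitesError(f"site {self.name!r} has no residues")


@dataclass
class SiteRecovery:
    site: KnownSite
    hits: list[tuple[int, frozenset[int]]] = field(default_factory=list)

    @property
    def found(self) -> bool:
        return bool(self.hits)

    @property
    def best_rank(self) -> int | None:
        return min((rank for rank, _ in self.hits), default=None)


@dataclass
class RecoveryReport:
    sites: list[SiteRecovery]
    top_k: int


def read_sites(path: str | Path) -> list[KnownSite]:
    """Parse a sites file: one ``name: resid,resid,...`` line per site."""
    sites: list[KnownSite] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise SitesError(f"{path}:{lineno}: expected 'name: id,id,...'")
            name, rest = line.split(":", 1)
            try:
                residues = frozenset(int(tok) for tok in rest.replace(",", " ").split())
            except ValueError:
                raise SitesError(f"{path}:{lineno}: non-integer residue id") from None
            sites.append(KnownSite(name=name.strip(), residues=residues))
    return sites


def evaluate_site_recovery(
    ranked_regions: Sequence[RegionCluster],
    sites: Sequence[KnownSite],
    topology: Topology | None = None,
    top_k: int = 10,
) -> RecoveryReport:
    """Report, per site, every region of rank <= top_k overlapping it."""
    if top_k < 1:
        raise SitesError("top_k must be at least 1")
    if topology is not None:
        known = {r.index for r in topology.residues}
        for site in sites:
            missing = sorted(site.residues - known)
            if missing:
                raise SitesError(
                    f"site {site.name!r} names residues absent from the topology: {missing}"
                )
    report = RecoveryReport(sites=[], top_k=top_k)
    for site in sites:
        rec = SiteRecovery(site=site)
        for region in ranked_regions:
            if region.rank is None or region.rank > top_k:
                continue
            overlap = region.member_residues & site.residues
            if overlap:
                rec.hits.append((region.rank, frozenset(overlap)))
        rec.hits.sort(key=lambda h: h[0])
        report.sites.append(rec)
        log.info(
            "site %s: %s",
            site.name,
            f"hit at ranks {[r for r, _ in rec.hits]}" if rec.found else "not found",
        )
    return report


def write_recovery_csv(report: RecoveryReport, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["site", "found", "best_rank", "hit_ranks", "overlap_residues"])
        for rec in report.sites:
            writer.writerow(
                [
                    rec.site.name,
                    rec.found,
                    rec.best_rank if rec.best_rank is not None else "",
                    ";".join(str(r) for r, _ in rec.hits),
                    ";".join(
                        "+".join(str(i) for i in sorted(ov)) for _, ov in rec.hits
                    ),
                ]
            )
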