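"""Overlap-aware palynomorph census.

Because neighbouring SEM tiles share an overlap strip, one specimen can
be detected in up to four images.  Detections are mapped into the
montage-global frame and merged by single-linkage clustering within a
distance tolerance; each cluster is one unique specimen.  The census
then reports per-taxon counts, relative abundance among identifiable
specimens, and areal density (specimens per cm**2), plus the
linear extrapolation used to estimate specimens overlooked by the whole
pipeline from a full audit of a subset of images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .cohort import INDETERMINABLE, Specimen
from .geometry import Point, TileGrid, TileIndex, local_to_global

__all__ = [
    "Detection",
    "SpecimenCluster",
    "CensusRow",
    "CensusTable",
    "PerformanceReport",
    "deduplicate_detections",
    "census_table",
    "estimate_overlooked",
    "detection_performance",
]


@dataclass(frozen=True)
class Detection:
    """One confirmed specimen occurrence in one image."""

    image_id: str
    montage: int
    tile: TileIndex
    local: Point
    label: str  # taxon label or "indeterminable"
    source: str = "expert"  # "volunteer_verified" | "expert"


@dataclass(frozen=True)
class SpecimenCluster:
    """A unique specimen: one single-linkage cluster of detections."""

    cluster_id: int
    montage: int
    centroid: Point  # montage-global
    label: str
    members: tuple[Detection, ...]

    @property
    def identifiable(self) -> bool:
        return self.label != INDETERMINABLE


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _majority_label(labels: Sequence[str]) -> str:
    counts: dict[str, int] = {}
    for l in labels:
        counts[l] = counts.get(l, 0) + 1
    best = max(counts.values())
    winners = [l for l, c in counts.items() if c == best]
    return winners[0] if len(winners) == 1 else INDETERMINABLE


def deduplicate_detections(
    detections: Sequence[Detection],
    grids: Sequence[TileGrid],
    epsilon_um: float = 10.0,
) -> list[SpecimenCluster]:
    """Merge duplicate detections of the same specimen across tiles.

    Detections are mapped to montage-global coordinates and clustered
    by single linkage: any two detections within ``epsilon_um`` join
    the same cluster, and chains merge transitively.  Detections from
    different montages are never merged.  A cluster's taxon is the
    majority label of its members; ties are indeterminable.
    """
    if epsilon_um < 0:
        raise ValueError("epsilon_um must be non-negative")
    clusters: list[SpecimenCluster] = []
    cid = 0
    by_montage: dict[int, list[Detection]] = {}
    for d in detections:
        by_montage.setdefault(d.montage, []).append(d)
    for mi in sorted(by_montage):
        dets = by_montage[mi]
        pts = np.array(
            [local_to_global(grids[mi], d.tile, d.local) for d in dets], dtype=float
        )
        uf = _UnionFind(len(dets))
        tree = cKDTree(pts)
        for i, j in tree.query_pairs(epsilon_um):
            uf.union(i, j)
        groups: dict[int, list[int]] = {}
        for i in range(len(dets)):
            groups.setdefault(uf.find(i), []).append(i)
        for root in sorted(groups):
            idx = groups[root]
            centroid = pts[idx].mean(axis=0)
            clusters.append(
                SpecimenCluster(
                    cluster_id=cid,
                    montage=mi,
                    centroid=Point(float(centroid[0]), float(centroid[1])),
                    label=_majority_label([dets[i].label for i in idx]),
                    members=tuple(dets[i] for i in idx),
                )
            )
            cid += 1
    return clusters


@dataclass(frozen=True)
class CensusRow:
    taxon: str
    count: int
    percent_of_identifiable: int  # reported as integer percent
    density_per_cm2: float  # reported to 1 decimal
    percent_exact: float
    density_exact: float


@dataclass(frozen=True)
class CensusTable:
    """Final specimen census over the surveyed area."""

    rows: tuple[CensusRow, ...]
    n_unique: int
    n_identifiable: int
    n_indeterminable: int
    total_area_cm2: float

    def as_records(self) -> list[dict]:
        return [
            {
                "taxon": r.taxon,
                "count": r.count,
                "percent_of_identifiable": r.percent_of_identifiable,
                "density_per_cm2": r.density_per_cm2,
            }
            for r in self.rows
        ]

    def row(self, taxon: str) -> CensusRow:
        for r in self.rows:
            if r.taxon == taxon:
                return r
        raise KeyError(taxon)


def census_table(
    clusters: Iterable[SpecimenCluster] | Mapping[str, int],
    total_area_cm2: float,
) -> CensusTable:
    """Per-taxon counts, relative abundance and density.

    ``clusters`` may be deduplicated clusters or a ready-made mapping of
    taxon label to unique-specimen count (``indeterminable`` allowed).
    Percentages use identifiable specimens as the base and are reported
    as integers; densities are count / area to 1 decimal.  Exact values
    are carried alongside so counts always reconcile before rounding.
    """
    if total_area_cm2 <= 0:
        raise ValueError("total_area_cm2 must be positive")
    if isinstance(clusters, Mapping):
        counts = dict(clusters)
    else:
        counts = {}
        for c in clusters:
            counts[c.label] = counts.get(c.label, 0) + 1
    n_indet = counts.pop(INDETERMINABLE, 0)
    n_ident = sum(counts.values())
    rows = []
    for taxon in sorted(counts, key=lambda t: (-counts[t], t)):
        n = counts[taxon]
        pct = 100.0 * n / n_ident if n_ident else 0.0
        dens = n / total_area_cm2
        rows.append(CensusRow(taxon, n, round(pct), round(dens, 1), pct, dens))
    return CensusTable(
        rows=tuple(rows),
        n_unique=n_ident + n_indet,
        n_identifiable=n_ident,
        n_indeterminable=n_indet,
        total_area_cm2=total_area_cm2,
    )


def estimate_overlooked(
    missed_in_audit: int, audit_n_images: int, total_n_images: int
) -> tuple[float, float]:
    """Extrapolate specimens missed by the whole pipeline from a full
    audit of a subset of images: (estimate, binomial standard error).

    estimate = missed * total / audit; the standard error scales the
    binomial SE of the per-image miss rate to the full dataset.
    """
    if audit_n_images <= 0:
        raise ValueError("audit_n_images must be positive")
    if missed_in_audit < 0 or missed_in_audit > audit_n_images:
        raise ValueError("missed_in_audit must be within the audit size")
    p = missed_in_audit / audit_n_images
    estimate = p * total_n_images
    se = total_n_images * math.sqrt(p * (1.0 - p) / audit_n_images)
    return estimate, se


@dataclass(frozen=True)
class PerformanceReport:
    recall: float
    n_truth: int
    n_matched: int
    missed_specimen_ids: tuple[str, ...]
    n_false_clusters: int


def detection_performance(
    ground_truth: Sequence[Specimen],
    clusters: Sequence[SpecimenCluster],
    epsilon_um: float = 10.0,
) -> PerformanceReport:
    """Audit the census against the generated specimen field.

    Each ground-truth specimen is matched (one-to-one, nearest first)
    to a cluster on the same montage within ``epsilon_um``.  Recall is
    matched / truth; unmatched clusters are false specimens.
    """
    matched_truth: set[str] = set()
    matched_clusters: set[int] = set()
    pairs: list[tuple[float, str, int]] = []
    by_montage: dict[int, list[SpecimenCluster]] = {}
    for c in clusters:
        by_montage.setdefault(c.montage, []).append(c)
    for mi, cs in by_montage.items():
        pts = np.array([c.centroid for c in cs], dtype=float)
        tree = cKDTree(pts)
        for sp in ground_truth:
            if sp.montage != mi:
                continue
            for j in tree.query_ball_point(np.asarray(sp.position, dtype=float), epsilon_um):
                d = math.dist(sp.position, cs[j].centroid)
                pairs.append((d, sp.specimen_id, cs[j].cluster_id))
    for d, sid, cid in sorted(pairs):
        if sid in matched_truth or cid in matched_clusters:
            continue
        matched_truth.add(sid)
        matched_clusters.add(cid)
    n_truth = len(ground_truth)
    missed = tuple(sorted(s.specimen_id for s in ground_truth if s.specimen_id not in matched_truth))
    return PerformanceReport(
        recall=len(matched_truth) / n_truth if n_truth else 1.0,
        n_truth=n_truth,
        n_matched=len(matched_truth),
        missed_specimen_ids=missed,
        n_false_clusters=len(clusters) - len(matched_clusters),
    )
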