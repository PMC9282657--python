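"""Populated target-zone assembly: the heart of the polygon-binary method.

For every populated source zone the method picks the sub-region believed to
hold its residents, through a four-step cascade:

  A. small residential parcels (whole boundaries) inside the zone;
  B. plus building footprints inside *large* residential parcels — a zone is
     tagged B as soon as any building-in-large-parcel geometry contributes;
  C. if the zone has no residential parcel area at all: every building in
     the zone;
  D. if there are neither parcels nor buildings: the whole zone.

Intersecting parcels with zone boundaries leaves slivers.  A single-part
piece descended from a parcel is removed when its area falls below

    original parcel area / (2 * number of descendant pieces of that parcel)

counted across the whole zone collection.  A zone whose resulting target
is implausibly dense (over a cap of 1 person per 10 m2 by default) first
gets its removed slivers back and, failing that, falls back to the whole
zone; both actions are recorded in the audit.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .geodata_io import BuildingFeature, ParcelFeature, SourceZone
from .parcel_classify import LARGE, SMALL, ClassifierConfig, size_class

log = logging.getLogger(__name__)

__all__ = [
    "DescendantPolygon",
    "TargetZone",
    "DasymetricConfig",
    "sliver_threshold",
    "intersect_zones_parcels",
    "remove_slivers",
    "partition_slivers",
    "select_buildings",
    "assemble_target_zones",
    "apply_density_cap",
    "audit_frame",
]

STEP_A, STEP_B, STEP_C, STEP_D = "A", "B", "C", "D"

_MIN_AREA = 1e-9  # m2; discards degenerate line/point intersection residue


@dataclass(frozen=True)
class DasymetricConfig:
    """Thresholds of the assembly stage.

    density_cap is in people per m2; the default 0.1 is the "1 person per
    10 m2" ceiling used to catch zones whose target collapsed to slivers.
    The cap is evaluated on ``total_variable`` when present, else on the sum
    of the zone's population vector.
    """

    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    density_cap: float = 0.1
    total_variable: str = "TOTAL"

    def __post_init__(self) -> None:
        if self.density_cap <= 0:
            raise ValueError("density_cap must be positive")


@dataclass
class DescendantPolygon:
    """Single-part piece of a parcel after intersection with the zones."""

    parent_parcel_id: str
    parent_zone_id: str
    geometry: BaseGeometry
    parent_parcel_area_m2: float
    n_siblings: int = 1

    @property
    def area_m2(self) -> float:
        return self.geometry.area


@dataclass
class TargetZone:
    """Populated sub-region of one source zone, tagged with its assembly step."""

    zone_id: str
    geometry: BaseGeometry
    step: str
    density: dict[str, float] = field(default_factory=dict)

    @property
    def area_m2(self) -> float:
        return self.geometry.area


def sliver_threshold(original_parcel_area_m2: float, n_descendants: int) -> float:
    """Area below which a descendant piece counts as a sliver."""
    if original_parcel_area_m2 <= 0:
        raise ValueError("parcel area must be positive")
    if n_descendants < 1:
        raise ValueError("a parcel with descendants has at least one")
    return original_parcel_area_m2 / (2 * n_descendants)


def _single_parts(geom: BaseGeometry) -> list[BaseGeometry]:
    if geom.is_empty:
        return []
    if geom.geom_type == "Polygon":
        return [geom]
    if geom.geom_type in ("MultiPolygon", "GeometryCollection"):
        out = []
        for g in geom.geoms:
            out.extend(_single_parts(g))
        return out
    return []  # lines/points from edge-touching intersections


def intersect_zones_parcels(
    zones: Sequence[SourceZone], parcels: Sequence[ParcelFeature]
) -> list[DescendantPolygon]:
    """Explode the zone x parcel overlay into tagged single-part descendants.

    ``n_siblings`` counts a parcel's pieces across the *whole* collection —
    the denominator of the sliver threshold — not per zone.  Degenerate
    (zero-area) intersection residue is discarded before counting.
    """
    if not zones or not parcels:
        return []
    parcel_geoms = [p.geometry for p in parcels]
    tree = STRtree(parcel_geoms)
    descendants: list[DescendantPolygon] = []
    per_parcel_count: dict[str, int] = {}
    for zone in zones:
        idx = tree.query(zone.geometry, predicate="intersects")
        if idx.size == 0:
            continue
        idx = np.sort(idx)  # deterministic order
        pieces = shapely.intersection(np.asarray(parcel_geoms, dtype=object)[idx], zone.geometry)
        for i, piece in zip(idx, pieces):
            parcel = parcels[int(i)]
            for part in _single_parts(piece):
                if part.area <= _MIN_AREA:
                    continue
                descendants.append(
                    DescendantPolygon(
                        parent_parcel_id=parcel.parcel_id,
                        parent_zone_id=zone.zone_id,
                        geometry=part,
                        parent_parcel_area_m2=parcel.area_m2,
                    )
                )
                per_parcel_count[parcel.parcel_id] = (
                    per_parcel_count.get(parcel.parcel_id, 0) + 1
                )
    for d in descendants:
        d.n_siblings = per_parcel_count[d.parent_parcel_id]
    return descendants


def partition_slivers(
    descendants: Iterable[DescendantPolygon],
) -> tuple[list[DescendantPolygon], list[DescendantPolygon]]:
    """Split descendants into (retained, removed-as-sliver).

    Removal is strict "less than" the threshold; a piece exactly at the
    threshold is retained.
    """
    retained, removed = [], []
    for d in descendants:
        if d.area_m2 < sliver_threshold(d.parent_parcel_area_m2, d.n_siblings):
            removed.append(d)
        else:
            retained.append(d)
    return retained, removed


def remove_slivers(descendants: Iterable[DescendantPolygon]) -> list[DescendantPolygon]:
    return partition_slivers(descendants)[0]


def select_buildings(
    buildings: Sequence[BuildingFeature], container: BaseGeometry
) -> list[BaseGeometry]:
    """Building geometries assigned to ``container``, clipped to it.

    Membership is by the building's representative interior point being
    strictly inside the container, so a footprint straddling adjacent
    containers is assigned to exactly one (or, on a measure-zero boundary
    tie, to neither).
    """
    out = []
    for b in buildings:
        if b.geometry.representative_point().within(container):
            geom = (
                b.geometry
                if container.covers(b.geometry)
                else b.geometry.intersection(container)
            )
            if geom.area > _MIN_AREA:
                out.append(geom)
    return out


def apply_density_cap(
    zone: SourceZone,
    target: TargetZone,
    removed_slivers: Sequence[DescendantPolygon],
    cfg: DasymetricConfig,
) -> tuple[TargetZone, str]:
    """Enforce the population-density ceiling on one assembled target.

    Returns (possibly rebuilt target, action) with action one of
    "none" / "slivers_restored" / "escalated_to_zone".  The cap is strict:
    density exactly at the cap passes.  Escalation restores the zone's own
    removed parcel slivers first; if the zone is still over the cap its
    target widens to the whole zone (step D), the terminal fallback.
    """
    pop_total = _total_population(zone, cfg)
    if pop_total <= 0 or target.area_m2 <= 0:
        return target, "none"
    if pop_total / target.area_m2 <= cfg.density_cap:
        return target, "none"
    if removed_slivers:
        geom = shapely.unary_union(
            [target.geometry] + [d.geometry for d in removed_slivers]
        )
        restored = TargetZone(zone.zone_id, geom, target.step)
        if restored.area_m2 > 0 and pop_total / restored.area_m2 <= cfg.density_cap:
            return restored, "slivers_restored"
        target = restored
    if target.geometry.equals(zone.geometry):
        return target, "none"
    return TargetZone(zone.zone_id, zone.geometry, STEP_D), "escalated_to_zone"


def _total_population(zone: SourceZone, cfg: DasymetricConfig) -> float:
    if cfg.total_variable in zone.pop:
        return zone.pop[cfg.total_variable]
    return sum(zone.pop.values())


def _union(geoms: list[BaseGeometry]) -> BaseGeometry:
    # Overlapping parcels are unioned per zone so duplicated coverage never
    # double-weights area.
    if len(geoms) == 1:
        return geoms[0]
    return shapely.unary_union(geoms)


def assemble_target_zones(
    zones: Sequence[SourceZone],
    parcels: Sequence[ParcelFeature],
    buildings: Sequence[BuildingFeature],
    cfg: DasymetricConfig | None = None,
) -> tuple[list[TargetZone], list[dict]]:
    """Run steps A-D for every populated zone.

    Returns (targets, audit rows).  Zones whose population vector is all
    zero emit nothing — their pixels will simply be 0.  The whole procedure
    is deterministic: no randomness, stable iteration order.
    """
    cfg = cfg or DasymetricConfig()
    small_parcels, large_parcels = [], []
    for p in parcels:
        cls = size_class(p, cfg.classifier)
        if cls == SMALL:
            small_parcels.append(p)
        elif cls == LARGE:
            large_parcels.append(p)

    small_desc = intersect_zones_parcels(zones, small_parcels)
    large_desc = intersect_zones_parcels(zones, large_parcels)
    small_keep, small_drop = partition_slivers(small_desc)
    large_keep, _large_drop = partition_slivers(large_desc)

    by_zone_small: dict[str, list[DescendantPolygon]] = {}
    for d in small_keep:
        by_zone_small.setdefault(d.parent_zone_id, []).append(d)
    by_zone_small_drop: dict[str, list[DescendantPolygon]] = {}
    for d in small_drop:
        by_zone_small_drop.setdefault(d.parent_zone_id, []).append(d)
    by_zone_large: dict[str, list[DescendantPolygon]] = {}
    for d in large_keep:
        by_zone_large.setdefault(d.parent_zone_id, []).append(d)
    pre_counts: dict[str, int] = {}
    for d in small_desc + large_desc:
        pre_counts[d.parent_zone_id] = pre_counts.get(d.parent_zone_id, 0) + 1

    # Building membership via an index over representative points: a point
    # query per container replaces a polygon-polygon scan.
    bld_geoms = [b.geometry for b in buildings]
    bld_points = [g.representative_point() for g in bld_geoms]
    bld_tree = STRtree(bld_points) if buildings else None

    def buildings_in(container: BaseGeometry) -> list[BaseGeometry]:
        if bld_tree is None:
            return []
        idx = np.sort(bld_tree.query(container, predicate="contains"))
        out = []
        for i in idx:
            g = bld_geoms[int(i)]
            if not container.covers(g):
                g = g.intersection(container)
            if g.area > _MIN_AREA:
                out.append(g)
        return out

    targets: list[TargetZone] = []
    audit: list[dict] = []
    for zone in zones:
        if not zone.pop or all(v <= 0 for v in zone.pop.values()):
            continue
        zid = zone.zone_id
        small_geoms = [d.geometry for d in by_zone_small.get(zid, [])]
        large_here = by_zone_large.get(zid, [])
        has_res = bool(small_geoms or large_here)

        step = None
        geom = None
        if has_res:
            bldg_geoms: list[BaseGeometry] = []
            for d in large_here:
                bldg_geoms.extend(buildings_in(d.geometry))
            pieces = small_geoms + bldg_geoms
            if pieces:
                geom = _union(pieces)
                step = STEP_B if bldg_geoms else STEP_A
        if geom is None or geom.area <= _MIN_AREA:
            pieces = buildings_in(zone.geometry)
            if pieces:
                geom = _union(pieces)
                step = STEP_C
        if geom is None or geom.area <= _MIN_AREA:
            geom = zone.geometry
            step = STEP_D

        target = TargetZone(zid, geom, step)
        target, cap_action = apply_density_cap(
            zone, target, by_zone_small_drop.get(zid, []), cfg
        )
        targets.append(target)
        audit.append(
            {
                "zone_id": zid,
                "step": target.step,
                "target_area_m2": target.area_m2,
                "n_descendants_pre": pre_counts.get(zid, 0),
                "n_descendants_post": len(small_geoms) + len(large_here),
                "cap_escalated": cap_action == "escalated_to_zone",
                "cap_action": cap_action,
            }
        )
    return targets, audit


def audit_frame(audit: list[dict]) -> pd.DataFrame:
    """Audit rows as a DataFrame, ready for CSV export."""
    cols = [
        "zone_id",
        "step",
        "target_area_m2",
        "n_descendants_pre",
        "n_descendants_post",
        "cap_escalated",
        "cap_action",
    ]
    return pd.DataFrame(audit, columns=cols)
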