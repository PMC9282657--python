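"""Seeded synthetic landscapes with known per-building ground truth.

The generator emulates the inputs of the real product — nested enumeration
zones at a ~1:20 fine-to-coarse ratio, a parcel mosaic of small single-family
lots, large rural-residential holdings, high-density apartment blocks and
non-residential land, and a building layer degraded by the detection error
rates of satellite-derived footprints (7.6% false negatives, 1.5% false
positives).  People live in buildings; zone tables are exact sums of the
per-building truth, so every pipeline stage can be scored against a known
answer without downloading anything.

Zones are recursive rectangular splits rather than Voronoi cells: areas and
nesting are then exact, and a single integer seed drives one RNG stream, so
identical parameters reproduce identical scenes on any platform.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box
from shapely.strtree import STRtree

from .geodata_io import (
    BuildingFeature,
    ParcelFeature,
    SourceZone,
    write_buildings,
    write_parcels,
    write_zones,
)

__all__ = ["SceneParams", "SceneTruth", "generate_scene", "aggregate_truth", "write_scene", "VARIABLES"]

#: Total population plus the eight demographic variables the tool grids.
VARIABLES = (
    "TOTAL",
    "HISP",
    "NHWHITE",
    "NHBLACK",
    "NHAMIND",
    "NHASIAN",
    "NHHIPI",
    "NHOTHERMULTI",
    "MINORS",
)
#: The seven mutually exclusive race/ethnicity groups that sum to TOTAL.
COMPOSITION_VARIABLES = VARIABLES[1:8]

_CLASS_LABELS = {
    "small": ("SINGLE FAMILY RESIDENTIAL", "CONDOMINIUM (RESIDENTIAL)"),
    "rural": ("RURAL RESIDENCE (AGRICULTURAL)",),
    "high_density": (
        "APARTMENT HOUSE (100+ UNITS)",
        "APARTMENT HOUSE (5+ UNITS)",
        "APARTMENTS (GENERIC)",
        "COOPERATIVE (RESIDENTIAL)",
        "HIGHRISE APARTMENTS",
    ),
    "nonres": ("GENERIC COMMERCIAL",),
}
_RESIDENTIAL_KINDS = ("small", "large_lot", "rural", "high_density")


@dataclass(frozen=True)
class SceneParams:
    """Knobs of the synthetic landscape.

    Defaults follow the conditions the method targets: fine zones average
    ~0.79 km2 (the statewide mean block area), coarse zones hold ~20 fine
    zones, footprint detection misses 7.6% of buildings and invents 1.5%,
    and settlement is clustered around a few town centers so that within a
    zone most land is empty — the situation dasymetric mapping exists for.
    """

    seed: int = 0
    n_coarse: int = 12
    fine_per_coarse: float = 20.0
    extent_m: float | None = None  # default: sized for ~0.79 km2 per fine zone
    class_mix: tuple[tuple[str, float], ...] = (
        ("small", 0.57),
        ("rural", 0.00),  # rural parcels are placed separately, outside towns
        ("high_density", 0.01),  # apartments mostly come as whole districts
        ("nonres", 0.12),
        ("open", 0.30),
    )
    people_per_building_mean: tuple[tuple[str, float], ...] = (
        ("small", 3.0),
        ("large_lot", 3.0),
        ("rural", 2.6),
        ("high_density", 45.0),
        ("nonres", 0.0),
        ("cabin", 2.2),
    )
    large_lot_prob: float = 0.03  # chance a town lot is an over-one-acre parcel
    exurb_prob: float = 0.15  # chance a settled zone is all multi-acre lots
    hd_district_prob: float = 0.08  # chance a settled zone is an apartment district
    rural_per_coarse: float = 1.2  # mean count of ~18-acre holdings per coarse zone
    cabin_per_coarse: float = 2.0  # building clusters outside any parcel
    detection_fn_rate: float = 0.076
    detection_fp_rate: float = 0.015
    dirichlet_alpha: tuple[float, ...] = (4.0, 3.5, 0.5, 0.2, 1.6, 0.1, 1.1)
    minors_share_beta: tuple[float, float] = (22.0, 78.0)
    town_count: int | None = None  # default max(2, n_coarse // 3)
    settlement_sigma_frac: float = 0.14
    crs: str = "EPSG:3310"

    def __post_init__(self) -> None:
        mix = dict(self.class_mix)
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix proportions sum to {total}, not 1")
        if any(v < 0 for v in mix.values()):
            raise ValueError("class_mix proportions must be non-negative")
        res_mass = sum(mix.get(k, 0.0) for k in _RESIDENTIAL_KINDS)
        if res_mass <= 0 and self.rural_per_coarse <= 0:
            raise ValueError(
                "infeasible class_mix: no residential mass anywhere to settle"
            )
        for name, rate in (
            ("detection_fn_rate", self.detection_fn_rate),
            ("detection_fp_rate", self.detection_fp_rate),
        ):
            if not 0 <= rate < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if len(self.dirichlet_alpha) != len(COMPOSITION_VARIABLES):
            raise ValueError(
                f"dirichlet_alpha needs {len(COMPOSITION_VARIABLES)} entries"
            )


@dataclass
class SceneTruth:
    """A complete scene: layers, per-building truth, and exact aggregates."""

    params: SceneParams
    extent_m: float
    crs: str
    coarse_zones: list[SourceZone]
    fine_zones: list[SourceZone]
    parcels: list[ParcelFeature]
    true_buildings: list[BuildingFeature]
    detected_buildings: list[BuildingFeature]
    building_people: pd.DataFrame  # index building_id; VARIABLES + zone ids
    fine_table: pd.DataFrame  # index zone_id, columns VARIABLES
    coarse_table: pd.DataFrame

    @property
    def total_population(self) -> float:
        return float(self.fine_table["TOTAL"].sum())


def _split_rect(bounds, n, rng):
    """Recursively split a rectangle into n rectangles (largest-first)."""
    rects = [tuple(bounds)]
    while len(rects) < n:
        i = max(
            range(len(rects)),
            key=lambda k: (rects[k][2] - rects[k][0]) * (rects[k][3] - rects[k][1]),
        )
        x0, y0, x1, y1 = rects.pop(i)
        f = rng.uniform(0.35, 0.65)
        if (x1 - x0) >= (y1 - y0):
            xm = x0 + f * (x1 - x0)
            rects.extend([(x0, y0, xm, y1), (xm, y0, x1, y1)])
        else:
            ym = y0 + f * (y1 - y0)
            rects.extend([(x0, y0, x1, ym), (x0, ym, x1, y1)])
    return rects


def _rect_in(rng, bounds, w, h):
    """Random w x h sub-rectangle inside bounds (shrunk to fit if needed)."""
    x0, y0, x1, y1 = bounds
    w = min(w, x1 - x0)
    h = min(h, y1 - y0)
    px = rng.uniform(x0, x1 - w)
    py = rng.uniform(y0, y1 - h)
    return (px, py, px + w, py + h)


def generate_scene(params: SceneParams) -> SceneTruth:
    """Generate the full synthetic landscape for one seed."""
    rng = np.random.default_rng(params.seed)
    n_fine_target = params.n_coarse * params.fine_per_coarse
    extent = params.extent_m or float(np.sqrt(n_fine_target * 790_000.0))

    # --- nested zones -----------------------------------------------------
    coarse_rects = _split_rect((0.0, 0.0, extent, extent), params.n_coarse, rng)
    coarse_zones, fine_zones, fine_rects = [], [], []
    for ci, crect in enumerate(coarse_rects):
        cid = f"C{ci:04d}"
        coarse_zones.append(SourceZone(cid, box(*crect)))
        n_fine = max(1, int(rng.poisson(params.fine_per_coarse)))
        for fi, frect in enumerate(_split_rect(crect, n_fine, rng)):
            fid = f"{cid}B{fi:03d}"
            fine_zones.append(SourceZone(fid, box(*frect), parent_id=cid))
            fine_rects.append(frect)

    # --- clustered settlement mask ----------------------------------------
    n_towns = params.town_count or max(2, params.n_coarse // 3)
    towns = rng.uniform(0.0, extent, size=(n_towns, 2))
    sigma = params.settlement_sigma_frac * extent
    centers = np.array(
        [((r[0] + r[2]) / 2, (r[1] + r[3]) / 2) for r in fine_rects]
    )
    d2 = ((centers[:, None, :] - towns[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    p_settle = 0.9 * np.exp(-d2 / sigma**2) + 0.02
    settled = rng.random(len(fine_zones)) < p_settle

    # --- parcel mosaic ------------------------------------------------------
    mix = dict(params.class_mix)
    kinds = list(mix)
    probs = np.array([mix[k] for k in kinds])
    parcels: list[ParcelFeature] = []
    parcel_kind: list[str] = []
    pid = 0
    for fz, frect, is_settled in zip(fine_zones, fine_rects, settled):
        if not is_settled:
            continue
        x0, y0, x1, y1 = frect
        w, h = x1 - x0, y1 - y0
        # Built-up core anchored at a random corner of the zone: settlement
        # inside a zone is itself clustered, not centered.
        bw, bh = w * rng.uniform(0.25, 0.55), h * rng.uniform(0.25, 0.55)
        if rng.random() < 0.5:
            bx0 = x0 if rng.random() < 0.5 else x1 - bw
        else:
            bx0 = rng.uniform(x0, x1 - bw)
        by0 = y0 if rng.random() < 0.5 else y1 - bh
        # Occasionally let the built patch spill over the zone edge so parcels
        # straddle zone boundaries and the sliver machinery gets exercised.
        if rng.random() < 0.15:
            bx0 = min(max(0.0, bx0 + rng.uniform(-40.0, 40.0)), extent - bw)
        # Each settled zone has a neighborhood style, mirroring how real
        # enumeration units tend to be internally homogeneous: ordinary town
        # lots, an exurb of multi-acre home lots, or an apartment district.
        style_draw = rng.random()
        if style_draw < params.exurb_prob:
            style = "exurb"
            cell = rng.uniform(95.0, 140.0)
        elif style_draw < params.exurb_prob + params.hd_district_prob:
            style = "hd_district"
            cell = rng.uniform(60.0, 85.0)
        else:
            style = "town"
            cell = rng.uniform(42.0, 62.0)
        nx = max(1, int(bw // cell))
        ny = max(1, int(bh // cell))
        draws = rng.choice(len(kinds), size=nx * ny, p=probs)
        used = np.zeros((ny, nx), dtype=bool)
        for iy in range(ny):
            for ix in range(nx):
                if used[iy, ix]:
                    continue
                kind = kinds[draws[iy * nx + ix]]
                if kind in ("open", "rural"):
                    continue
                if style == "exurb":
                    kind = "large_lot"
                elif style == "hd_district" and kind == "small":
                    kind = "high_density"
                px0 = bx0 + ix * cell
                py0 = by0 + iy * cell
                span = 1
                # Occasionally a residential lot spans a 2x2 block of cells,
                # exceeding one acre: its people then ride on its buildings.
                if (
                    style == "town"
                    and kind == "small"
                    and rng.random() < params.large_lot_prob
                    and ix + 1 < nx
                    and iy + 1 < ny
                    and not used[iy : iy + 2, ix : ix + 2].any()
                ):
                    kind = "large_lot"
                    span = 2
                    used[iy : iy + 2, ix : ix + 2] = True
                side = span * cell
                if px0 + side > extent or py0 + side > extent or px0 < 0 or py0 < 0:
                    continue  # keep every parcel (hence building) inside the extent
                labels = _CLASS_LABELS["small" if kind == "large_lot" else kind]
                label = labels[int(rng.integers(len(labels)))]
                parcels.append(
                    ParcelFeature(f"P{pid:06d}", box(px0, py0, px0 + side, py0 + side), label)
                )
                parcel_kind.append(kind)
                pid += 1

    # Country coarse zones (no settled fine zone) split into ranch country,
    # which receives the big rural-residential holdings, and wilderness,
    # where the only structures are parcel-less cabin clusters.  Keeping the
    # two apart mirrors how coarser enumeration units tend to cover
    # internally similar landscapes.
    parent_index = {z.zone_id: i for i, z in enumerate(coarse_zones)}
    settled_coarse = {
        parent_index[fz.parent_id] for fz, s in zip(fine_zones, settled) if s
    }
    country = [i for i in range(params.n_coarse) if i not in settled_coarse]
    country = list(rng.permutation(country)) if country else []
    ranch_coarse = set(country[::2])
    wild_coarse = set(country[1::2])
    rural_idx = [
        i
        for i, (fz, s) in enumerate(zip(fine_zones, settled))
        if not s and parent_index[fz.parent_id] in ranch_coarse
    ]
    cabin_idx = [
        i
        for i, (fz, s) in enumerate(zip(fine_zones, settled))
        if not s and parent_index[fz.parent_id] in wild_coarse
    ]

    # Rural-residential holdings (~18 acres): one big parcel per chosen zone,
    # exercising the large-parcel path (population borne by buildings only).
    if params.rural_per_coarse > 0 and rural_idx:
        n_rural = int(rng.poisson(params.rural_per_coarse * params.n_coarse))
        for _ in range(n_rural):
            i = rural_idx[int(rng.integers(len(rural_idx)))]
            side = rng.uniform(240.0, 300.0)  # ~58k-90k m2, mean ~18 acres
            rect = _rect_in(rng, fine_rects[i], side, side)
            parcels.append(
                ParcelFeature(f"P{pid:06d}", box(*rect), "RURAL RESIDENCE (AGRICULTURAL)")
            )
            parcel_kind.append("rural")
            pid += 1

    # --- true buildings ----------------------------------------------------
    means = dict(params.people_per_building_mean)
    true_buildings: list[BuildingFeature] = []
    bld_kind: list[str] = []
    bid = 0
    for p, kind in zip(parcels, parcel_kind):
        if kind == "nonres" and rng.random() >= 0.7:
            continue  # some commercial lots are bare
        if kind == "small":
            n_b, lo, hi = 1, 9.0, 16.0
        elif kind == "large_lot":
            n_b, lo, hi = 1 + int(rng.poisson(1.0)), 10.0, 18.0
        elif kind == "high_density":
            n_b, lo, hi = 1, 28.0, 45.0
        elif kind == "rural":
            n_b, lo, hi = 1 + int(rng.poisson(0.8)), 10.0, 25.0
        else:
            n_b, lo, hi = 1, 15.0, 35.0
        for _ in range(n_b):
            bw, bh = rng.uniform(lo, hi), rng.uniform(lo, hi)
            rect = _rect_in(rng, p.geometry.bounds, bw, bh)
            true_buildings.append(BuildingFeature(f"B{bid:06d}", box(*rect)))
            bld_kind.append(kind)
            bid += 1

    # Cabins: occupied structures on land with no surrounding parcel at all,
    # in unsettled zones — the blocks whose only ancillary signal is the
    # building layer itself (or nothing, when detection misses them).
    all_parcel_tree = STRtree([p.geometry for p in parcels]) if parcels else None
    if params.cabin_per_coarse > 0 and cabin_idx:
        n_cabin = int(rng.poisson(params.cabin_per_coarse * params.n_coarse))
        placed_cabins = 0
        attempts = 0
        while placed_cabins < n_cabin and attempts < 40 * max(1, n_cabin):
            attempts += 1
            i = cabin_idx[int(rng.integers(len(cabin_idx)))]
            # a cluster of a few detached dwellings within a ~150 m patch
            patch = _rect_in(rng, fine_rects[i], 150.0, 150.0)
            n_in_cluster = 1 + int(rng.poisson(2.0))
            geoms = []
            for _ in range(n_in_cluster):
                s = rng.uniform(8.0, 15.0)
                geoms.append(box(*_rect_in(rng, patch, s, s)))
            if all_parcel_tree is not None and any(
                all_parcel_tree.query(g, predicate="intersects").size for g in geoms
            ):
                continue
            for g in geoms:
                true_buildings.append(BuildingFeature(f"B{bid:06d}", g))
                bld_kind.append("cabin")
                bid += 1
            placed_cabins += 1

    # --- per-building people with per-zone demographic composition ---------
    fine_ids = [z.zone_id for z in fine_zones]
    comp = rng.dirichlet(params.dirichlet_alpha, size=len(fine_zones))
    minors_share = rng.beta(*params.minors_share_beta, size=len(fine_zones))
    fine_tree = STRtree([z.geometry for z in fine_zones])

    bld_centers = shapely.centroid(np.array([b.geometry for b in true_buildings], dtype=object))
    # Assign each building to the fine zone containing its centroid; on a
    # boundary tie take the lowest zone index for determinism.
    zone_of = np.full(len(true_buildings), -1, dtype=int)
    if len(true_buildings):
        q_bld, q_zone = fine_tree.query(bld_centers, predicate="intersects")
        for b_i, z_i in zip(q_bld, q_zone):
            if zone_of[b_i] == -1 or z_i < zone_of[b_i]:
                zone_of[b_i] = z_i

    rows = []
    for b, kind, z_i in zip(true_buildings, bld_kind, zone_of):
        mean = means.get(kind, 0.0)
        total = int(rng.poisson(mean)) if mean > 0 else 0
        split = (
            rng.multinomial(total, comp[z_i]) if total > 0 else np.zeros(7, dtype=int)
        )
        minors = int(rng.binomial(total, minors_share[z_i])) if total > 0 else 0
        row = {"building_id": b.building_id, "zone_id": fine_ids[z_i] if z_i >= 0 else ""}
        row["TOTAL"] = total
        for name, v in zip(COMPOSITION_VARIABLES, split):
            row[name] = int(v)
        row["MINORS"] = minors
        rows.append(row)
    building_people = (
        pd.DataFrame(rows).set_index("building_id")
        if rows
        else pd.DataFrame(columns=["zone_id", *VARIABLES]).rename_axis("building_id")
    )

    # --- imperfect detection -----------------------------------------------
    detected: list[BuildingFeature] = []
    keep = rng.random(len(true_buildings)) >= params.detection_fn_rate
    for b, k in zip(true_buildings, keep):
        if k:
            detected.append(b)
    n_fp = int(rng.poisson(params.detection_fp_rate * len(true_buildings)))
    res_parcel_geoms = [
        p.geometry for p, k in zip(parcels, parcel_kind) if k in _RESIDENTIAL_KINDS
    ]
    res_tree = STRtree(res_parcel_geoms) if res_parcel_geoms else None
    placed = 0
    attempts = 0
    while placed < n_fp and attempts < 60 * max(1, n_fp):
        attempts += 1
        s = rng.uniform(8.0, 20.0)
        cx, cy = rng.uniform(0.0, extent - s, size=2)
        geom = box(cx, cy, cx + s, cy + s)
        # spurious detections only appear in open / non-residential space
        if res_tree is not None and res_tree.query(geom, predicate="intersects").size:
            continue
        detected.append(BuildingFeature(f"FP{placed:05d}", geom))
        placed += 1

    # --- exact truth aggregates ---------------------------------------------
    fine_table = pd.DataFrame(0, index=pd.Index(fine_ids, name="zone_id"), columns=list(VARIABLES), dtype=float)
    if len(building_people):
        sums = building_people.groupby("zone_id")[list(VARIABLES)].sum()
        sums = sums[sums.index != ""]
        fine_table.loc[sums.index, :] = sums.astype(float)
    parent_of = {z.zone_id: z.parent_id for z in fine_zones}
    coarse_table = (
        fine_table.groupby([parent_of[i] for i in fine_table.index]).sum()
    )
    coarse_table = coarse_table.reindex(
        [z.zone_id for z in coarse_zones], fill_value=0.0
    ).rename_axis("zone_id")

    for z in fine_zones:
        z.pop = {v: float(fine_table.at[z.zone_id, v]) for v in VARIABLES}
    for z in coarse_zones:
        z.pop = {v: float(coarse_table.at[z.zone_id, v]) for v in VARIABLES}

    return SceneTruth(
        params=params,
        extent_m=extent,
        crs=params.crs,
        coarse_zones=coarse_zones,
        fine_zones=fine_zones,
        parcels=parcels,
        true_buildings=true_buildings,
        detected_buildings=detected,
        building_people=building_people,
        fine_table=fine_table,
        coarse_table=coarse_table,
    )


def aggregate_truth(truth: SceneTruth, level: str = "fine") -> pd.DataFrame:
    """Ground-truth population table at the fine or coarse zone level."""
    if level == "fine":
        return truth.fine_table.copy()
    if level == "coarse":
        return truth.coarse_table.copy()
    raise ValueError(f"level must be 'fine' or 'coarse', got {level!r}")


def write_scene(truth: SceneTruth, outdir) -> dict[str, Path]:
    """Write the scene in the formats the pipeline reads.

    GeoJSON layers for zones, parcels and detected buildings; CSV population
    tables; scene.json recording the parameters for provenance.  The output
    is a drop-in pipeline input.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fine_zones": outdir / "fine_zones.geojson",
        "coarse_zones": outdir / "coarse_zones.geojson",
        "parcels": outdir / "parcels.geojson",
        "buildings": outdir / "buildings.geojson",
        "true_buildings": outdir / "true_buildings.geojson",
        "fine_population": outdir / "fine_population.csv",
        "coarse_population": outdir / "coarse_population.csv",
        "scene": outdir / "scene.json",
    }
    write_zones(truth.fine_zones, paths["fine_zones"], truth.crs)
    write_zones(truth.coarse_zones, paths["coarse_zones"], truth.crs)
    write_parcels(truth.parcels, paths["parcels"], truth.crs)
    write_buildings(truth.detected_buildings, paths["buildings"], truth.crs)
    write_buildings(truth.true_buildings, paths["true_buildings"], truth.crs)
    truth.fine_table.to_csv(paths["fine_population"])
    truth.coarse_table.to_csv(paths["coarse_population"])
    with open(paths["scene"], "w") as fh:
        json.dump(asdict(truth.params), fh, indent=2, sort_keys=True)
    return paths
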