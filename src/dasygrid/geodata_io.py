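"""Vector/raster I/O, geometry validation and population-table preparation.

Vector layers travel as GeoJSON FeatureCollections carrying a legacy-style
``crs`` member naming a *projected, meter-unit* CRS (e.g. "EPSG:3310").  The
tool never reprojects: every area threshold in the method is in m2, and a
silent reprojection would corrupt them, so a geographic or missing CRS is an
error, and mixing CRSs across layers is the caller's error to avoid.

Rasters are single-band float32 GeoTIFFs (one file per population variable,
people per pixel, north-up, pixel-is-area, no nodata — unpopulated in-extent
pixels are genuine zeros).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .gridder import GridSpec, PopulationGrid

log = logging.getLogger(__name__)

__all__ = [
    "CRSError",
    "GeodataError",
    "SourceZone",
    "ParcelFeature",
    "BuildingFeature",
    "Derivation",
    "DEFAULT_DERIVATIONS",
    "check_projected_crs",
    "repair_geometry",
    "read_zones",
    "read_parcels",
    "read_buildings",
    "write_zones",
    "write_parcels",
    "write_buildings",
    "read_population_table",
    "prepare_population_table",
    "join_population",
    "write_grid",
    "read_grid",
]


class CRSError(ValueError):
    """Missing, unknown-unit or geographic coordinate reference system."""


class GeodataError(ValueError):
    """Malformed vector layer or population table."""


#: Identifiers the tool recognizes as geographic (degree-unit) CRSs.
GEOGRAPHIC_CRS_IDS = frozenset(
    {
        "EPSG:4326",
        "EPSG:4269",
        "EPSG:4267",
        "EPSG:4258",
        "OGC:CRS84",
        "CRS84",
        "WGS84",
        "URN:OGC:DEF:CRS:OGC:1.3:CRS84",
    }
)


def check_projected_crs(crs: str | None) -> str:
    """Reject missing or geographic CRSs; return the identifier unchanged.

    Without a full CRS database the check is a deny-list of the common
    geographic identifiers plus a ``longlat`` substring test; anything else
    is trusted to be the projected meter CRS the user declared.
    """
    if not crs:
        raise CRSError("projected CRS required: layer has no CRS identifier")
    upper = crs.strip().upper()
    if upper in GEOGRAPHIC_CRS_IDS or "LONGLAT" in upper:
        raise CRSError(f"projected CRS required: {crs!r} is geographic")
    return crs.strip()


def repair_geometry(geom: BaseGeometry) -> BaseGeometry | None:
    """Make-valid contract: return the positive-area polygonal part, or None.

    Valid polygonal input passes through untouched.  Invalid input (bowties,
    self-touching rings) is repaired with shapely's make_valid and reduced to
    its polygonal component; anything that repairs to empty yields None so
    the caller can drop it with a warning.
    """
    if geom is None or geom.is_empty:
        return None
    if geom.is_valid and geom.geom_type in ("Polygon", "MultiPolygon"):
        return geom
    fixed = shapely.make_valid(geom)
    if fixed.geom_type == "GeometryCollection":
        parts = [g for g in fixed.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        if not parts:
            return None
        fixed = shapely.unary_union(parts)
    if fixed.is_empty or fixed.geom_type not in ("Polygon", "MultiPolygon"):
        return None
    return fixed


@dataclass
class SourceZone:
    """Enumeration polygon carrying a per-variable population vector."""

    zone_id: str
    geometry: BaseGeometry
    pop: dict[str, float] = field(default_factory=dict)
    parent_id: str | None = None

    @property
    def area_m2(self) -> float:
        return self.geometry.area


@dataclass
class ParcelFeature:
    """Land-use-classed polygon, the primary ancillary layer."""

    parcel_id: str
    geometry: BaseGeometry
    landuse_class: str

    @property
    def area_m2(self) -> float:
        return self.geometry.area


@dataclass
class BuildingFeature:
    building_id: str
    geometry: BaseGeometry

    @property
    def area_m2(self) -> float:
        return self.geometry.area


# ---------------------------------------------------------------------------
# GeoJSON reading / writing


def _read_collection(path) -> tuple[list[dict], str]:
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise GeodataError(f"{path}: expected a GeoJSON FeatureCollection")
    crs = doc.get("crs", {}).get("properties", {}).get("name")
    crs = check_projected_crs(crs)
    return doc.get("features", []), crs


def _repair_features(features, path, id_field):
    """Yield (properties, repaired geometry) per feature; log repair count."""
    n_repaired = 0
    out = []
    for feat in features:
        props = feat.get("properties") or {}
        if id_field not in props or props[id_field] in (None, ""):
            raise GeodataError(f"{path}: feature missing id field {id_field!r}")
        geom = shape(feat["geometry"])
        fixed = repair_geometry(geom)
        if fixed is None:
            log.warning(
                "%s: feature %s repaired to empty geometry; dropped",
                path,
                props[id_field],
            )
            continue
        if fixed is not geom:
            n_repaired += 1
        out.append((props, fixed))
    if n_repaired:
        log.info("%s: repaired %d invalid geometries", path, n_repaired)
    return out


def _check_unique(ids: list[str], path, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise GeodataError(f"{path}: duplicate {what} {i!r}")
        seen.add(i)


def read_zones(
    path,
    id_field: str = "zone_id",
    parent_field: str | None = None,
) -> tuple[list[SourceZone], str]:
    """Read source zones from GeoJSON; returns (zones, crs).

    Populations are joined separately from a table (see join_population);
    zones come back with empty pop vectors.
    """
    features, crs = _read_collection(path)
    records = _repair_features(features, path, id_field)
    zones = [
        SourceZone(
            zone_id=str(props[id_field]),
            geometry=geom,
            parent_id=(
                str(props[parent_field])
                if parent_field and props.get(parent_field) not in (None, "")
                else None
            ),
        )
        for props, geom in records
    ]
    _check_unique([z.zone_id for z in zones], path, "zone_id")
    return zones, crs


def read_parcels(
    path,
    id_field: str = "parcel_id",
    landuse_field: str = "landuse_class",
) -> tuple[list[ParcelFeature], str]:
    features, crs = _read_collection(path)
    records = _repair_features(features, path, id_field)
    parcels = []
    for props, geom in records:
        landuse = props.get(landuse_field)
        if not landuse:
            raise GeodataError(
                f"{path}: parcel {props[id_field]!r} missing {landuse_field!r}"
            )
        parcels.append(ParcelFeature(str(props[id_field]), geom, str(landuse)))
    _check_unique([p.parcel_id for p in parcels], path, "parcel_id")
    return parcels, crs


def read_buildings(path, id_field: str = "building_id") -> tuple[list[BuildingFeature], str]:
    features, crs = _read_collection(path)
    records = _repair_features(features, path, id_field)
    buildings = [BuildingFeature(str(props[id_field]), geom) for props, geom in records]
    _check_unique([b.building_id for b in buildings], path, "building_id")
    return buildings, crs


def _write_collection(path, rows: Iterable[tuple[dict, BaseGeometry]], crs: str) -> None:
    crs = check_projected_crs(crs)
    features = [
        {"type": "Feature", "properties": props, "geometry": mapping(geom)}
        for props, geom in rows
    ]
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs}},
        "features": features,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh)


def write_zones(zones: Sequence[SourceZone], path, crs: str) -> None:
    rows = []
    for z in zones:
        props = {"zone_id": z.zone_id}
        if z.parent_id is not None:
            props["parent_id"] = z.parent_id
        props.update(z.pop)
        rows.append((props, z.geometry))
    _write_collection(path, rows, crs)


def write_parcels(parcels: Sequence[ParcelFeature], path, crs: str) -> None:
    _write_collection(
        path,
        (({"parcel_id": p.parcel_id, "landuse_class": p.landuse_class}, p.geometry) for p in parcels),
        crs,
    )


def write_buildings(buildings: Sequence[BuildingFeature], path, crs: str) -> None:
    _write_collection(
        path, (({"building_id": b.building_id}, b.geometry) for b in buildings), crs
    )


# ---------------------------------------------------------------------------
# Population tables


@dataclass(frozen=True)
class Derivation:
    """Derived column = sum(add) - sum(subtract), must be non-negative."""

    name: str
    add: tuple[str, ...] = ()
    subtract: tuple[str, ...] = ()


#: Standard redistricting-file derivations: other/multiracial is the sum of
#: "some other race alone" and "two or more races"; minors are total
#: population minus adults.
DEFAULT_DERIVATIONS: tuple[Derivation, ...] = (
    Derivation("NHOTHERMULTI", add=("P002010", "P002011")),
    Derivation("MINORS", add=("P002001",), subtract=("P003001",)),
)


def read_population_table(path, zone_id_column: str = "zone_id") -> pd.DataFrame:
    """CSV with a zone_id column; all other columns are people counts."""
    df = pd.read_csv(path, dtype={zone_id_column: str})
    if zone_id_column not in df.columns:
        raise GeodataError(f"{path}: missing {zone_id_column!r} column")
    if df[zone_id_column].duplicated().any():
        dupes = df[zone_id_column][df[zone_id_column].duplicated()].tolist()
        raise GeodataError(f"{path}: duplicate zone_id rows {dupes[:5]}")
    df = df.set_index(zone_id_column)
    if (df < 0).any().any():
        raise GeodataError(f"{path}: negative population counts")
    return df


def prepare_population_table(
    raw: pd.DataFrame,
    derivations: Sequence[Derivation] = DEFAULT_DERIVATIONS,
) -> pd.DataFrame:
    """Append derived variable columns; original columns are preserved.

    Counts are accepted as non-negative reals so fractional (synthetic or
    coarse-zone-derived) inputs work the same as census integers.  A derived
    value that comes out negative (e.g. adults exceeding total population)
    is a data error and names the offending zone.
    """
    if (raw.select_dtypes("number") < 0).any().any():
        raise GeodataError("population table contains negative counts")
    out = raw.copy()
    for rule in derivations:
        missing = [c for c in rule.add + rule.subtract if c not in out.columns]
        if missing:
            raise GeodataError(
                f"derivation {rule.name!r} references missing columns {missing}"
            )
        derived = sum(out[c] for c in rule.add) - sum(
            (out[c] for c in rule.subtract), start=pd.Series(0.0, index=out.index)
        )
        bad = derived[derived < 0]
        if len(bad):
            raise GeodataError(
                f"derived column {rule.name!r} negative for zone(s) "
                f"{list(bad.index[:5])}"
            )
        out[rule.name] = derived
    return out


def join_population(
    zones: Sequence[SourceZone],
    table: pd.DataFrame,
    variables: Sequence[str] | None = None,
) -> list[SourceZone]:
    """Attach per-variable counts to zones in place; returns the zones.

    Zones absent from the table get all-zero counts with a logged warning
    (genuinely empty zones are tolerable); table rows matching no zone are an
    error (orphan data should fail loudly).
    """
    if variables is None:
        variables = list(table.columns)
    zone_ids = {z.zone_id for z in zones}
    orphans = [i for i in table.index if i not in zone_ids]
    if orphans:
        raise GeodataError(
            f"population table rows with no matching zone: {orphans[:5]}"
        )
    n_missing = 0
    for z in zones:
        if z.zone_id in table.index:
            row = table.loc[z.zone_id]
            z.pop = {v: float(row[v]) for v in variables}
        else:
            z.pop = {v: 0.0 for v in variables}
            n_missing += 1
    if n_missing:
        log.warning(
            "%d zone(s) missing from the population table; assigned zeros",
            n_missing,
        )
    return list(zones)


# ---------------------------------------------------------------------------
# Raster I/O (GeoTIFF via tifffile)

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735


def _epsg_code(crs: str) -> int | None:
    parts = crs.strip().upper().split(":")
    if len(parts) == 2 and parts[0] == "EPSG" and parts[1].isdigit():
        return int(parts[1])
    return None


def write_grid(grid: PopulationGrid, path) -> None:
    """Write one variable as a single-band float32 GeoTIFF.

    Accumulation upstream is float64; the down-cast to float32 happens here,
    at the file boundary.  Georeferencing goes into the standard GeoTIFF tags
    (pixel scale, tiepoint, geo-key directory when the CRS is an EPSG code)
    plus a JSON ImageDescription carrying the CRS string and variable name.
    """
    spec = grid.spec
    check_projected_crs(spec.crs)
    data = grid.values.astype(np.float32)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (spec.resolution, spec.resolution, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.origin_x, spec.origin_y, 0.0)),
    ]
    epsg = _epsg_code(spec.crs)
    if epsg is not None:
        keys = (1, 1, 0, 3, 1024, 0, 1, 1, 1025, 0, 1, 1, 3072, 0, 1, epsg)
        extratags.append((_TAG_GEO_KEYS, "H", len(keys), keys))
    desc = json.dumps(
        {"crs": spec.crs, "variable": grid.variable, "resolution": spec.resolution}
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, data, extratags=extratags, description=desc)


def read_grid(path) -> PopulationGrid:
    """Read a grid written by write_grid; values round-trip bit-exactly."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray()
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise GeodataError(f"{path}: missing georeferencing tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        if abs(sx - sy) > 1e-9:
            raise GeodataError(f"{path}: non-square pixels ({sx} x {sy})")
        tie = tags[_TAG_TIEPOINT].value
        origin_x, origin_y = tie[3], tie[4]
        meta = {}
        desc = tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, ValueError):
                meta = {}
        crs = meta.get("crs")
        if crs is None and _TAG_GEO_KEYS in tags:
            keys = tags[_TAG_GEO_KEYS].value
            for i in range(4, len(keys), 4):
                if keys[i] == 3072:
                    crs = f"EPSG:{keys[i + 3]}"
    if crs is None:
        raise GeodataError(f"{path}: no CRS recorded")
    if values.ndim != 2:
        raise GeodataError(f"{path}: expected a single-band raster")
    spec = GridSpec(crs, float(origin_x), float(origin_y), float(sx), *values.shape)
    return PopulationGrid(spec, meta.get("variable", Path(path).stem), values)
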