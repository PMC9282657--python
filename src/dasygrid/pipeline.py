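"""End-to-end orchestration: zones + ancillary layers -> per-variable grids."""
from __future__ import annotations

from typing import Sequence

import pandas as pd
import shapely

from .geodata_io import BuildingFeature, ParcelFeature, SourceZone
from .gridder import GridSpec, PopulationGrid, assign_density, rasterize
from .target_zones import DasymetricConfig, assemble_target_zones, audit_frame


def build_grids(
    zones: Sequence[SourceZone],
    parcels: Sequence[ParcelFeature],
    buildings: Sequence[BuildingFeature],
    cfg: DasymetricConfig | None = None,
    crs: str = "EPSG:3310",
    resolution: float = 100.0,
    spec: GridSpec | None = None,
    variables: Sequence[str] | None = None,
) -> tuple[dict[str, PopulationGrid], list, pd.DataFrame]:
    """Assemble target zones, assign densities, and rasterize.

    Returns (grids by variable, target zones, audit table).  The grid spec
    defaults to the snapped 100 m grid covering the zone layer.
    """
    cfg = cfg or DasymetricConfig()
    targets, audit = assemble_target_zones(zones, parcels, buildings, cfg)
    by_id = {z.zone_id: z for z in zones}
    for t in targets:
        assign_density(by_id[t.zone_id], t)
    if spec is None:
        bounds = shapely.total_bounds([z.geometry for z in zones])
        spec = GridSpec.from_bounds(tuple(bounds), resolution, crs)
    grids = rasterize(targets, spec, variables)
    return grids, targets, audit_frame(audit)


def step_population_shares(
    zones: Sequence[SourceZone],
    audit: pd.DataFrame,
    total_variable: str = "TOTAL",
) -> pd.Series:
    """Fraction of total population apportioned via each assembly step."""
    pop = {
        z.zone_id: z.pop.get(total_variable, sum(z.pop.values())) for z in zones
    }
    df = audit.assign(pop=lambda d: d["zone_id"].map(pop))
    total = df["pop"].sum()
    shares = df.groupby("step")["pop"].sum() / (total if total else 1.0)
    return shares.reindex(["A", "B", "C", "D"], fill_value=0.0)
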