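"""Assemble PSU output attributes and write vector layers.

One record per PSU carrying the population bookkeeping needed for design
weights (stratum totals, PSU totals, per-stratum PSU counts) plus the seed
centroid and a dissolved polygon of the member cells.  Writers: GeoJSON
(full field names), ESRI shapefile (10-character names via a fixed
truncation map), and a plain CSV of the attribute table.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from . import _shapefile
from .frame import GridFrame
from .growth import Psu

__all__ = [
    "ATTRIBUTE_COLUMNS",
    "SHAPEFILE_NAME_MAP",
    "summarize_strata",
    "psu_records",
    "psu_polygon",
    "write_psu_layer",
    "write_attribute_csv",
]

ATTRIBUTE_COLUMNS = [
    "PSUid",
    "stratum",
    "psu_pop",
    "psu_r_pop",
    "psu_u_pop",
    "psus_in_stratum",
    "str_pop",
    "str_r_pop",
    "str_u_pop",
    "str_cells",
    "xCent",
    "yCent",
    "U_R",
]

#: Stable truncation of attribute names to the shapefile 10-character limit.
SHAPEFILE_NAME_MAP = {"psus_in_stratum": "psus_in_st"}


def summarize_strata(frame: GridFrame) -> pd.DataFrame:
    """Per-stratum totals over eligible cells only.

    Columns: str_pop, str_r_pop, str_u_pop, str_cells, indexed by stratum id.
    """
    if len(frame) == 0:
        raise ValueError("empty frame")
    cells = frame.cells
    grouped = cells.groupby("stratum_id")
    urban_pop = (
        cells.loc[cells["urban"]].groupby("stratum_id")["population"].sum()
    )
    out = pd.DataFrame(
        {
            "str_pop": grouped["population"].sum(),
            "str_u_pop": urban_pop.reindex(grouped.size().index, fill_value=0.0),
            "str_cells": grouped.size(),
        }
    )
    out["str_r_pop"] = out["str_pop"] - out["str_u_pop"]
    out.index.name = "stratum_id"
    return out[["str_pop", "str_r_pop", "str_u_pop", "str_cells"]]


def psu_records(psus: list[Psu], strata_totals: pd.DataFrame) -> pd.DataFrame:
    """Flat attribute table, one row per PSU, in the output schema."""
    counts: dict[int, int] = {}
    for p in psus:
        counts[p.stratum_id] = counts.get(p.stratum_id, 0) + 1
    rows = []
    for p in psus:
        totals = strata_totals.loc[p.stratum_id]
        rows.append(
            {
                "PSUid": p.psu_id,
                "stratum": p.stratum_id,
                "psu_pop": p.psu_pop,
                "psu_r_pop": p.psu_r_pop,
                "psu_u_pop": p.psu_u_pop,
                "psus_in_stratum": counts[p.stratum_id],
                "str_pop": float(totals["str_pop"]),
                "str_r_pop": float(totals["str_r_pop"]),
                "str_u_pop": float(totals["str_u_pop"]),
                "str_cells": int(totals["str_cells"]),
                "xCent": p.centroid_x,
                "yCent": p.centroid_y,
                "U_R": "U" if p.urban else "R",
            }
        )
    return pd.DataFrame(rows, columns=ATTRIBUTE_COLUMNS)


def psu_polygon(psu: Psu, frame: GridFrame) -> shapely.Geometry:
    """Dissolved union of the PSU's member-cell rectangles."""
    cw, ch = frame.cell_width, frame.cell_height
    boxes = []
    for cell_id in sorted(psu.member_cells):
        row, col = divmod(cell_id, frame.n_cols)
        west = frame.origin_x + col * cw
        north = frame.origin_y - row * ch
        boxes.append(box(west, north - ch, west + cw, north))
    return unary_union(boxes)


def write_psu_layer(
    psus: list[Psu],
    strata_totals: pd.DataFrame,
    frame: GridFrame,
    path: str | os.PathLike,
    fmt: str = "geojson",
    sidecar: dict | None = None,
) -> Path:
    """Write the PSU polygon layer plus a sidecar of run metadata.

    ``fmt`` is ``"geojson"`` or ``"shapefile"``.  Centroids are the seed-cell
    centres in the grid's native coordinates; whether those are decimal
    degrees is recorded in the sidecar (``coordinates_are_degrees``).
    """
    if not psus:
        raise ValueError("no PSUs to write")
    path = Path(path)
    table = psu_records(psus, strata_totals)
    geoms = [psu_polygon(p, frame) for p in psus]

    if fmt.lower() == "geojson":
        out = path if path.suffix else path.with_suffix(".geojson")
        features = []
        for (_, rec), geom in zip(table.iterrows(), geoms):
            features.append(
                {
                    "type": "Feature",
                    "properties": _jsonable(rec.to_dict()),
                    "geometry": mapping(geom),
                }
            )
        with open(out, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
            fh.write("\n")
    elif fmt.lower() == "shapefile":
        out = path if path.suffix else path.with_suffix(".shp")
        fields = [
            (SHAPEFILE_NAME_MAP.get(c, c), "C" if c == "U_R" else "N",
             3 if c == "U_R" else 24,
             0 if c in ("PSUid", "stratum", "psus_in_stratum", "str_cells") else 6)
            for c in ATTRIBUTE_COLUMNS
        ]
        records = [tuple(rec[c] for c in ATTRIBUTE_COLUMNS) for _, rec in table.iterrows()]
        _shapefile.write_polygon_shapefile(out, [_shp_rings(g) for g in geoms], fields, records)
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'geojson' or 'shapefile'")

    side = dict(sidecar or {})
    side.setdefault("coordinates_are_degrees", frame.is_geographic())
    side.setdefault("crs_label", frame.crs_label)
    with open(out.with_suffix(out.suffix + ".sidecar.json"), "w", encoding="utf-8") as fh:
        json.dump(_jsonable(side), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out


def write_attribute_csv(
    psus: list[Psu], strata_totals: pd.DataFrame, path: str | os.PathLike
) -> Path:
    path = Path(path)
    psu_records(psus, strata_totals).to_csv(path, index=False)
    return path


def _shp_rings(geom: shapely.Geometry):
    """Shapefile ring lists (outer rings clockwise, holes counter-clockwise)."""
    polys = list(geom.geoms) if geom.geom_type == "MultiPolygon" else [geom]
    rings = []
    for poly in polys:
        exterior = list(shapely.geometry.polygon.orient(poly, sign=-1.0).exterior.coords)
        rings.append([(float(x), float(y)) for x, y in exterior])
        for interior in shapely.geometry.polygon.orient(poly, sign=-1.0).interiors:
            rings.append([(float(x), float(y)) for x, y in interior.coords])
    return rings


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
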