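"""Zone polygon output and choropleth rendering for the synthetic region.

Zones are unions of planar hexagons; they are written as GeoJSON and
rendered with matplotlib.  Zones without data are drawn hatched
("striped = no data" map convention).
"""

from __future__ import annotations

import json
from math import cos, pi, sin, sqrt

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import PatchCollection
from matplotlib.patches import PathPatch
from matplotlib.path import Path as MplPath
from shapely.geometry import Polygon, mapping
from shapely.ops import unary_union

from .synthetic_region import Region

__all__ = ["zone_polygons", "write_zones_geojson", "choropleth", "importance_barplot"]

_HEX_R = 1.0 / sqrt(3.0) * 1.001  # slight overlap so unions have no slivers


def _hexagon(cx: float, cy: float) -> Polygon:
    pts = [
        (cx + _HEX_R * sin(pi / 3.0 * k), cy + _HEX_R * cos(pi / 3.0 * k))
        for k in range(6)
    ]
    return Polygon(pts)


def zone_polygons(region: Region) -> dict[str, Polygon]:
    """Union of member-cell hexagons per zone (a split cell counts in its
    majority zone for rendering)."""
    hexes: dict[str, list[Polygon]] = {}
    for cell in region.cells:
        zone = max(cell.zone_weights, key=cell.zone_weights.get)
        hexes.setdefault(zone, []).append(_hexagon(*cell.center))
    return {z: unary_union(hs) for z, hs in sorted(hexes.items())}


def write_zones_geojson(region: Region, path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"zone_id": zone},
            "geometry": mapping(poly),
        }
        for zone, poly in zone_polygons(region).items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def _geojson_patches(geojson: dict):
    for feature in geojson["features"]:
        geom = feature["geometry"]
        polys = [geom["coordinates"]] if geom["type"] == "Polygon" else geom["coordinates"]
        paths = []
        for rings in polys:
            for ring in rings:
                arr = np.asarray(ring)
                codes = [MplPath.MOVETO] + [MplPath.LINETO] * (len(arr) - 2) + [MplPath.CLOSEPOLY]
                paths.append(MplPath(arr, codes))
        yield feature["properties"]["zone_id"], MplPath.make_compound_path(*paths)


def choropleth(
    geojson_path,
    values: dict[str, float],
    title: str,
    out_path,
    cmap: str = "viridis",
    label: str = "pCi/L",
) -> None:
    """Render zone values; zones absent from ``values`` are hatched gray."""
    with open(geojson_path) as fh:
        gj = json.load(fh)
    fig, ax = plt.subplots(figsize=(7, 6))
    have, have_vals, missing = [], [], []
    for zone, path in _geojson_patches(gj):
        if zone in values and np.isfinite(values[zone]):
            have.append(PathPatch(path))
            have_vals.append(values[zone])
        else:
            missing.append(PathPatch(path))
    if have:
        coll = PatchCollection(have, cmap=cmap, edgecolor="white", linewidth=0.2)
        coll.set_array(np.asarray(have_vals))
        ax.add_collection(coll)
        fig.colorbar(coll, ax=ax, label=label, shrink=0.8)
    if missing:
        ax.add_collection(
            PatchCollection(
                missing, facecolor="lightgray", hatch="///", edgecolor="gray", linewidth=0.2
            )
        )
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title(title)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def importance_barplot(importance_df, title: str, out_path, top: int = 15) -> None:
    df = importance_df.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(df) + 1.5))
    ax.barh(df["feature"], df["importance"], xerr=df.get("sd"), color="steelblue")
    ax.set_xlabel("mean decrease in out-of-sample R²")
    ax.set_title(title)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
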