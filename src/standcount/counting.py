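"""Plot-level aggregation of detections into stand counts and densities."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point

from .io_geo import GeoImage, PlotMap, pixel_to_world
from .matching import Detection

__all__ = ["PlotCount", "assign_to_plots", "summarize", "write_plot_summary"]


@dataclass
class PlotCount:
    plot_id: str
    digital_count: int
    density: float  # plants per m^2
    area_m2: float
    manual_count: int | None = None


def assign_to_plots(
    detections: list[Detection],
    plots: PlotMap,
    geo: GeoImage | None = None,
) -> tuple[dict[str, list[Detection]], list[Detection]]:
    """Assign each detection to at most one plot by point-in-polygon.

    Detection centers are mapped to the plot frame (world coordinates via
    the image transform when the plot map is in world coordinates, raw
    pixel coordinates otherwise).  Boundary points are assigned to the
    plot whose id sorts first, so abutting plots never double-count.
    Returns ``(per-plot assignment, unassigned detections)``.
    """
    if plots.frame == "world":
        if geo is None or geo.transform is None:
            raise ValueError(
                "plot map is in world coordinates but the image has no transform"
            )
        if detections:
            cols = np.array([d.col for d in detections], dtype=float)
            rows = np.array([d.row for d in detections], dtype=float)
            xs, ys = pixel_to_world(geo.transform, cols, rows)
            xs, ys = np.atleast_1d(xs), np.atleast_1d(ys)
        else:
            xs = ys = np.empty(0)
    else:
        xs = np.array([d.col for d in detections], dtype=float)
        ys = np.array([d.row for d in detections], dtype=float)

    idx = assign_points(xs, ys, plots)
    assignment: dict[str, list[Detection]] = {p.plot_id: [] for p in plots.plots}
    unassigned: list[Detection] = []
    for i, det in enumerate(detections):
        if idx[i] is None:
            unassigned.append(det)
        else:
            assignment[idx[i]].append(det)
    return assignment, unassigned


def assign_points(xs, ys, plots: PlotMap) -> list[str | None]:
    """Plot id (or None) for each point, in the plot map's own frame.

    Boundary points go to the plot whose id sorts first — deterministic and
    never double-counted.
    """
    order = sorted(range(len(plots)), key=lambda i: plots.plots[i].plot_id)
    tree = STRtree([plots.plots[i].polygon for i in order])
    out: list[str | None] = []
    for x, y in zip(np.atleast_1d(xs), np.atleast_1d(ys)):
        hits = sorted(tree.query(Point(x, y), predicate="covered_by").tolist())
        out.append(plots.plots[order[hits[0]]].plot_id if hits else None)
    return out


def summarize(
    assignment: dict[str, list[Detection]],
    plots: PlotMap,
    manual: pd.DataFrame | dict | None = None,
) -> list[PlotCount]:
    """One :class:`PlotCount` per plot; density = count / polygon area (m^2).

    ``manual`` may be a mapping or a DataFrame with columns
    ``plot_id, manual_count``; rows referencing unknown plots are ignored
    with a warning.
    """
    manual_map: dict[str, int] = {}
    if manual is not None:
        if isinstance(manual, pd.DataFrame):
            manual_map = {
                str(r.plot_id): int(r.manual_count) for r in manual.itertuples()
            }
        else:
            manual_map = {str(k): int(v) for k, v in dict(manual).items()}
        unknown = set(manual_map) - set(plots.ids())
        if unknown:
            warnings.warn(
                f"manual counts for unknown plot ids ignored: {sorted(unknown)}"
            )
            for pid in unknown:
                manual_map.pop(pid)
    out = []
    for p in plots.plots:
        n = len(assignment.get(p.plot_id, []))
        out.append(
            PlotCount(
                plot_id=p.plot_id,
                digital_count=n,
                density=n / p.area_m2,
                area_m2=p.area_m2,
                manual_count=manual_map.get(p.plot_id),
            )
        )
    return out


def write_plot_summary(counts: list[PlotCount], path: str | Path) -> Path:
    """Plot summary CSV with a stable column order."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "plot_id": [c.plot_id for c in counts],
            "digital_count": [c.digital_count for c in counts],
            "density_per_m2": [c.density for c in counts],
            "manual_count": [
                "" if c.manual_count is None else c.manual_count for c in counts
            ],
        }
    )
    df.to_csv(path, index=False)
    return path
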