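"""Synthetic UAV orthomosaic fields with known per-plant ground truth.

Emulates the imaging conditions of an early-season stand-count flight over
small-plot field trials: ~0.19 cm/px ground sampling distance, brown
soil with correlated texture, dicot seedlings at mixed 2-4 leaf growth
stages rendered as green rosettes of elliptical leaves, heterogeneous
per-plot densities, a configurable share of plants in tight pairs/triples
(canopy overlap), and occasional grass-like weeds.

Generator contracts (asserted in tests):

* soil pixels keep green ratio < 0.33 everywhere, so they never classify
  as vegetation at the 0.36 threshold;
* every opaque sprite pixel has green ratio > 0.40 and each sprite covers
  at least 30 px, so real plants always survive Part I;
* everything is a pure function of ``(config, seed)``; per-plot RNG streams
  are derived by counter so changing ``n_plots`` never alters earlier plots.

Radiometric realism (shadows, blur, mosaic seams) is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk, ellipse, line

from .io_geo import Affine, GeoImage, PlotMap, PlotPolygon, write_orthomosaic, write_plot_map

__all__ = [
    "FieldConfig",
    "PlotTruth",
    "GroundTruth",
    "Experiment",
    "render_seedling",
    "generate_plot",
    "generate_experiment",
    "assemble_mosaic",
]

_SOIL_RGB = (115.0, 90.0, 72.0)  # green ratio 0.325
_SOIL_RATIO_CAP = 0.328  # hard clamp, below the 0.33 generator contract
_MARGIN_PX = 40  # tile margin so border canopies and footprints fit
_LEAF_NOISE = 0.32  # std of per-pixel luminance speckle inside leaves


@dataclass
class FieldConfig:
    """Study conditions for one synthetic experiment.

    Defaults mirror a winter-sown small-plot trial imaged at 20 m altitude:
    5 m x 1 m plots, 0.19 cm/px, target densities between 8 and 40
    plants/m^2 (40-200 per plot), a 30/40/30 mix of 2-, 3- and 4-leaf
    seedlings, 15% of plants in tight clusters and sparse grassy weeds.
    """

    n_plots: int = 10
    plot_length_m: float = 5.0
    plot_width_m: float = 1.0
    alley_m: float = 0.5
    gsd_cm: float = 0.19
    count_range: tuple[int, int] = (40, 200)
    growth_mix: tuple[float, float, float] = (0.3, 0.4, 0.3)  # 2/3/4 leaves
    leaf_length_px: tuple[float, float] = (7.0, 12.0)
    overlap_fraction: float = 0.15
    cluster_size_range: tuple[int, int] = (2, 3)
    weed_rate: float = 0.5  # weeds per m^2
    soil_texture_sigma_px: float = 8.0
    soil_texture_amp: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.growth_mix) - 1.0) > 1e-9:
            raise ValueError("growth_mix proportions must sum to 1")
        if self.gsd_cm <= 0:
            raise ValueError("gsd_cm must be > 0")
        lo, hi = self.count_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid count_range")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if min(self.leaf_length_px) <= 0:
            raise ValueError("leaf_length_px must be positive")

    # derived pixel geometry -------------------------------------------------
    @property
    def gsd_m(self) -> float:
        return self.gsd_cm / 100.0

    @property
    def plot_cols(self) -> int:
        return int(round(self.plot_length_m / self.gsd_m))

    @property
    def plot_rows(self) -> int:
        return int(round(self.plot_width_m / self.gsd_m))

    @property
    def min_spacing_px(self) -> float:
        """Minimum center spacing of non-clustered plants (canopies touch)."""
        return 2.2 * float(np.mean(self.leaf_length_px))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @staticmethod
    def from_json(text: str) -> "FieldConfig":
        doc = json.loads(text)
        for key in ("count_range", "growth_mix", "leaf_length_px", "cluster_size_range"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return FieldConfig(**doc)


@dataclass
class PlotTruth:
    plot_id: str
    centers_px: np.ndarray  # n x 2 (col, row) in the plot tile
    centers_world: np.ndarray  # n x 2 (x, y)
    leaf_counts: np.ndarray
    n_weeds: int = 0

    @property
    def count(self) -> int:
        return len(self.centers_px)


@dataclass
class GroundTruth:
    plots: list[PlotTruth]

    def counts(self) -> dict[str, int]:
        return {p.plot_id: p.count for p in self.plots}

    def manual_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plot_id": [p.plot_id for p in self.plots],
                "manual_count": [p.count for p in self.plots],
            }
        )


# ---------------------------------------------------------------------------
# sprites


def _leaf_angles(leaf_count: int, rng: np.random.Generator) -> np.ndarray:
    """Rosette leaf directions: opposite cotyledons, then true leaves."""
    if leaf_count == 2:
        base = [0.0, 180.0]
    elif leaf_count == 3:
        base = [0.0, 180.0, 90.0]
    else:
        base = [0.0, 180.0, 90.0, 270.0]
    return np.asarray(base) + rng.uniform(-14.0, 14.0, size=leaf_count)


def render_seedling(
    leaf_count: int,
    size_px: float,
    orientation_deg: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one rosette sprite.

    Returns ``(rgb, alpha)`` where rgb is float in [0, 255] and alpha is a
    boolean opacity mask.  Leaves are filled ellipses radiating from a
    small central disc; per-plant and per-pixel colour jitter keeps sprites
    non-identical while every opaque pixel keeps green ratio > 0.40.
    Deterministic for a fixed RNG state.
    """
    if leaf_count not in (2, 3, 4):
        raise ValueError("leaf_count must be 2, 3 or 4")
    # younger plants are smaller: cotyledon-stage rosettes at ~3/4 scale
    size_px = size_px * {2: 0.85, 3: 0.95, 4: 1.05}[leaf_count]
    radius = int(np.ceil(size_px)) + 3
    side = 2 * radius + 1
    alpha = np.zeros((side, side), dtype=bool)
    cr = cc = radius

    angles = np.deg2rad(orientation_deg + _leaf_angles(leaf_count, rng))
    leaf_lum = rng.uniform(0.78, 1.18, size=leaf_count)
    for i, ang in enumerate(angles):
        L = size_px * rng.uniform(0.65, 1.0)
        if i >= 2:  # true leaves: slightly longer and narrower
            L *= rng.uniform(0.95, 1.1)
            width = L * rng.uniform(0.30, 0.40)
        else:  # cotyledons: shorter, rounder
            width = L * rng.uniform(0.38, 0.50)
        ecr = cr - 0.52 * L * np.sin(ang)
        ecc = cc + 0.52 * L * np.cos(ang)
        rr, cco = ellipse(ecr, ecc, width / 2.0 + 0.5, L / 2.0 + 0.5,
                          shape=alpha.shape, rotation=ang)
        alpha[rr, cco] = True
    rr, cco = disk((cr, cc), max(2.0, 0.16 * size_px), shape=alpha.shape)
    alpha[rr, cco] = True

    g_base = rng.uniform(150.0, 185.0)
    r_base = g_base * rng.uniform(0.40, 0.50)
    b_base = g_base * rng.uniform(0.30, 0.40)
    rgb = np.zeros((side, side, 3))
    # young central leaves are lighter green than the shaded leaf tips:
    # radial luminance falloff from ~1.3 at the apex to ~0.55 at the rim,
    # with leaf-to-leaf brightness differences and in-leaf texture
    yy, xx = np.mgrid[0:side, 0:side]
    dist = np.hypot(yy - cr, xx - cc) / max(radius, 1)
    lum = (1.30 - 0.75 * np.clip(dist, 0.0, 1.0) ** 1.2) * (
        1.0 + _LEAF_NOISE * rng.standard_normal((side, side))
    )
    theta = np.arctan2(-(yy - cr), xx - cc)
    sector = ((theta - np.deg2rad(orientation_deg)) / (2 * np.pi) * leaf_count)
    lum *= leaf_lum[np.round(sector).astype(int) % leaf_count]
    for ch, base in enumerate((r_base, g_base, b_base)):
        rgb[:, :, ch] = base * lum + rng.uniform(-6.0, 6.0, (side, side))
    rgb = np.clip(rgb, 1.0, 255.0)
    # enforce the >0.40 green-ratio contract on opaque pixels
    total = rgb.sum(axis=2)
    floor = 0.42 * total / (1.0 - 0.42)
    low = rgb[:, :, 1] < floor  # g < 0.42 * (r + g + b)
    rgb[:, :, 1] = np.where(low, 0.45 * (rgb[:, :, 0] + rgb[:, :, 2]) / 0.55, rgb[:, :, 1])
    rgb = np.clip(rgb, 1.0, 255.0)
    # area floor: every plant must survive a >=30 px object filter, so the
    # smallest cotyledon-stage sprites are thickened until they cover 32 px
    while alpha.sum() < 32:
        alpha = ndimage.binary_dilation(alpha)
    rgb[~alpha] = 0.0
    return rgb, alpha


def _render_weed(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Grass-like weed: a few thin blades from a common base."""
    radius = 18
    side = 2 * radius + 1
    alpha = np.zeros((side, side), dtype=bool)
    n_blades = rng.integers(2, 5)
    for _ in range(n_blades):
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(10, radius - 1)
        r1 = int(radius - length * np.sin(ang))
        c1 = int(radius + length * np.cos(ang))
        rr, cc = line(radius, radius, r1, c1)
        alpha[rr, cc] = True
    alpha = ndimage.binary_dilation(alpha, iterations=1)
    g = rng.uniform(120.0, 150.0)
    rgb = np.zeros((side, side, 3))
    rgb[:, :, 0] = g * 0.55
    rgb[:, :, 1] = g
    rgb[:, :, 2] = g * 0.45
    rgb *= 1.0 + 0.08 * rng.standard_normal((side, side, 1))
    rgb = np.clip(rgb, 1.0, 255.0)
    rgb[~alpha] = 0.0
    return rgb, alpha


# ---------------------------------------------------------------------------
# per-plot planning and rendering


@dataclass
class _PlotPlan:
    centers: np.ndarray  # n x 2 (col, row), tile pixel coordinates
    leaf_counts: np.ndarray
    sizes: np.ndarray
    orientations: np.ndarray
    weed_centers: np.ndarray


def _plot_rng(config: FieldConfig, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, index, stream]))


def _plan_plot(config: FieldConfig, index: int) -> _PlotPlan:
    rng = _plot_rng(config, index, 0)
    lo, hi = config.count_range
    target = int(rng.integers(lo, hi + 1))
    n_clustered = int(round(config.overlap_fraction * target))

    # cluster composition: sizes drawn from cluster_size_range
    cluster_sizes: list[int] = []
    budget = n_clustered
    cmin, cmax = config.cluster_size_range
    while budget >= cmin:
        c = int(rng.integers(cmin, cmax + 1))
        c = min(c, budget)
        if c < cmin:
            break
        cluster_sizes.append(c)
        budget -= c
    n_in_clusters = sum(cluster_sizes)
    n_anchors = len(cluster_sizes)
    n_singletons = target - n_in_clusters

    inset = 8.0
    c_lo, c_hi = _MARGIN_PX + inset, _MARGIN_PX + config.plot_cols - inset
    r_lo, r_hi = _MARGIN_PX + inset, _MARGIN_PX + config.plot_rows - inset
    d_min = config.min_spacing_px
    cell = max(d_min, 1.0)
    grid: dict[tuple[int, int], list[int]] = {}
    pts: list[tuple[float, float]] = []

    def far_enough(col: float, row: float) -> bool:
        key = (int(row // cell), int(col // cell))
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for j in grid.get((key[0] + dr, key[1] + dc), ()):
                    if (pts[j][0] - col) ** 2 + (pts[j][1] - row) ** 2 < d_min * d_min:
                        return False
        return True

    def place_one() -> tuple[float, float] | None:
        for _ in range(60):
            col = rng.uniform(c_lo, c_hi)
            row = rng.uniform(r_lo, r_hi)
            if far_enough(col, row):
                pts.append((col, row))
                grid.setdefault((int(row // cell), int(col // cell)), []).append(
                    len(pts) - 1
                )
                return col, row
        return None

    centers: list[tuple[float, float]] = []
    mean_leaf = float(np.mean(config.leaf_length_px))
    for _ in range(n_singletons):
        p = place_one()
        if p is not None:
            centers.append(p)
    for csize in cluster_sizes:
        anchor = place_one()
        if anchor is None:
            continue
        centers.append(anchor)
        for _ in range(csize - 1):
            for _try in range(40):
                ang = rng.uniform(0, 2 * np.pi)
                dist = rng.uniform(0.5, 1.0) * 2.0 * mean_leaf
                col = anchor[0] + dist * np.cos(ang)
                row = anchor[1] + dist * np.sin(ang)
                if c_lo <= col <= c_hi and r_lo <= row <= r_hi:
                    centers.append((col, row))
                    break

    n = len(centers)
    leaf_counts = rng.choice([2, 3, 4], size=n, p=list(config.growth_mix))
    sizes = rng.uniform(*config.leaf_length_px, size=n)
    orientations = rng.uniform(0.0, 360.0, size=n)

    area_m2 = config.plot_length_m * config.plot_width_m
    n_weeds = int(rng.poisson(config.weed_rate * area_m2))
    weed_centers = np.column_stack(
        [
            rng.uniform(c_lo, c_hi, size=n_weeds),
            rng.uniform(r_lo, r_hi, size=n_weeds),
        ]
    ) if n_weeds else np.empty((0, 2))
    return _PlotPlan(
        centers=np.asarray(centers, dtype=float).reshape(-1, 2),
        leaf_counts=leaf_counts,
        sizes=sizes,
        orientations=orientations,
        weed_centers=weed_centers,
    )


def _render_soil(shape: tuple[int, int], config: FieldConfig,
                 rng: np.random.Generator) -> np.ndarray:
    # gaussian-filtered white noise has std ~ 1/(2*sigma*sqrt(pi)); rescale
    # so soil_texture_amp is the std of the smooth luminance field
    sigma = config.soil_texture_sigma_px
    smooth = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    smooth *= 2.0 * sigma * np.sqrt(np.pi)
    lum = 1.0 + config.soil_texture_amp * smooth + 0.035 * rng.standard_normal(shape)
    tile = np.empty(shape + (3,))
    for ch, base in enumerate(_SOIL_RGB):
        tile[:, :, ch] = base * lum
    # chromatic jitter on red/blue only; green stays put so the ratio is tame
    tile[:, :, 0] += rng.uniform(-3.0, 3.0, shape)
    tile[:, :, 2] += rng.uniform(-3.0, 3.0, shape)
    tile = np.rint(np.clip(tile, 8.0, 250.0))
    # clamp the green-ratio contract on the final 8-bit values: soil green
    # is capped so that g / (r+g+b) < 0.33 survives quantisation exactly
    factor = _SOIL_RATIO_CAP / (1.0 - _SOIL_RATIO_CAP)
    cap = np.floor(factor * (tile[:, :, 0] + tile[:, :, 2]))
    tile[:, :, 1] = np.minimum(tile[:, :, 1], np.maximum(cap, 1.0))
    return tile


def _paste(tile: np.ndarray, rgb: np.ndarray, alpha: np.ndarray,
           center: tuple[float, float]) -> None:
    side = alpha.shape[0]
    radius = side // 2
    r0 = int(round(center[1])) - radius
    c0 = int(round(center[0])) - radius
    rs, cs = max(r0, 0), max(c0, 0)
    re, ce = min(r0 + side, tile.shape[0]), min(c0 + side, tile.shape[1])
    if re <= rs or ce <= cs:
        return
    sub_a = alpha[rs - r0 : re - r0, cs - c0 : ce - c0]
    sub_rgb = rgb[rs - r0 : re - r0, cs - c0 : ce - c0]
    region = tile[rs:re, cs:ce]
    region[sub_a] = sub_rgb[sub_a]


def _tile_shape(config: FieldConfig) -> tuple[int, int]:
    return (
        config.plot_rows + 2 * _MARGIN_PX,
        config.plot_cols + 2 * _MARGIN_PX,
    )


def _layout(config: FieldConfig) -> tuple[PlotMap, list[tuple[float, float]]]:
    """Grid plot map plus per-plot tile world origins (top-left corner)."""
    cols = int(np.ceil(np.sqrt(config.n_plots)))
    rows = int(np.ceil(config.n_plots / cols))
    pitch_x = config.plot_length_m + config.alley_m
    pitch_y = config.plot_width_m + config.alley_m
    plots = []
    origins = []
    n = 0
    from shapely.geometry import Polygon

    for r in range(rows):
        for c in range(cols):
            if n >= config.n_plots:
                break
            n += 1
            px, py = c * pitch_x, -r * pitch_y
            plots.append(
                PlotPolygon(
                    f"P{n:03d}",
                    Polygon(
                        [
                            (px, py),
                            (px + config.plot_length_m, py),
                            (px + config.plot_length_m, py - config.plot_width_m),
                            (px, py - config.plot_width_m),
                        ]
                    ),
                    config.plot_length_m * config.plot_width_m,
                )
            )
            origins.append(
                (px - _MARGIN_PX * config.gsd_m, py + _MARGIN_PX * config.gsd_m)
            )
    return PlotMap(plots), origins


def generate_plot(
    config: FieldConfig,
    index: int,
    _layout_cache: tuple[PlotMap, list] | None = None,
) -> tuple[GeoImage, PlotTruth]:
    """Render plot ``index`` (0-based) of the experiment grid.

    Returns the plot tile (with margin, georeferenced into the experiment's
    common world frame) and its ground truth.  Pure function of
    ``(config, index)``.
    """
    plot_map, origins = _layout_cache or _layout(config)
    if not 0 <= index < len(plot_map):
        raise IndexError(f"plot index {index} out of range")
    plan = _plan_plot(config, index)
    rng = _plot_rng(config, index, 1)
    shape = _tile_shape(config)
    tile = _render_soil(shape, config, rng)
    for i in range(len(plan.centers)):
        rgb, alpha = render_seedling(
            int(plan.leaf_counts[i]), float(plan.sizes[i]),
            float(plan.orientations[i]), rng,
        )
        _paste(tile, rgb, alpha, tuple(plan.centers[i]))
    for w in plan.weed_centers:
        rgb, alpha = _render_weed(rng)
        _paste(tile, rgb, alpha, tuple(w))
    tile8 = np.clip(np.rint(tile), 0, 255).astype(np.uint8)

    x0, y0 = origins[index]
    transform = Affine.from_origin(x0, y0, config.gsd_m)
    geo = GeoImage(pixels=tile8, gsd_cm=config.gsd_cm, transform=transform)
    from .io_geo import pixel_to_world

    if len(plan.centers):
        xs, ys = pixel_to_world(transform, plan.centers[:, 0], plan.centers[:, 1])
        world = np.column_stack([np.atleast_1d(xs), np.atleast_1d(ys)])
    else:
        world = np.empty((0, 2))
    truth = PlotTruth(
        plot_id=plot_map.plots[index].plot_id,
        centers_px=plan.centers,
        centers_world=world,
        leaf_counts=plan.leaf_counts,
        n_weeds=len(plan.weed_centers),
    )
    return geo, truth


@dataclass
class Experiment:
    """A generated experiment: plot map, truth, and lazily rendered tiles.

    Tiles are re-rendered on demand (deterministically) instead of being
    held in memory, so hundreds of plots stream through the pipeline at a
    small constant footprint.
    """

    config: FieldConfig
    plot_map: PlotMap
    truth: GroundTruth

    def iter_plots(self) -> Iterator[tuple[str, GeoImage, PlotTruth]]:
        cache = _layout(self.config)
        for i in range(self.config.n_plots):
            geo, truth = generate_plot(self.config, i, _layout_cache=cache)
            yield truth.plot_id, geo, truth

    def plot_image(self, index: int) -> GeoImage:
        return generate_plot(self.config, index)[0]

    def manual_counts(self) -> pd.DataFrame:
        return self.truth.manual_table()

    def write(self, out_dir: str | Path, image_format: str = "tif") -> Path:
        """Write tiles, plot map, truth points and the manual-count table."""
        out = Path(out_dir)
        (out / "tiles").mkdir(parents=True, exist_ok=True)
        for pid, geo, _tr in self.iter_plots():
            write_orthomosaic(geo, out / "tiles" / f"{pid}.{image_format}")
        write_plot_map(self.plot_map, out / "plots.geojson")
        self.manual_counts().to_csv(out / "manual_counts.csv", index=False)
        rows = []
        for p in self.truth.plots:
            for i in range(p.count):
                rows.append(
                    {
                        "plot_id": p.plot_id,
                        "col": p.centers_px[i, 0],
                        "row": p.centers_px[i, 1],
                        "x": p.centers_world[i, 0],
                        "y": p.centers_world[i, 1],
                        "leaf_count": int(p.leaf_counts[i]),
                    }
                )
        pd.DataFrame(
            rows, columns=["plot_id", "col", "row", "x", "y", "leaf_count"]
        ).to_csv(out / "truth_points.csv", index=False)
        (out / "config.json").write_text(self.config.to_json())
        return out


def generate_experiment(config: FieldConfig) -> Experiment:
    """Plan a whole experiment (truth for every plot; tiles render lazily)."""
    plot_map, origins = _layout(config)
    plots = []
    from .io_geo import pixel_to_world

    for i in range(config.n_plots):
        plan = _plan_plot(config, i)
        transform = Affine.from_origin(*origins[i], config.gsd_m)
        if len(plan.centers):
            xs, ys = pixel_to_world(transform, plan.centers[:, 0], plan.centers[:, 1])
            world = np.column_stack([np.atleast_1d(xs), np.atleast_1d(ys)])
        else:
            world = np.empty((0, 2))
        plots.append(
            PlotTruth(
                plot_id=plot_map.plots[i].plot_id,
                centers_px=plan.centers,
                centers_world=world,
                leaf_counts=plan.leaf_counts,
                n_weeds=len(plan.weed_centers),
            )
        )
    return Experiment(config=config, plot_map=plot_map, truth=GroundTruth(plots))


def assemble_mosaic(experiment: Experiment) -> GeoImage:
    """Paste all plot tiles into one georeferenced orthomosaic.

    Intended for small demonstrations; memory grows with field area.
    Alleys between tiles are filled with the flat soil base colour.
    """
    config = experiment.config
    _plot_map, origins = _layout(config)
    gsd = config.gsd_m
    xs = [o[0] for o in origins]
    ys = [o[1] for o in origins]
    shape = _tile_shape(config)
    x_min, y_max = min(xs), max(ys)
    x_max = max(xs) + shape[1] * gsd
    y_min = min(ys) - shape[0] * gsd
    W = int(round((x_max - x_min) / gsd))
    H = int(round((y_max - y_min) / gsd))
    canvas = np.empty((H, W, 3), dtype=np.uint8)
    canvas[:] = np.array(_SOIL_RGB, dtype=np.uint8)
    for i in range(config.n_plots):
        tile = experiment.plot_image(i).pixels
        c0 = int(round((origins[i][0] - x_min) / gsd))
        r0 = int(round((y_max - origins[i][1]) / gsd))
        canvas[r0 : r0 + shape[0], c0 : c0 + shape[1]] = tile
    transform = Affine.from_origin(x_min, y_max, gsd)
    return GeoImage(pixels=canvas, gsd_cm=config.gsd_cm, transform=transform)
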