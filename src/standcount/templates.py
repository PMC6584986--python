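"""Grouped seedling templates built from sample patches.

A seedling template is a small (default 20 x 20 px) intensity patch; because
seedlings at mixed growth stages vary in shape, a *grouped* template — a bank
of k subgroup templates obtained by clustering the sample patches — performs
far better than a single average.  Patches are zero-mean / unit-norm
normalised so that clustering distance and matching score share the same
correlation geometry: for unit-norm zero-mean vectors,
``||p - q||^2 = 2 (1 - corr(p, q))``.

Template quality R is the mean zero-normalised correlation between training
patches and their best-matching subgroup template; it rises with k and with
cleaner (background-masked) source layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .io_geo import GeoImage, PointSet
from .vegetation import PlantLayer, PlantMask, make_plant_layer

__all__ = [
    "PatchSet",
    "GroupedTemplate",
    "extract_patches",
    "normalize_patch",
    "build_grouped_template",
    "template_quality",
    "compare_channels",
    "save_template",
    "load_template",
]

DEFAULT_PATCH_SIZE = 20
DEFAULT_N_SUBGROUPS = 10


@dataclass
class PatchSet:
    """Sample patches cut from a layer, all the same size."""

    patches: np.ndarray  # n x s x s float
    source_points: PointSet
    channel: str = "green"
    n_skipped: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.patches, dtype=np.float64)
        if p.ndim != 3 or p.shape[1] != p.shape[2]:
            raise ValueError("patches must be n x s x s")
        if p.shape[0] < 1:
            raise ValueError("PatchSet requires at least one patch")
        self.patches = p

    @property
    def size(self) -> int:
        return self.patches.shape[1]

    def __len__(self) -> int:
        return self.patches.shape[0]


@dataclass
class GroupedTemplate:
    """A bank of k normalised subgroup templates with quality scores."""

    templates: np.ndarray  # k x s x s, each zero-mean unit-norm
    assignment: np.ndarray  # patch index -> subgroup (0-based)
    quality_per_group: np.ndarray  # k means of within-group correlations
    quality_R: float
    channel: str = "green"
    seed: int | None = None

    @property
    def k(self) -> int:
        return self.templates.shape[0]

    @property
    def size(self) -> int:
        return self.templates.shape[1]


def normalize_patch(patch: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-L2-norm copy; an exactly flat patch maps to zeros."""
    p = np.asarray(patch, dtype=np.float64)
    p = p - p.mean()
    n = np.linalg.norm(p)
    if n > 0:
        p = p / n
    return p


def extract_patches(
    layer: PlantLayer | np.ndarray,
    centers: PointSet,
    size: int = DEFAULT_PATCH_SIZE,
) -> PatchSet:
    """Cut ``size`` x ``size`` windows centred on each point.

    A window starts at ``round(center) - size // 2``; centers whose window
    would cross the layer border are skipped and counted in ``n_skipped``.
    Raises if no center is retainable.
    """
    values = layer.values if isinstance(layer, PlantLayer) else np.asarray(layer)
    channel = layer.channel if isinstance(layer, PlantLayer) else "green"
    H, W = values.shape
    half = size // 2
    patches = []
    kept = []
    skipped = 0
    for col, row in np.atleast_2d(centers.points):
        r0 = int(round(row)) - half
        c0 = int(round(col)) - half
        if r0 < 0 or c0 < 0 or r0 + size > H or c0 + size > W:
            skipped += 1
            continue
        patches.append(values[r0 : r0 + size, c0 : c0 + size])
        kept.append((col, row))
    if not patches:
        raise ValueError(
            f"no retainable patch centers ({skipped} skipped at the border)"
        )
    return PatchSet(
        patches=np.stack(patches),
        source_points=PointSet(np.array(kept), label=centers.label),
        channel=channel,
        n_skipped=skipped,
    )


def build_grouped_template(
    patches: PatchSet,
    k: int = DEFAULT_N_SUBGROUPS,
    seed: int | None = 0,
) -> GroupedTemplate:
    """Cluster normalised patches into k subgroups and average each.

    Clustering is k-means (10 restarts, fixed seed, deterministic) on the
    flattened zero-mean unit-norm patches; each subgroup template is the
    per-pixel mean of its member patches, re-normalised.  ``quality_R`` is
    the mean correlation between patches and their assigned subgroup
    template.
    """
    n = len(patches)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds patch count n={n}")
    s = patches.size
    normed = np.stack([normalize_patch(p) for p in patches.patches])
    flat = normed.reshape(n, s * s)
    if k == 1:
        assignment = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        assignment = km.fit_predict(flat)
    templates = np.empty((k, s, s))
    for g in range(k):
        members = normed[assignment == g]
        templates[g] = normalize_patch(members.mean(axis=0))
    corr = np.einsum("nij,nij->n", normed, templates[assignment])
    quality_per_group = np.array(
        [corr[assignment == g].mean() for g in range(k)]
    )
    return GroupedTemplate(
        templates=templates,
        assignment=assignment,
        quality_per_group=quality_per_group,
        quality_R=float(corr.mean()),
        channel=patches.channel,
        seed=seed,
    )


def template_quality(gt: GroupedTemplate, patches: PatchSet):
    """Mean best-match correlation of patches against the template bank.

    Returns ``(R, per_group_means)`` where each patch scores against its
    best-matching subgroup template (zero-normalised correlation) and
    per-group means are taken over the patches each subgroup wins.
    """
    if patches.size != gt.size:
        raise ValueError("patch size does not match template size")
    normed = np.stack([normalize_patch(p) for p in patches.patches])
    flat = normed.reshape(len(patches), -1)
    tflat = gt.templates.reshape(gt.k, -1)
    corr = flat @ tflat.T  # n x k
    best = corr.argmax(axis=1)
    best_corr = corr[np.arange(len(patches)), best]
    per_group = np.array(
        [best_corr[best == g].mean() if (best == g).any() else np.nan for g in range(gt.k)]
    )
    return float(best_corr.mean()), per_group


def compare_channels(
    image: GeoImage,
    plants: PlantMask,
    centers: PointSet,
    k: int = DEFAULT_N_SUBGROUPS,
    seed: int | None = 0,
    size: int = DEFAULT_PATCH_SIZE,
):
    """Template quality for each colour channel, masked vs raw source layer.

    Builds and scores a grouped template from patches taken from (a) the
    background-zeroed plant layer and (b) the raw band, for each of R/G/B.
    Returns a nested dict ``{"masked"|"raw": {channel: R}}`` (import into
    a DataFrame for display).
    """
    table: dict[str, dict[str, float]] = {"masked": {}, "raw": {}}
    for channel in ("red", "green", "blue"):
        masked_layer = make_plant_layer(image, plants, channel=channel)
        raw_layer = PlantLayer(
            values=image.band(channel).astype(np.float64), channel=channel
        )
        for kind, layer in (("masked", masked_layer), ("raw", raw_layer)):
            patches = extract_patches(layer, centers, size=size)
            gt = build_grouped_template(patches, k=k, seed=seed)
            R, _ = template_quality(gt, patches)
            table[kind][channel] = R
    return table


# ---------------------------------------------------------------------------
# template archive (single JSON manifest; floats round-trip exactly)


def save_template(gt: GroupedTemplate, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "k": gt.k,
        "size": gt.size,
        "channel": gt.channel,
        "seed": gt.seed,
        "quality_R": gt.quality_R,
        "quality_per_group": gt.quality_per_group.tolist(),
        "assignment": gt.assignment.tolist(),
        "templates": gt.templates.tolist(),
    }
    path.write_text(json.dumps(doc))
    return path


def load_template(path: str | Path) -> GroupedTemplate:
    doc = json.loads(Path(path).read_text())
    return GroupedTemplate(
        templates=np.array(doc["templates"], dtype=np.float64),
        assignment=np.array(doc["assignment"], dtype=int),
        quality_per_group=np.array(doc["quality_per_group"], dtype=np.float64),
        quality_R=float(doc["quality_R"]),
        channel=doc.get("channel", "green"),
        seed=doc.get("seed"),
    )
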