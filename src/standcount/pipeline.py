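"""End-to-end seedling counting, packaged as scikit-learn style estimators.

:class:`GroupedTemplateMatcher` is the core detector: ``fit`` builds the
grouped template bank from sample seedling locations, ``predict`` returns
detections for an image.  :class:`SeedlingCounter` wraps it together with
plot aggregation and accuracy evaluation for whole experiments.  The
module-level helpers (``sample_patch_centers``, ``run_experiment``) are thin
wrappers used by the command-line interface and the test-bench scripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import counting, matching, metrics, templates, vegetation
from .io_geo import GeoImage, PlotMap, PointSet
from .matching import Detection
from .synthetic_field import Experiment
from .vegetation import PlantLayer

__all__ = [
    "GroupedTemplateMatcher",
    "SeedlingCounter",
    "ExperimentResult",
    "sample_patch_centers",
    "run_experiment",
]


class GroupedTemplateMatcher(BaseEstimator):
    """Seedling detector: green-ratio segmentation + grouped-template ZNCC.

    Parameters
    ----------
    green_ratio_threshold : float, default 0.36
        Pixels with green ratio strictly above this classify as plant.
    min_component_px : int, default 30
        Connected components smaller than this are discarded as soil.
    connectivity : {4, 8}, default 8
        Pixel connectivity used when merging plant objects.
    patch_size : int, default 20
        Side length (px) of sample patches and subgroup templates.
    n_subgroups : int, default 10
        Number of template subgroups (k in the grouped template).
    channel : {"red", "green", "blue"}, default "green"
        Band used for the classified plant layer.
    match_threshold : float, default 0.5
        Minimum ZNCC (strict) for a detection.
    nms_radius : float, default 10
        Non-maximum-suppression radius in pixels (half a template).
    random_state : int, default 0
        Seed for the patch clustering.

    Attributes
    ----------
    template_ : GroupedTemplate
        Fitted subgroup template bank.
    quality_R_ : float
        Mean correlation between training patches and their subgroup
        templates (the template quality score).
    n_patches_ : int
        Number of training patches retained.
    """

    def __init__(
        self,
        green_ratio_threshold: float = 0.36,
        min_component_px: int = 30,
        connectivity: int = 8,
        patch_size: int = 20,
        n_subgroups: int = 10,
        channel: str = "green",
        match_threshold: float = 0.5,
        nms_radius: float = 10.0,
        random_state: int = 0,
    ):
        self.green_ratio_threshold = green_ratio_threshold
        self.min_component_px = min_component_px
        self.connectivity = connectivity
        self.patch_size = patch_size
        self.n_subgroups = n_subgroups
        self.channel = channel
        self.match_threshold = match_threshold
        self.nms_radius = nms_radius
        self.random_state = random_state

    # ------------------------------------------------------------------
    def segment(self, image: GeoImage) -> PlantLayer:
        """Part-I segmentation of one image into a zeroed plant layer."""
        return vegetation.segment(
            image,
            threshold=self.green_ratio_threshold,
            min_size=self.min_component_px,
            connectivity=self.connectivity,
            channel=self.channel,
        )

    def fit(self, X, y=None):
        """Build the grouped template from sample seedling centers.

        Parameters
        ----------
        X : GeoImage or sequence of GeoImage
            Source image(s); each is segmented into a plant layer first.
        y : PointSet / array of (col, row), or a sequence of them
            Sample seedling centers per image.
        """
        if isinstance(X, GeoImage):
            X, y = [X], [y]
        if y is None or len(X) != len(y):
            raise ValueError("fit needs one center set per image")
        all_patches = []
        kept_points = []
        skipped = 0
        for image, centers in zip(X, y):
            if not isinstance(centers, PointSet):
                centers = PointSet(np.asarray(centers, dtype=float))
            if len(centers) == 0:
                continue
            layer = self.segment(image)
            try:
                ps = templates.extract_patches(layer, centers, size=self.patch_size)
            except ValueError:
                skipped += len(centers)
                continue
            all_patches.append(ps.patches)
            kept_points.append(ps.source_points.points)
            skipped += ps.n_skipped
        if not all_patches:
            raise ValueError("no usable sample patches")
        patch_set = templates.PatchSet(
            patches=np.concatenate(all_patches),
            source_points=PointSet(np.concatenate(kept_points)),
            channel=self.channel,
            n_skipped=skipped,
        )
        self.template_ = templates.build_grouped_template(
            patch_set, k=self.n_subgroups, seed=self.random_state
        )
        self.quality_R_ = self.template_.quality_R
        self.n_patches_ = len(patch_set)
        return self

    def score_map(self, image: GeoImage) -> matching.ScoreMap:
        self._check_fitted()
        return matching.combined_score_map(self.segment(image), self.template_)

    def predict(self, image: GeoImage) -> list[Detection]:
        """Detect seedlings in one image."""
        return matching.detect_seedlings(
            self.score_map(image),
            threshold=self.match_threshold,
            nms_radius=self.nms_radius,
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "template_"):
            raise RuntimeError("estimator is not fitted; call fit() first")


@dataclass
class ExperimentResult:
    counts: list[counting.PlotCount]
    report: metrics.AccuracyReport
    quality_R: float
    n_unassigned: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plot_id": [c.plot_id for c in self.counts],
                "digital_count": [c.digital_count for c in self.counts],
                "density_per_m2": [c.density for c in self.counts],
                "manual_count": [c.manual_count for c in self.counts],
            }
        )


class SeedlingCounter(BaseEstimator):
    """Whole-experiment stand counting built on GroupedTemplateMatcher.

    ``fit`` takes an iterable of (image, sample centers) and builds the
    template; ``predict`` maps a sequence of georeferenced images plus a
    plot map to per-plot digital counts.
    """

    def __init__(
        self,
        green_ratio_threshold: float = 0.36,
        min_component_px: int = 30,
        connectivity: int = 8,
        patch_size: int = 20,
        n_subgroups: int = 10,
        channel: str = "green",
        match_threshold: float = 0.5,
        nms_radius: float = 10.0,
        random_state: int = 0,
    ):
        self.green_ratio_threshold = green_ratio_threshold
        self.min_component_px = min_component_px
        self.connectivity = connectivity
        self.patch_size = patch_size
        self.n_subgroups = n_subgroups
        self.channel = channel
        self.match_threshold = match_threshold
        self.nms_radius = nms_radius
        self.random_state = random_state

    def _matcher(self) -> GroupedTemplateMatcher:
        return GroupedTemplateMatcher(**self.get_params())

    def fit(self, X, y=None):
        matcher = self._matcher()
        matcher.fit(X, y)
        self.matcher_ = matcher
        self.quality_R_ = matcher.quality_R_
        return self

    def predict(
        self,
        images,
        plots: PlotMap,
        manual: pd.DataFrame | None = None,
    ) -> ExperimentResult:
        """Detect, aggregate per plot, and (when manual counts are given)
        evaluate accuracy."""
        if not hasattr(self, "matcher_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
        assignment: dict[str, list[Detection]] = {p.plot_id: [] for p in plots.plots}
        n_unassigned = 0
        for image in images:
            dets = self.matcher_.predict(image)
            assign, unassigned = counting.assign_to_plots(dets, plots, image)
            n_unassigned += len(unassigned)
            for pid, ds in assign.items():
                assignment[pid].extend(ds)
        plot_counts = counting.summarize(assignment, plots, manual)
        report = None
        if manual is not None:
            pairs = [
                (c.manual_count, c.digital_count)
                for c in plot_counts
                if c.manual_count is not None
            ]
            report = metrics.evaluate(pairs, verbose=True)
        return ExperimentResult(
            counts=plot_counts,
            report=report,
            quality_R=self.quality_R_,
            n_unassigned=n_unassigned,
        )


def sample_patch_centers(
    experiment: Experiment,
    n_patches: int = 1000,
    seed: int | None = None,
    jitter_px: float = 1.0,
) -> dict[int, np.ndarray]:
    """Pick ~n_patches sample seedling locations from the first plots.

    Mirrors the field protocol of hand-digitizing sample seedlings in a
    subset of plots: plots are consumed in order until the requested number
    of centers is reached, the selection is trimmed at random, and each
    center gets isotropic Gaussian "click error" of ``jitter_px`` px (std) —
    hand-marked patch centers are never pixel-perfect, and that positional
    noise is part of what limits template quality.
    """
    if seed is None:
        seed = experiment.config.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9721]))
    chosen: dict[int, np.ndarray] = {}
    total = 0
    for i, truth in enumerate(experiment.truth.plots):
        if total >= n_patches:
            break
        chosen[i] = truth.centers_px
        total += truth.count
    if total > n_patches:
        # drop a random subset of the final plot's centers
        last = max(chosen)
        excess = total - n_patches
        pts = chosen[last]
        keep = rng.permutation(len(pts))[: len(pts) - excess]
        chosen[last] = pts[np.sort(keep)]
    if jitter_px > 0:
        chosen = {
            i: pts + rng.normal(0.0, jitter_px, size=pts.shape)
            for i, pts in chosen.items()
        }
    return chosen


def run_experiment(
    experiment: Experiment,
    counter: SeedlingCounter | None = None,
    n_patches: int = 1000,
) -> ExperimentResult:
    """Full pipeline on a synthetic experiment: fit template on truth-centred
    patches, detect in every plot, aggregate and score against truth.

    Tiles are rendered lazily twice (once for template building on the
    sampled plots, once for detection) to keep memory flat.
    """
    if counter is None:
        counter = SeedlingCounter(random_state=experiment.config.seed)
    centers = sample_patch_centers(experiment, n_patches=n_patches)
    fit_images = [experiment.plot_image(i) for i in sorted(centers)]
    fit_centers = [centers[i] for i in sorted(centers)]
    counter.fit(fit_images, fit_centers)
    del fit_images

    def images():
        for _pid, geo, _truth in experiment.iter_plots():
            yield geo

    return counter.predict(
        images(), experiment.plot_map, manual=experiment.manual_counts()
    )
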