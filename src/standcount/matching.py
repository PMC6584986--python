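"""Template matching on the classified plant layer.

Scores are zero-normalised cross-correlation (ZNCC): the Pearson
correlation between the s x s window around a candidate center and the
template.  ZNCC is invariant to positive affine intensity changes, which
absorbs illumination differences across a field.  Background zeros inside
the window are part of the signal — matching runs on the classified layer
whose non-plant pixels are zeroed, and a seedling surrounded by zeroed soil
is exactly what the templates encode.

The combined score of a grouped template is the pointwise maximum over the
k subgroup maps.  Candidate centers are *valid* only when the full template
footprint lies inside the image and overlaps at least one plant-mask pixel;
everything else is flagged invalid and never thresholded.  Detections are
score-thresholded (strict >) and thinned by greedy non-maximum suppression.

The heavy lifting uses FFT correlation with one shared forward transform of
the layer per plot; the result is checked against the direct ZNCC formula
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from .templates import GroupedTemplate, normalize_patch
from .vegetation import PlantLayer

__all__ = [
    "ScoreMap",
    "Detection",
    "zncc_map",
    "combined_score_map",
    "detect_seedlings",
    "match_detections",
    "threshold_sweep",
]

DEFAULT_MATCH_THRESHOLD = 0.5
DEFAULT_NMS_RADIUS = 10.0

_VAR_EPS = 1e-12


@dataclass
class Detection:
    """A matched seedling center in pixel coordinates."""

    col: int
    row: int
    score: float
    subgroup: int  # 1-based index of the winning subgroup template


@dataclass
class ScoreMap:
    """Best-over-subgroups ZNCC score per pixel with a validity mask."""

    scores: np.ndarray  # H x W float, -inf outside the valid region
    argmax_group: np.ndarray  # H x W int, 1..k where valid, 0 elsewhere
    valid: np.ndarray  # H x W bool
    k: int


def _window_sums(arr: np.ndarray, s: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding s x s window sums of arr and arr**2 ('valid' placement grid).

    Uses a zero-padded integral image; float64 keeps the sums exact for
    8-bit intensity content at any realistic raster size.
    """
    a = np.asarray(arr, dtype=np.float64)
    ii = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
    np.cumsum(a, axis=0, out=ii[1:, 1:])
    np.cumsum(ii[1:, 1:], axis=1, out=ii[1:, 1:])
    s1 = ii[s:, s:] - ii[:-s, s:] - ii[s:, :-s] + ii[:-s, :-s]
    ii2 = np.zeros_like(ii)
    np.cumsum(a * a, axis=0, out=ii2[1:, 1:])
    np.cumsum(ii2[1:, 1:], axis=1, out=ii2[1:, 1:])
    s2 = ii2[s:, s:] - ii2[:-s, s:] - ii2[s:, :-s] + ii2[:-s, :-s]
    return s1, s2


class _LayerFFT:
    """Shared rfft2 of a layer for correlating many same-size templates."""

    def __init__(self, values: np.ndarray, s: int):
        self.values = np.asarray(values, dtype=np.float64)
        H, W = self.values.shape
        if s > min(H, W):
            raise ValueError(f"template ({s}px) larger than layer {H}x{W}")
        self.s = s
        self.out_shape = (H - s + 1, W - s + 1)
        self.fshape = (
            sp_fft.next_fast_len(H, real=True),
            sp_fft.next_fast_len(W, real=True),
        )
        self.f_layer = sp_fft.rfft2(self.values, self.fshape)
        win_sum, win_sq = _window_sums(self.values, s)
        n = s * s
        var = win_sq - win_sum * win_sum / n
        np.maximum(var, 0.0, out=var)
        self.win_std = np.sqrt(var)  # = ||window - mean|| over the footprint

    def correlate(self, template: np.ndarray) -> np.ndarray:
        """ZNCC against one template over the valid placement grid."""
        t = normalize_patch(template)
        f_t = sp_fft.rfft2(t[::-1, ::-1], self.fshape)
        conv = sp_fft.irfft2(self.f_layer * f_t, self.fshape)
        num = conv[self.s - 1 : self.s - 1 + self.out_shape[0],
                   self.s - 1 : self.s - 1 + self.out_shape[1]]
        # t is zero-mean unit-norm: ZNCC = (w . t) / ||w - mean(w)||
        ok = self.win_std > _VAR_EPS
        out = np.zeros(self.out_shape)
        np.divide(num, self.win_std, out=out, where=ok)
        np.clip(out, -1.0, 1.0, out=out)
        return out


def _center_offset(s: int) -> int:
    """Row/col of a window's center pixel relative to its top-left corner.

    Matches patch extraction, where a window starts at center - s // 2.
    """
    return s // 2


def zncc_map(layer: PlantLayer | np.ndarray, template: np.ndarray) -> np.ndarray:
    """Full-frame ZNCC of one template; NaN where the footprint leaves the image.

    The value at (row, col) is the Pearson correlation between the template
    and the window whose center pixel is (row, col).  Windows with (near)
    zero variance score 0 — a flat window is never a seedling.
    """
    values = layer.values if isinstance(layer, PlantLayer) else np.asarray(layer)
    template = np.asarray(template, dtype=np.float64)
    s = template.shape[0]
    if template.shape != (s, s):
        raise ValueError("template must be square")
    eng = _LayerFFT(values, s)
    valid = eng.correlate(template)
    out = np.full(values.shape, np.nan)
    off = _center_offset(s)
    out[off : off + valid.shape[0], off : off + valid.shape[1]] = valid
    return out


def _score_crop(values: np.ndarray, gt: GroupedTemplate):
    """Best-over-subgroups ZNCC and winning subgroup on one array."""
    eng = _LayerFFT(values, gt.size)
    best = np.full(eng.out_shape, -np.inf)
    group = np.zeros(eng.out_shape, dtype=np.int32)
    for g in range(gt.k):
        sc = eng.correlate(gt.templates[g])
        better = sc > best  # strict: ties keep the lower subgroup index
        best[better] = sc[better]
        group[better] = g + 1
    return best, group


def combined_score_map(
    layer: PlantLayer,
    gt: GroupedTemplate,
    require_mask: bool = True,
) -> ScoreMap:
    """Best score over the k subgroup templates, restricted to valid centers.

    A center is valid when its full footprint fits in the image and (when
    the layer carries a plant mask and ``require_mask`` is true) the
    footprint contains at least one plant pixel; scores elsewhere are -inf
    and never enter thresholding.  Ties between subgroups go to the lowest
    subgroup index.

    When a plant mask is present the correlation is evaluated only over the
    padded bounding boxes of the mask components — plant cover is sparse,
    so this skips most of the frame.  Values are identical to the
    full-frame computation because every valid center's footprint lies
    inside its padded box.
    """
    s = gt.size
    H, W = layer.values.shape
    if s > min(H, W):
        raise ValueError(f"template ({s}px) larger than layer {H}x{W}")
    off = _center_offset(s)
    oh, ow = H - s + 1, W - s + 1

    masked = require_mask and layer.mask is not None
    if masked:
        mask_sum, _ = _window_sums(layer.mask.mask.astype(np.float64), s)
        in_valid = mask_sum > 0.5
    else:
        in_valid = np.ones((oh, ow), dtype=bool)

    best = np.full((oh, ow), -np.inf)
    group = np.zeros((oh, ow), dtype=np.int32)
    if masked:
        from scipy import ndimage as _ndi

        for sl in _ndi.find_objects(layer.mask.labels):
            if sl is None:
                continue
            r0 = max(sl[0].start - s + 1, 0)
            r1 = min(sl[0].stop + s - 1, H)
            c0 = max(sl[1].start - s + 1, 0)
            c1 = min(sl[1].stop + s - 1, W)
            if r1 - r0 < s or c1 - c0 < s:
                continue
            b, g = _score_crop(layer.values[r0:r1, c0:c1], gt)
            dst = (slice(r0, r0 + b.shape[0]), slice(c0, c0 + b.shape[1]))
            upd = b > best[dst]
            best[dst][upd] = b[upd]
            group[dst][upd] = g[upd]
    else:
        best, group = _score_crop(layer.values, gt)

    scores = np.full((H, W), -np.inf)
    argmax = np.zeros((H, W), dtype=np.int32)
    valid = np.zeros((H, W), dtype=bool)
    sl = (slice(off, off + oh), slice(off, off + ow))
    scores[sl] = np.where(in_valid, best, -np.inf)
    argmax[sl] = np.where(in_valid, group, 0)
    valid[sl] = in_valid
    return ScoreMap(scores=scores, argmax_group=argmax, valid=valid, k=gt.k)


def detect_seedlings(
    sm: ScoreMap,
    threshold: float = DEFAULT_MATCH_THRESHOLD,
    nms_radius: float = DEFAULT_NMS_RADIUS,
) -> list[Detection]:
    """Threshold the score map and thin it by greedy non-maximum suppression.

    Candidates with score strictly above ``threshold`` are visited in
    descending score order (ties: lower row, then lower col); a candidate is
    accepted iff no previously accepted detection lies within Euclidean
    distance < ``nms_radius``.  The result is sorted by descending score and
    independent of enumeration order.
    """
    if not 0.0 < threshold <= 1.0:
        # 1.0 is allowed: maximal stringency, never exceeded (strict >)
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    if nms_radius < 1:
        raise ValueError("nms_radius must be >= 1")
    cand = sm.valid & (sm.scores > threshold)
    rows, cols = np.nonzero(cand)
    if rows.size == 0:
        return []
    scores = sm.scores[rows, cols]
    order = np.lexsort((cols, rows, -scores))
    rows, cols, scores = rows[order], cols[order], scores[order]
    groups = sm.argmax_group[rows, cols]

    # grid-hashed greedy NMS: only 3x3 neighbouring cells can conflict
    cell = max(int(np.ceil(nms_radius)), 1)
    occupied: dict[tuple[int, int], list[int]] = {}
    r2 = nms_radius * nms_radius
    acc_r: list[int] = []
    acc_c: list[int] = []
    accepted: list[Detection] = []
    for i in range(rows.size):
        r, c = int(rows[i]), int(cols[i])
        key = (r // cell, c // cell)
        clash = False
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for j in occupied.get((key[0] + dr, key[1] + dc), ()):
                    dy = acc_r[j] - r
                    dx = acc_c[j] - c
                    if dy * dy + dx * dx < r2:
                        clash = True
                        break
                if clash:
                    break
            if clash:
                break
        if clash:
            continue
        occupied.setdefault(key, []).append(len(acc_r))
        acc_r.append(r)
        acc_c.append(c)
        accepted.append(
            Detection(col=c, row=r, score=float(scores[i]), subgroup=int(groups[i]))
        )
    return accepted


def match_detections(
    detections: list[Detection],
    truth: np.ndarray,
    tol: float,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detections to truth centers.

    Detections are visited in descending score order; each claims its
    nearest unclaimed truth point within ``tol`` pixels.  Returns
    ``(tp, fp, fn)``.
    """
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if truth.size == 0:
        return 0, len(detections), 0
    from scipy.spatial import cKDTree

    tree = cKDTree(truth)
    claimed = np.zeros(len(truth), dtype=bool)
    tp = 0
    for det in sorted(detections, key=lambda d: -d.score):
        idxs = tree.query_ball_point([det.col, det.row], tol)
        best_j, best_d = -1, np.inf
        for j in idxs:
            if claimed[j]:
                continue
            d = (truth[j, 0] - det.col) ** 2 + (truth[j, 1] - det.row) ** 2
            if d < best_d:
                best_d, best_j = d, j
        if best_j >= 0:
            claimed[best_j] = True
            tp += 1
    fp = len(detections) - tp
    fn = len(truth) - tp
    return tp, fp, fn


def threshold_sweep(
    sm: ScoreMap,
    thresholds: list[float],
    truth: np.ndarray | None = None,
    tol: float = 10.0,
    nms_radius: float = DEFAULT_NMS_RADIUS,
) -> list[dict]:
    """Detection count (and precision/recall against truth) per threshold.

    One score map is reused across stringencies, so the count column is
    guaranteed non-increasing in the threshold.
    """
    if sorted(thresholds) != list(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    out = []
    for t in thresholds:
        dets = detect_seedlings(sm, threshold=t, nms_radius=nms_radius)
        rec: dict = {"threshold": t, "count": len(dets)}
        if truth is not None:
            tp, fp, fn = match_detections(dets, truth, tol)
            rec["precision"] = tp / (tp + fp) if (tp + fp) else 1.0
            rec["recall"] = tp / (tp + fn) if (tp + fn) else 1.0
        out.append(rec)
    return out
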