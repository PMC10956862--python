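"""Spine mask extraction and center-curve computation.

From the LCM label map: pick the label that looks like the spine (bright
and centered), binarize it, keep the largest connected component, detect
the mask walls with a Canny edge map, and reduce the walls to a per-row
midline (the center curve) that the Cobb construction consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import feature, measure

__all__ = [
    "BinaryMask",
    "CenterCurve",
    "select_spine_label",
    "spine_binary_mask",
    "spine_mask_by_background_subtraction",
    "canny_edges",
    "extract_center_curve",
]


@dataclass
class BinaryMask:
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class CenterCurve:
    """Ordered per-row midline of the spine mask.

    points : (n, 2) array of (row, col_real); rows strictly increasing.
    """

    points: np.ndarray
    smoothed: bool = False
    window: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if np.any(np.diff(self.points[:, 0]) <= 0):
            raise ValueError("curve rows must be strictly increasing")

    @property
    def rows(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def cols(self) -> np.ndarray:
        return self.points[:, 1]


def select_spine_label(labels: np.ndarray, image: np.ndarray, override: int | None = None) -> int:
    """Label most likely to be the spine: bright and centered.

    Score = (mean intensity of the region) x (fraction of its pixels inside
    the central half of the columns); ties broken by larger area.  Pass
    ``override`` to force a label.
    """
    labels = np.asarray(labels)
    image = np.asarray(image, dtype=float)
    if labels.shape != image.shape:
        raise ValueError("labels and image shapes differ")
    ids = np.unique(labels)
    if override is not None:
        if override not in ids:
            raise ValueError(f"label {override} not present")
        return int(override)
    w = labels.shape[1]
    central = np.zeros_like(labels, dtype=bool)
    central[:, w // 4 : (3 * w) // 4] = True
    best = None
    for lab in ids:
        sel = labels == lab
        area = int(sel.sum())
        score = float(image[sel].mean()) * float(central[sel].mean())
        key = (score, area)
        if best is None or key > best[0]:
            best = (key, int(lab))
    return best[1]


def spine_binary_mask(labels: np.ndarray, spine_label: int) -> BinaryMask:
    """Binary mask of one label, reduced to its largest 4-connected component."""
    labels = np.asarray(labels)
    sel = labels == spine_label
    if not sel.any():
        raise ValueError(f"label {spine_label} not present in label map")
    comp = measure.label(sel, connectivity=1)
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    return BinaryMask(mask=comp == np.argmax(sizes))


def spine_mask_by_background_subtraction(
    labels: np.ndarray, image: np.ndarray, threshold: float | None = None
) -> BinaryMask:
    """Spine mask as the union of all non-background labels.

    An elongated curved structure can legitimately come out of the LCM
    clustering as several labels (its trackers accumulate at a handful of
    modes along the column), so the mask is built the other way around:
    labels whose mean image intensity falls below ``threshold`` are declared
    background and subtracted; everything else is spine.  With
    ``threshold=None`` the midpoint between the darkest and brightest label
    means is used (a histogram split over a handful of label means is not
    meaningful); if all labels are equally bright everything is kept.  The
    largest 4-connected foreground component is returned.
    """
    labels = np.asarray(labels)
    image = np.asarray(image, dtype=float)
    if labels.shape != image.shape:
        raise ValueError("labels and image shapes differ")
    ids = np.unique(labels)
    means = np.array([image[labels == lab].mean() for lab in ids])
    if threshold is None:
        if means.max() - means.min() < 1e-12:
            keep = np.ones(len(ids), dtype=bool)  # single effective level
        else:
            thr = 0.5 * (means.min() + means.max())
            keep = means > thr
    else:
        keep = means > threshold
    fg = np.isin(labels, ids[keep])
    if not fg.any():
        raise ValueError("background subtraction removed every label")
    comp = measure.label(fg, connectivity=1)
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    return BinaryMask(mask=comp == np.argmax(sizes))


def canny_edges(mask: BinaryMask | np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Canny edge map of the binary mask (standard thresholds).

    The mask is padded with one background pixel before detection so a wall
    lying exactly on the frame border still registers as an edge.
    """
    m = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    padded = np.pad(m, 1, mode="constant", constant_values=False)
    e = feature.canny(padded.astype(float), sigma=sigma)
    return e[1:-1, 1:-1]


def _moving_average(x: np.ndarray, half_width: int) -> np.ndarray:
    """Centered moving average of width 2*half_width+1; the window shrinks
    symmetrically at the ends (always an average of in-range values)."""
    if half_width <= 0:
        return x.copy()
    n = len(x)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    out = np.empty(n)
    for i in range(n):
        k = min(half_width, i, n - 1 - i)
        out[i] = (cs[i + k + 1] - cs[i - k]) / (2 * k + 1)
    return out


def extract_center_curve(
    edges: np.ndarray,
    smooth_window: int = 5,
    method: str = "wall_midpoint",
    trim_partial_rows: bool = True,
) -> CenterCurve:
    """Per-row midline of an edge map.

    ``wall_midpoint`` (default): the midpoint of the leftmost and rightmost
    edge pixels per row — robust to texture edges inside the spine.
    ``mean``: the mean column of all edge pixels per row.  Rows inside the
    spanned range with no edge pixels are filled by linear interpolation,
    then a centered moving average of width ``2*smooth_window + 1`` smooths
    the columns.

    With ``trim_partial_rows`` (default), leading and trailing rows whose
    wall-to-wall span falls short of the local full span are treated as
    unreliable: at a tilted end of the structure these rows cut through a
    corner rather than the full cross-section, so their midpoints are
    biased toward the surviving corner by up to half the structure width —
    enough to corrupt the chord of the downstream angle construction.
    Their midline values are replaced by a linear extrapolation of the
    reliable midline, keeping the curve's row span equal to the span of
    the edge map.
    """
    if method not in ("wall_midpoint", "mean"):
        raise ValueError("method must be 'wall_midpoint' or 'mean'")
    e = np.asarray(edges, dtype=bool)
    rows_with = np.nonzero(e.any(axis=1))[0]
    if len(rows_with) < 2:
        raise ValueError("need edges in at least 2 rows")
    r0, r1 = rows_with[0], rows_with[-1]
    n = r1 - r0 + 1
    mid = np.full(n, np.nan)
    span = np.full(n, np.nan)
    for r in rows_with:
        cset = np.nonzero(e[r])[0]
        span[r - r0] = cset[-1] - cset[0]
        if method == "wall_midpoint":
            mid[r - r0] = 0.5 * (cset[0] + cset[-1])
        else:
            mid[r - r0] = cset.mean()
    rows = np.arange(r0, r1 + 1, dtype=float)
    have = ~np.isnan(mid)
    mid[~have] = np.interp(rows[~have], rows[have], mid[have])
    span[~have] = 0.0

    lo, hi = 0, n - 1
    if trim_partial_rows and n > 20:
        # reference full span near each end: high percentile of the spans in
        # a window just inward (the local span varies with the structure's
        # tilt, so the global median is not a fair bar at a steep end)
        win = min(40, n // 2)
        bar_top = 0.9 * np.nanpercentile(span[:win], 90)
        bar_bot = 0.9 * np.nanpercentile(span[-win:], 90)
        while lo < hi and span[lo] < bar_top:
            lo += 1
        while hi > lo and span[hi] < bar_bot:
            hi -= 1
    if hi - lo < 2:
        lo, hi = 0, n - 1
    core = _moving_average(mid[lo : hi + 1], smooth_window)
    out = np.empty(n)
    out[lo : hi + 1] = core
    k = min(8, hi - lo)  # end slope over the nearest reliable rows
    if lo > 0:
        sl = np.polyfit(rows[lo : lo + k + 1], core[: k + 1], 1)[0]
        out[:lo] = core[0] + sl * (rows[:lo] - rows[lo])
    if hi < n - 1:
        sl = np.polyfit(rows[hi - k : hi + 1], core[-k - 1 :], 1)[0]
        out[hi + 1 :] = core[-1] + sl * (rows[hi + 1 :] - rows[hi])
    return CenterCurve(
        points=np.column_stack([rows, out]),
        smoothed=smooth_window > 0,
        window=smooth_window,
    )
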