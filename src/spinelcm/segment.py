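"""2D unsupervised segmentation by local centers of mass.

The 1D LCM profile generalizes to images by scanning the frame with K
families of parallel lines (orientations evenly spaced over [0, 180)
degrees).  Along every scanline the 1D LCM is computed; the quantity
``C_n - n`` is a signed displacement along the line pointing from each
sample toward the center of mass of its homogeneous segment.  Averaging the
per-orientation displacement vectors at each pixel yields a displacement
field ``V`` under which all pixels of one region flow toward a common
accumulation set.

Tracker points (one per pixel) are then iterated in two phases:

* phase 1 — advection: ``x <- x + V(x)`` with bilinear interpolation of the
  field and clamping at the image border;
* phase 2 — consolidation: each tracker moves to the mean position of all
  trackers within ``merge_radius`` of it, collapsing the loose accumulation
  sets into tight modes.

Finally trackers within ``cluster_eps`` of one another (single linkage) are
assigned one label, and every pixel inherits the label of its tracker.  The
whole procedure is deterministic: there is no randomness anywhere.

`LCMSegmenter` packages the procedure as a scikit-learn style clustering
estimator whose sample matrix is the 2D image itself; the module functions
are thin wrappers used by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, ClusterMixin

from .lcm import LCMParams, lcm_fast_batch

__all__ = [
    "OrientationSet",
    "IterationSchedule",
    "ScanlineFamily",
    "LabelMap",
    "LCMSegmenter",
    "orientation_scanlines",
    "lcm_displacement_field",
    "converge_and_cluster",
    "segment_image",
]


@dataclass(frozen=True)
class OrientationSet:
    """K scan orientations evenly spaced over [0, 180) degrees.

    Angle 0 scans along image rows (samples advance with the column index);
    angle 90 scans along columns.
    """

    K: int = 180

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.K) * (180.0 / self.K)


@dataclass(frozen=True)
class IterationSchedule:
    """Tracker iteration plan.

    t_total : total iterations; the trailing ``t_phase2`` of them run the
        consolidation update instead of field advection.
    merge_radius : neighborhood radius (px) of the phase-2 mean.
    cluster_eps : single-linkage distance (px) for the final labeling.
    """

    t_total: int = 1000
    t_phase2: int = 250
    merge_radius: float = 2.0
    cluster_eps: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.t_phase2 <= self.t_total):
            raise ValueError("need 0 <= t_phase2 <= t_total")


@dataclass
class ScanlineFamily:
    """Parallel scanlines of one orientation.

    Lines are indexed by their integer offset along the unit normal; samples
    advance at unit spacing along the unit direction.  ``t_start[i]`` is the
    parameter of the first sample of line i, ``lengths[i]`` its sample
    count.  A point with normal/tangential projections (s, t) belongs to
    line ``round(s) - s0`` at local position ``t - t_start``.
    """

    angle_deg: float
    direction: np.ndarray   # (dr, dc), unit
    normal: np.ndarray      # (dr, dc), unit
    s0: int
    t_start: np.ndarray
    lengths: np.ndarray

    @property
    def n_lines(self) -> int:
        return len(self.t_start)

    def sample_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(rows, cols, valid) arrays of shape (n_lines, max_len)."""
        m = int(self.lengths.max())
        t = self.t_start[:, None] + np.arange(m)[None, :]
        s = (self.s0 + np.arange(self.n_lines))[:, None]
        rows = s * self.normal[0] + t * self.direction[0]
        cols = s * self.normal[1] + t * self.direction[1]
        valid = np.arange(m)[None, :] < self.lengths[:, None]
        return rows, cols, valid


@dataclass
class LabelMap:
    labels: np.ndarray
    n_regions: int
    tracker_points: np.ndarray | None = field(default=None, repr=False)


def _line_family(shape: tuple[int, int], angle_deg: float) -> ScanlineFamily | None:
    h, w = shape
    theta = np.radians(angle_deg)
    d = np.array([np.sin(theta), np.cos(theta)])
    n = np.array([np.cos(theta), -np.sin(theta)])
    # snap near-zero components so axis-aligned families are exact
    d[np.abs(d) < 1e-12] = 0.0
    n[np.abs(n) < 1e-12] = 0.0
    corners = np.array([[0, 0], [0, w - 1], [h - 1, 0], [h - 1, w - 1]], dtype=float)
    s_vals = corners @ n
    s_ids = np.arange(int(np.ceil(s_vals.min() - 0.5)), int(np.floor(s_vals.max() + 0.5)) + 1)
    if len(s_ids) == 0:
        return None
    # for each line, the t-interval where it intersects the pixel rectangle
    # expanded by half the line spacing (so off-line pixels still project
    # inside their nearest line's sample range)
    pad = 0.71
    lo = np.array([-pad, -pad])
    hi = np.array([h - 1 + pad, w - 1 + pad])
    t_lo = np.full(len(s_ids), -np.inf)
    t_hi = np.full(len(s_ids), np.inf)
    base = np.outer(s_ids.astype(float), n)  # point at t=0 per line
    for axis in range(2):
        if d[axis] == 0.0:
            keep = (base[:, axis] >= lo[axis]) & (base[:, axis] <= hi[axis])
            t_lo = np.where(keep, t_lo, np.inf)
            continue
        a = (lo[axis] - base[:, axis]) / d[axis]
        b = (hi[axis] - base[:, axis]) / d[axis]
        t_lo = np.maximum(t_lo, np.minimum(a, b))
        t_hi = np.minimum(t_hi, np.maximum(a, b))
    t_start = np.ceil(t_lo)
    lengths = np.floor(t_hi) - t_start + 1
    ok = np.isfinite(t_start) & (lengths >= 1)
    if not np.any(ok):
        return None
    return ScanlineFamily(
        angle_deg=angle_deg,
        direction=d,
        normal=n,
        s0=int(s_ids[ok][0]),
        t_start=t_start[ok].astype(float),
        lengths=lengths[ok].astype(int),
    )


def orientation_scanlines(shape: tuple[int, int], orient: OrientationSet) -> list[ScanlineFamily]:
    """Scanline geometry for every orientation (unit line and sample spacing)."""
    fams = []
    for ang in orient.angles_deg:
        fam = _line_family(shape, float(ang))
        if fam is not None:
            fams.append(fam)
    return fams


def lcm_displacement_field(
    image: np.ndarray,
    orient: OrientationSet = OrientationSet(),
    params: LCMParams = LCMParams(),
) -> np.ndarray:
    """Per-pixel displacement field V, shape (H, W, 2), mean over orientations.

    For each orientation the image is sampled bilinearly along every
    scanline, the 1D LCM profile is computed, and ``C_n - n`` (in sample
    units, i.e. pixels) times the line direction is assigned to each pixel
    via its nearest line and linear interpolation along it.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D grayscale")
    h, w = img.shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    V = np.zeros((h, w, 2))
    fams = orientation_scanlines(img.shape, orient)
    for fam in fams:
        rows, cols, valid = fam.sample_coords()
        F = map_coordinates(img, [rows.ravel(), cols.ravel()], order=1, mode="nearest")
        F = F.reshape(rows.shape)
        C = lcm_fast_batch(F, fam.lengths, params)
        idx = np.arange(1, F.shape[1] + 1, dtype=float)[None, :]
        disp = C - idx          # signed displacement along the line, px
        disp[~valid] = 0.0
        # project every pixel onto the family
        s = rr * fam.normal[0] + cc * fam.normal[1]
        t = rr * fam.direction[0] + cc * fam.direction[1]
        li = np.clip(np.rint(s).astype(int) - fam.s0, 0, fam.n_lines - 1)
        u = t - fam.t_start[li]
        u = np.clip(u, 0.0, (fam.lengths[li] - 1).astype(float))
        u0 = np.floor(u).astype(int)
        u1 = np.minimum(u0 + 1, fam.lengths[li] - 1)
        frac = u - u0
        dval = disp[li, u0] * (1.0 - frac) + disp[li, u1] * frac
        V[:, :, 0] += dval * fam.direction[0]
        V[:, :, 1] += dval * fam.direction[1]
    V /= max(len(fams), 1)
    return V


def _collapse(points: np.ndarray, weights: np.ndarray, precision: float = 0.25):
    """Merge coincident trackers (within `precision`) into weighted reps."""
    q = np.round(points / precision).astype(np.int64)
    _, idx, inv = np.unique(q, axis=0, return_index=True, return_inverse=True)
    n = idx.size
    wsum = np.bincount(inv, weights=weights, minlength=n)
    pr = np.bincount(inv, weights=points[:, 0] * weights, minlength=n) / wsum
    pc = np.bincount(inv, weights=points[:, 1] * weights, minlength=n) / wsum
    return np.column_stack([pr, pc]), wsum, inv


def converge_and_cluster(V: np.ndarray, sched: IterationSchedule = IterationSchedule()) -> LabelMap:
    """Iterate one tracker per pixel under the field and label the modes.

    Phase 1 advects trackers along V; phase 2 repeatedly replaces each
    tracker by the mean of all trackers within ``merge_radius`` (trackers
    closer than 0.25 px are treated as coincident and carried as one
    weighted representative, which leaves the mean unchanged).  Final
    representatives within ``cluster_eps`` of each other (single linkage)
    share a label; labels are consecutive integers from 0 in row-major
    order of first appearance.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 3 or V.shape[2] != 2:
        raise ValueError("V must have shape (H, W, 2)")
    if not np.all(np.isfinite(V)):
        raise ValueError("displacement field must be finite")
    h, w = V.shape[:2]
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()])

    lim = np.array([h - 1.0, w - 1.0])
    for _ in range(sched.t_total - sched.t_phase2):
        vr = map_coordinates(V[:, :, 0], [pts[:, 0], pts[:, 1]], order=1, mode="nearest")
        vc = map_coordinates(V[:, :, 1], [pts[:, 0], pts[:, 1]], order=1, mode="nearest")
        pts[:, 0] = np.clip(pts[:, 0] + vr, 0.0, lim[0])
        pts[:, 1] = np.clip(pts[:, 1] + vc, 0.0, lim[1])

    reps, wts, owner = _collapse(pts, np.ones(len(pts)))
    for _ in range(sched.t_phase2):
        tree = cKDTree(reps)
        neigh = tree.query_ball_point(reps, r=sched.merge_radius)
        new = np.empty_like(reps)
        for i, nb in enumerate(neigh):
            wv = wts[nb]
            new[i] = (reps[nb] * wv[:, None]).sum(axis=0) / wv.sum()
        moved = np.max(np.abs(new - reps)) if len(reps) else 0.0
        reps2, wts2, inv2 = _collapse(new, wts)
        owner = inv2[owner]
        reps, wts = reps2, wts2
        if moved < 1e-9:
            break

    # single-linkage labeling of the representatives
    n = len(reps)
    tree = cKDTree(reps)
    pairs = tree.query_pairs(r=sched.cluster_eps, output_type="ndarray")
    g = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, comp = sparse.csgraph.connected_components(g, directed=False)
    pixel_comp = comp[owner]
    # relabel consecutively by first appearance in row-major pixel order
    _, first_idx = np.unique(pixel_comp, return_index=True)
    order = np.argsort(first_idx)
    remap = np.empty(len(order), dtype=int)
    remap[order] = np.arange(len(order))
    labels = remap[pixel_comp].reshape(h, w)
    return LabelMap(labels=labels, n_regions=int(labels.max()) + 1, tracker_points=pts)


class LCMSegmenter(ClusterMixin, BaseEstimator):
    """Scikit-learn style estimator for LCM image segmentation.

    Unlike tabular clusterers the sample matrix ``X`` is the 2D grayscale
    image itself; ``fit`` assigns every pixel a region label.

    Parameters
    ----------
    alpha, p : LCM edge-energy scale and exponent.
    index_convention : 'edge_complete' or 'as_printed' (see spinelcm.lcm).
    n_orientations : number K of scan orientations over [0, 180).
    t_total, t_phase2 : iteration schedule (phase 2 = consolidation).
    merge_radius, cluster_eps : consolidation radius and final single-linkage
        distance, in pixels.

    Attributes
    ----------
    labels_ : (H, W) int array of region labels.
    n_regions_ : number of distinct labels.
    displacement_field_ : (H, W, 2) LCM displacement field.
    """

    def __init__(
        self,
        alpha: float = 2000.0,
        p: float = 1.0,
        index_convention: str = "edge_complete",
        n_orientations: int = 180,
        t_total: int = 1000,
        t_phase2: int = 250,
        merge_radius: float = 2.0,
        cluster_eps: float = 1.0,
    ):
        self.alpha = alpha
        self.p = p
        self.index_convention = index_convention
        self.n_orientations = n_orientations
        self.t_total = t_total
        self.t_phase2 = t_phase2
        self.merge_radius = merge_radius
        self.cluster_eps = cluster_eps

    @classmethod
    def desk_profile(cls, **overrides) -> "LCMSegmenter":
        """Reduced-cost configuration (K=8, 50 iterations) for desk-scale runs."""
        kw = dict(n_orientations=8, t_total=50, t_phase2=12)
        kw.update(overrides)
        return cls(**kw)

    def fit(self, X, y=None):
        img = np.asarray(X, dtype=float)
        if img.ndim != 2:
            raise ValueError("X must be a 2D grayscale image")
        params = LCMParams(alpha=self.alpha, p=self.p, index_convention=self.index_convention)
        orient = OrientationSet(K=self.n_orientations)
        sched = IterationSchedule(
            t_total=self.t_total,
            t_phase2=self.t_phase2,
            merge_radius=self.merge_radius,
            cluster_eps=self.cluster_eps,
        )
        self.displacement_field_ = lcm_displacement_field(img, orient, params)
        lm = converge_and_cluster(self.displacement_field_, sched)
        self.labels_ = lm.labels
        self.n_regions_ = lm.n_regions
        self.label_map_ = lm
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def segment_image(
    image: np.ndarray,
    orient: OrientationSet = OrientationSet(),
    params: LCMParams = LCMParams(),
    sched: IterationSchedule = IterationSchedule(),
) -> LabelMap:
    """Functional wrapper: displacement field + convergence + clustering."""
    seg = LCMSegmenter(
        alpha=params.alpha,
        p=params.p,
        index_convention=params.index_convention,
        n_orientations=orient.K,
        t_total=sched.t_total,
        t_phase2=sched.t_phase2,
        merge_radius=sched.merge_radius,
        cluster_eps=sched.cluster_eps,
    )
    seg.fit(image)
    return seg.label_map_
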