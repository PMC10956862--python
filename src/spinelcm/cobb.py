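"""Geometric Cobb-angle construction on a spinal center curve.

Given the ordered midline of the segmented spine (one point per image row),
the construction is:

1. endpoints ``U`` (topmost) and ``L`` (bottommost) of the curve;
2. the chord ``UL``; its crossings with the curve give ``M`` (topmost) and
   ``N`` (bottommost) — since the chord passes through both endpoints these
   are the endpoints themselves, and any interior sign change of the
   perpendicular offset is recorded as a diagnostic (an S-shaped spine);
3. the apex ``C``: the curve point between ``M`` and ``N`` of maximum
   absolute perpendicular deviation from chord ``MN`` (option ``min_x``
   instead takes the literal smallest column);
4. perpendiculars to ``MC`` at ``M`` and to ``NC`` at ``N`` meet at ``O``;
5. ``P`` is the foot of the perpendicular from ``O`` onto line ``MN``.

The reported Cobb angle (convention ``mon``) is the angle ``MON`` at ``O``
between the rays ``OM`` and ``ON``; for a symmetric construction (``P``
midway, ``|MP| = |NP|``) this equals ``2*atan(|MP| / |OP|)``, twice the
half-angle of the right triangle ``MOP``.  The alternative convention
``eq5_printed`` is its supplement, ``180 - MON``, which for the symmetric
construction is exactly ``2*atan(|OP| / |MP|)`` — the ratio as printed in
the source construction; the two conventions always sum to 180 degrees.

For a center curve that is a circular arc of central angle phi, ``O`` is the
antipode of the apex and the ``mon`` angle equals phi/2 exactly — this
analytic identity is the oracle used by the synthetic phantoms.

All operations are pure vector geometry on (row, col) points and are
invariant under translation, rotation, reflection and uniform scaling of the
curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CobbConstruction",
    "CobbResult",
    "StraightSpineError",
    "curve_endpoints",
    "chord_intersections",
    "find_apex",
    "perpendicular_intersection",
    "foot_of_perpendicular",
    "cobb_from_construction",
    "classify_scoliosis",
    "measure_cobb",
]

_CONVENTIONS = ("mon", "eq5_printed")
_APEX_RULES = ("max_dev", "min_x")


class StraightSpineError(ValueError):
    """The curve has no usable curvature (collinear construction)."""


@dataclass
class CobbConstruction:
    """Construction points, each a (row, col) float pair."""

    U: np.ndarray
    L: np.ndarray
    M: np.ndarray
    N: np.ndarray
    C: np.ndarray
    O: np.ndarray
    P: np.ndarray
    theta_deg: float
    interior_crossings: list = field(default_factory=list)

    def as_dict(self) -> dict:
        pts = {k: [float(x) for x in getattr(self, k)] for k in "ULMNCOP"}
        pts["theta_deg"] = float(self.theta_deg)
        return pts


@dataclass
class CobbResult:
    angle_deg: float
    is_scoliosis: bool
    convention: str = "mon"
    construction: CobbConstruction | None = None


def _curve_points(curve) -> np.ndarray:
    """Accept a CenterCurve or an (n, 2) array of (row, col) points."""
    pts = getattr(curve, "points", curve)
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"curve must be (n, 2) points, got shape {pts.shape}")
    return pts


def curve_endpoints(curve) -> tuple[np.ndarray, np.ndarray]:
    """Topmost point U and bottommost point L of the ordered curve."""
    pts = _curve_points(curve)
    if len(pts) < 3:
        raise ValueError("curve must have at least 3 points")
    rows = pts[:, 0]
    if np.any(np.diff(rows) <= 0):
        raise ValueError("curve rows must be strictly increasing")
    return pts[0].copy(), pts[-1].copy()


def _signed_offsets(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed perpendicular distance of each point from line a-b."""
    ab = b - a
    norm = np.hypot(*ab)
    if norm == 0:
        raise ValueError("degenerate chord: endpoints coincide")
    # 2D cross product / |ab|
    return ((pts[:, 0] - a[0]) * ab[1] - (pts[:, 1] - a[1]) * ab[0]) / norm


def chord_intersections(curve, U=None, L=None):
    """Chord-curve crossing points M (top) and N (bottom).

    The chord passes through both endpoints, so M = U and N = L; interior
    sign changes of the perpendicular offset are returned as diagnostics
    (indices of the curve points just before each interior crossing).
    """
    pts = _curve_points(curve)
    if U is None or L is None:
        U, L = curve_endpoints(pts)
    off = _signed_offsets(pts, U, L)
    interior = []
    s = np.sign(off)
    nz = np.nonzero(s)[0]
    for i, j in zip(nz[:-1], nz[1:]):
        if s[i] != s[j]:
            interior.append(int(i))
    return np.asarray(U, float), np.asarray(L, float), interior


def find_apex(curve, M, N, rule: str = "max_dev") -> np.ndarray:
    """Apex C between M and N.

    ``max_dev``: point of maximum absolute perpendicular deviation from the
    chord MN (ties broken by smaller row).  ``min_x``: the literal smallest
    column index along the curve.  Raises StraightSpineError when the
    maximum deviation is zero.
    """
    if rule not in _APEX_RULES:
        raise ValueError(f"apex rule must be one of {_APEX_RULES}")
    pts = _curve_points(curve)
    M = np.asarray(M, float)
    N = np.asarray(N, float)
    off = _signed_offsets(pts, M, N)
    if np.max(np.abs(off)) == 0:
        raise StraightSpineError("curve is straight: no apex")
    if rule == "max_dev":
        k = int(np.argmax(np.abs(off)))  # argmax returns first max: smaller row
    else:
        k = int(np.argmin(pts[:, 1]))
    return pts[k].copy()


def perpendicular_intersection(M, N, C) -> np.ndarray:
    """Intersection O of the perpendicular to MC at M and to NC at N.

    Solves the 2x2 system (O-M).(C-M) = 0, (O-N).(C-N) = 0.  Collinear
    M, C, N make the perpendiculars parallel -> StraightSpineError.
    """
    M, N, C = (np.asarray(q, float) for q in (M, N, C))
    a = C - M
    b = C - N
    A = np.stack([a, b])
    rhs = np.array([a @ M, b @ N])
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    scale = max(np.abs(A).max(), 1.0)
    if abs(det) < 1e-12 * scale**2:
        raise StraightSpineError("M, C, N are collinear: perpendiculars are parallel")
    return np.linalg.solve(A, rhs)


def foot_of_perpendicular(O, M, N) -> np.ndarray:
    """Foot P of the perpendicular from O onto line MN."""
    O, M, N = (np.asarray(q, float) for q in (O, M, N))
    d = N - M
    t = (O - M) @ d / (d @ d)
    return M + t * d


def cobb_from_construction(cons: CobbConstruction, convention: str = "mon") -> float:
    """Cobb angle in degrees from a completed construction.

    ``mon``: the angle MON at O (= 2*atan(|MP|/|OP|) when the construction
    is symmetric).  ``eq5_printed``: its supplement 180 - MON
    (= 2*atan(|OP|/|MP|) in the symmetric case).
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}")
    OP = np.hypot(*(cons.P - cons.O))
    if OP == 0:
        raise ValueError("degenerate construction: O lies on chord MN")
    om = cons.M - cons.O
    on = cons.N - cons.O
    cross = om[0] * on[1] - om[1] * on[0]
    mon = float(np.degrees(np.arctan2(abs(cross), om @ on)))
    if convention == "mon":
        return mon
    return 180.0 - mon


def _build_construction(curve, apex_rule: str) -> CobbConstruction:
    pts = _curve_points(curve)
    U, L = curve_endpoints(pts)
    M, N, interior = chord_intersections(pts, U, L)
    C = find_apex(pts, M, N, rule=apex_rule)
    O = perpendicular_intersection(M, N, C)
    P = foot_of_perpendicular(O, M, N)
    OP = np.hypot(*(P - O))
    MP = np.hypot(*(P - M))
    theta = float(np.degrees(np.arctan2(MP, OP)))
    return CobbConstruction(
        U=U, L=L, M=M, N=N, C=C, O=O, P=P, theta_deg=theta,
        interior_crossings=interior,
    )


def classify_scoliosis(
    curve,
    min_dev_px: float = 3.0,
    convention: str = "mon",
    apex_rule: str = "max_dev",
) -> CobbResult:
    """Scoliosis decision plus angle.

    If the maximum perpendicular deviation of the curve from its endpoint
    chord is below ``min_dev_px`` the image is labeled "no scoliosis" with
    angle 0 and no construction; otherwise the full construction runs.
    """
    pts = _curve_points(curve)
    U, L = curve_endpoints(pts)
    off = _signed_offsets(pts, U, L)
    if np.max(np.abs(off)) < min_dev_px:
        return CobbResult(angle_deg=0.0, is_scoliosis=False, convention=convention)
    cons = _build_construction(pts, apex_rule)
    angle = cobb_from_construction(cons, convention)
    return CobbResult(
        angle_deg=angle, is_scoliosis=True, convention=convention, construction=cons
    )


def measure_cobb(curve, convention: str = "mon", apex_rule: str = "max_dev") -> CobbResult:
    """Unconditional construction + angle (no deviation threshold)."""
    cons = _build_construction(curve, apex_rule)
    angle = cobb_from_construction(cons, convention)
    return CobbResult(
        angle_deg=angle, is_scoliosis=True, convention=convention, construction=cons
    )
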