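"""Synthetic AP-spine radiograph phantoms with analytic ground truth.

A phantom is a bright column of vertebra-like rectangular blocks laid along a
parametric center curve on a darker, optionally noisy background — the
geometry an anteroposterior spine radiograph presents to the segmentation
pipeline.  Because the curve is analytic, every downstream stage has an
exact oracle: the true foreground mask, the true center curve, and the true
construction angle.

Curve kinds
-----------
``circular_arc``
    a circular arc of central angle phi whose chord is vertical; the
    construction angle (``mon`` convention) equals phi/2 analytically.
``cosine``
    col(r) = chord_col - d * sin(pi * (r - r0) / (r1 - r0)), a single bow of
    apex deviation d.
``straight``
    a vertical line; construction angle 0 (no scoliosis).

Ground truth is defined by the same chord/apex/perpendicular construction
the pipeline applies, evaluated on the continuous curve at 10x
supersampling, so end-to-end error isolates the pixel pipeline rather than
differences between angle definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .cobb import measure_cobb

__all__ = ["PhantomSpec", "PhantomBundle", "generate_phantom", "truth_angle"]

_CURVE_KINDS = ("circular_arc", "cosine", "straight")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic spine phantom.

    All geometry is in pixels of the rendered image; intensities in [0, 1].
    ``arc_central_angle_deg`` applies to circular_arc (construction truth is
    half of it); ``apex_deviation_px`` applies to cosine.
    """

    image_side: int = 256
    curve_kind: str = "circular_arc"
    arc_central_angle_deg: float = 40.0
    apex_deviation_px: float = 20.0
    n_vertebrae: int = 12
    vertebra_width_px: float = 24.0
    gap_px: float = 0.0
    fg_level: float = 0.8
    bg_level: float = 0.2
    noise_sigma: float = 0.0
    row_margin: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.curve_kind not in _CURVE_KINDS:
            raise ValueError(f"curve_kind must be one of {_CURVE_KINDS}")
        if not self.fg_level > self.bg_level:
            raise ValueError("fg_level must exceed bg_level")
        if self.curve_kind == "circular_arc" and not (
            0.0 < self.arc_central_angle_deg <= 120.0
        ):
            raise ValueError("arc_central_angle_deg must be in (0, 120]")
        if min(self.image_side, self.n_vertebrae, self.vertebra_width_px) <= 0:
            raise ValueError("sizes must be positive")
        if self.gap_px < 0 or self.noise_sigma < 0:
            raise ValueError("gap_px and noise_sigma must be nonnegative")


@dataclass
class PhantomBundle:
    image: np.ndarray          # noisy rendered image, [0, 1]
    truth_mask: np.ndarray     # noiseless foreground (bool)
    truth_curve: np.ndarray    # (n, 2) continuous (row, col) samples
    truth_angle_deg: float
    spec: PhantomSpec


def _curve_samples(spec: PhantomSpec, n: int) -> np.ndarray:
    """(row, col) samples of the continuous center curve, apex included.

    ``n`` is forced odd so the symmetric apex lands exactly on a sample.
    """
    side = spec.image_side
    r0, r1 = spec.row_margin, side - 1 - spec.row_margin
    if n % 2 == 0:
        n += 1
    if spec.curve_kind == "circular_arc":
        phi = np.radians(spec.arc_central_angle_deg)
        chord = r1 - r0
        R = chord / (2.0 * np.sin(phi / 2.0))
        sagitta = R * (1.0 - np.cos(phi / 2.0))
        # chord column placed so the bow (toward smaller columns) is centered;
        # circle center sits at chord_col + (R - sagitta) on the column axis
        chord_col = (side - 1) / 2.0 + sagitta / 2.0
        center = np.array([(r0 + r1) / 2.0, chord_col + (R - sagitta)])
        psi = np.linspace(-phi / 2.0, phi / 2.0, n)
        rows = center[0] + R * np.sin(psi)
        cols = center[1] - R * np.cos(psi)
    elif spec.curve_kind == "cosine":
        d = spec.apex_deviation_px
        chord_col = (side - 1) / 2.0 + d / 2.0
        rows = np.linspace(r0, r1, n)
        cols = chord_col - d * np.sin(np.pi * (rows - r0) / (r1 - r0))
    else:  # straight
        rows = np.linspace(r0, r1, n)
        cols = np.full(n, (side - 1) / 2.0)
    return np.column_stack([rows, cols])


def truth_angle(spec: PhantomSpec) -> float:
    """Construction angle (mon convention) of the continuous center curve.

    Evaluated at 10x supersampling relative to the row count the curve
    spans; returns 0 for a straight spec.  For circular_arc this equals
    arc_central_angle_deg / 2 analytically.
    """
    if spec.curve_kind == "straight":
        return 0.0
    span = spec.image_side - 1 - 2 * spec.row_margin
    curve = _curve_samples(spec, int(10 * span) + 1)
    return measure_cobb(curve, convention="mon").angle_deg


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Render the phantom image, its truth mask, curve and angle.

    Vertebra blocks are rectangles of width ``vertebra_width_px`` centered on
    the curve and aligned with the local tangent; consecutive blocks occupy
    equal arc-length slots separated by ``gap_px`` (0 renders a contiguous
    column).  Noise is additive Gaussian from a seeded generator; the truth
    mask is the noiseless foreground.  Deterministic per seed.
    """
    side = spec.image_side
    dense = _curve_samples(spec, 8 * side + 1)
    half_w = spec.vertebra_width_px / 2.0
    if dense[:, 1].min() - half_w < 0 or dense[:, 1].max() + half_w > side - 1:
        raise ValueError("curve (plus vertebra width) exits the image frame")

    # arc length parametrization for equal-slot block placement
    seglen = np.hypot(*np.diff(dense, axis=0).T)
    s = np.concatenate(([0.0], np.cumsum(seglen)))
    total = s[-1]
    slot = total / spec.n_vertebrae
    block_len = max(slot - spec.gap_px, 1.0)

    rr, cc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    mask = np.zeros((side, side), dtype=bool)
    # tiny overlap between contiguous blocks avoids wedge notches where
    # adjacent tilted rectangles meet on the convex side
    overlap = 0.5 if spec.gap_px == 0 else 0.0
    for k in range(spec.n_vertebrae):
        mid = (k + 0.5) * slot
        i = int(np.searchsorted(s, mid))
        i = min(max(i, 1), len(dense) - 1)
        center = dense[i]
        tang = dense[min(i + 4, len(dense) - 1)] - dense[max(i - 4, 0)]
        tang = tang / np.hypot(*tang)
        norm = np.array([-tang[1], tang[0]])
        dr = rr - center[0]
        dc = cc - center[1]
        along = dr * tang[0] + dc * tang[1]
        across = dr * norm[0] + dc * norm[1]
        mask |= (np.abs(along) <= block_len / 2.0 + overlap) & (
            np.abs(across) <= half_w
        )

    image = np.where(mask, spec.fg_level, spec.bg_level).astype(float)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sigma, image.shape)
    image = np.clip(image, 0.0, 1.0)
    return PhantomBundle(
        image=image,
        truth_mask=mask,
        truth_curve=_curve_samples(spec, 10 * side + 1),
        truth_angle_deg=truth_angle(spec),
        spec=spec,
    )


def spec_to_dict(spec: PhantomSpec) -> dict:
    return asdict(spec)
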