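"""Analytic test phantoms: ellipse composites (Shepp-Logan) and an annulus.

The phantoms stand in for the patient images the clinical workflow would
supply. ``shepp_logan`` uses the standard ten-ellipse table (the
contrast-enhanced variant common in reconstruction benchmarks) scaled so the
attenuation range is [0, 0.04] 1/mm. ``annulus`` builds a high-attenuation
ring reminiscent of an aortic annulus cross-section, with optional bright
spots mimicking leaflet calcifications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Image

__all__ = ["PhantomSpec", "make_phantom", "SHEPP_LOGAN_ELLIPSES"]

# (additive value, semi-axis a, semi-axis b, centre x, centre y, rotation deg)
# in the unit square convention (coordinates in [-1, 1]); contrast-enhanced
# ("modified") amplitudes.
SHEPP_LOGAN_ELLIPSES = (
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
)

#: attenuation (1/mm) assigned to the maximum of the unit-amplitude table
SHEPP_LOGAN_PEAK = 0.04


@dataclass
class PhantomSpec:
    """Parametric phantom description.

    ``kind`` is one of ``shepp_logan``, ``ellipses``, ``annulus``.
    For ``ellipses``, ``ellipses`` lists tuples
    ``(value 1/mm, axis_a mm, axis_b mm, cx mm, cy mm, rot rad)``.
    For ``annulus``: ``outer_radius``/``wall_thickness`` in mm and ``spots``
    a list of ``(cx mm, cy mm, radius mm, value 1/mm)`` calcification discs.
    """

    kind: str = "shepp_logan"
    n: int = 128
    pixel_size: float = 1.0
    ellipses: tuple = ()
    outer_radius: float = 40.0
    wall_thickness: float = 6.0
    wall_value: float = 0.04
    background_value: float = 0.01
    spots: tuple = ()

    def __post_init__(self):
        if self.n < 8:
            raise ValueError("phantom grid size must be >= 8")


def _ellipse_sum(n: int, pixel_size: float, ellipses) -> np.ndarray:
    cols = (np.arange(n) - (n - 1) / 2.0) * pixel_size
    rows = ((n - 1) / 2.0 - np.arange(n)) * pixel_size
    X, Y = np.meshgrid(cols, rows)
    img = np.zeros((n, n))
    for val, a, b, cx, cy, rot in ellipses:
        ct, st = np.cos(rot), np.sin(rot)
        xr = (X - cx) * ct + (Y - cy) * st
        yr = -(X - cx) * st + (Y - cy) * ct
        img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += val
    return img


def make_phantom(spec: PhantomSpec) -> Image:
    """Evaluate a phantom spec on pixel centres. Deterministic, values >= 0."""
    n, p = spec.n, spec.pixel_size
    if spec.kind == "shepp_logan":
        half = n * p / 2.0
        ell = [
            (v, a * half, b * half, cx * half, cy * half, np.deg2rad(rot))
            for v, a, b, cx, cy, rot in SHEPP_LOGAN_ELLIPSES
        ]
        img = _ellipse_sum(n, p, ell)
        img *= SHEPP_LOGAN_PEAK / 1.0  # table max is 1.0 by construction
    elif spec.kind == "ellipses":
        img = _ellipse_sum(n, p, spec.ellipses)
    elif spec.kind == "annulus":
        cols = (np.arange(n) - (n - 1) / 2.0) * p
        rows = ((n - 1) / 2.0 - np.arange(n)) * p
        X, Y = np.meshgrid(cols, rows)
        R = np.hypot(X, Y)
        img = np.zeros((n, n))
        img[R <= spec.outer_radius] = spec.background_value
        ring = (R <= spec.outer_radius) & (R >= spec.outer_radius - spec.wall_thickness)
        img[ring] = spec.wall_value
        for cx, cy, r, val in spec.spots:
            img[np.hypot(X - cx, Y - cy) <= r] = val
    else:
        raise ValueError(f"unknown phantom kind: {spec.kind!r}")
    # additive cancellation (e.g. 1 - 0.8 - 0.2) leaves O(eps) residue
    img[np.abs(img) < 1e-12] = 0.0
    if np.any(img < 0):
        raise ValueError("phantom spec produced negative attenuation values")
    return Image(img, p)
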