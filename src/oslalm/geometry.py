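"""2D parallel-beam scan geometry and the basic image/sinogram containers.

Conventions used throughout the package:

* the image is an ``n_y x n_x`` grid of attenuation values (1/mm) with the
  grid centre at the origin; row 0 sits at +y, column index grows toward +x;
* a projection view at angle ``phi`` (radians, in ``[0, pi)``) integrates
  along the direction ``(-sin phi, cos phi)``; a detector bin at signed
  offset ``s`` (mm from the detector centre) collects the line
  ``x cos phi + y sin phi = s``.

The geometry object fully determines the system matrix; see
:mod:`oslalm.projector` for the matched forward/back projector pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScanGeometry",
    "Image",
    "Sinogram",
    "SubsetPartition",
    "make_geometry",
    "partition_subsets",
    "bit_reversal_order",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Parallel-beam acquisition geometry.

    Parameters
    ----------
    n_x, n_y : int
        Image pixel counts along x (columns) and y (rows).
    pixel_size : float
        Square pixel side, mm.
    view_angles : tuple of float
        Projection angles in radians, strictly increasing, all in ``[0, pi)``.
    n_bins : int
        Detector element count per view.
    bin_spacing : float
        Detector element pitch, mm.
    detector_offset : float
        Shift of the detector centre from the rotation axis, mm.
    """

    n_x: int
    n_y: int
    pixel_size: float
    view_angles: tuple
    n_bins: int
    bin_spacing: float
    detector_offset: float = 0.0

    def __post_init__(self):
        if self.n_x < 1 or self.n_y < 1 or self.n_bins < 1:
            raise ValueError("all counts must be >= 1")
        if self.pixel_size <= 0 or self.bin_spacing <= 0:
            raise ValueError("pixel_size and bin_spacing must be > 0")
        ang = np.asarray(self.view_angles, dtype=float)
        if ang.ndim != 1 or ang.size < 1:
            raise ValueError("view_angles must be a non-empty 1-D sequence")
        if np.any(ang < 0) or np.any(ang >= math.pi):
            raise ValueError("view_angles must lie in [0, pi)")
        if ang.size > 1 and np.any(np.diff(ang) <= 0):
            raise ValueError("view_angles must be strictly increasing")
        diag = math.hypot(self.n_x * self.pixel_size, self.n_y * self.pixel_size)
        if self.n_bins * self.bin_spacing < diag:
            raise ValueError(
                f"detector width {self.n_bins * self.bin_spacing:g} mm does not "
                f"cover the image diagonal {diag:g} mm"
            )
        object.__setattr__(self, "view_angles", tuple(float(a) for a in ang))

    @property
    def n_views(self) -> int:
        return len(self.view_angles)

    @property
    def shape(self) -> tuple:
        """Sinogram shape ``(n_views, n_bins)``."""
        return (self.n_views, self.n_bins)

    @property
    def image_shape(self) -> tuple:
        return (self.n_y, self.n_x)

    @property
    def n_pixels(self) -> int:
        return self.n_x * self.n_y

    @property
    def n_rays(self) -> int:
        return self.n_views * self.n_bins

    def bin_positions(self) -> np.ndarray:
        """Signed detector offsets (mm) of the bin centres."""
        b = np.arange(self.n_bins, dtype=float)
        return (b - (self.n_bins - 1) / 2.0) * self.bin_spacing + self.detector_offset

    def pixel_centers(self):
        """``(X, Y)`` meshgrids of pixel-centre coordinates in mm."""
        cols = (np.arange(self.n_x) - (self.n_x - 1) / 2.0) * self.pixel_size
        rows = ((self.n_y - 1) / 2.0 - np.arange(self.n_y)) * self.pixel_size
        return np.meshgrid(cols, rows)

    def cache_key(self) -> tuple:
        return (
            self.n_x,
            self.n_y,
            self.pixel_size,
            self.view_angles,
            self.n_bins,
            self.bin_spacing,
            self.detector_offset,
        )


@dataclass
class Image:
    """A 2D attenuation map (1/mm) on a square-pixel grid."""

    values: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("image values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def copy(self) -> "Image":
        return Image(self.values.copy(), self.pixel_size)


@dataclass
class Sinogram:
    """Line-integral data (views x bins) tied to its acquisition geometry."""

    values: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"{self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def copy(self) -> "Sinogram":
        return Sinogram(self.values.copy(), self.geometry)


@dataclass
class SubsetPartition:
    """Ordered-subsets partition of the projection views.

    ``subsets[j]`` is the array of view indices visited at subset step ``j``;
    the list order is the visiting order.
    """

    subsets: list
    W: int

    def __post_init__(self):
        if len(self.subsets) != self.W:
            raise ValueError("partition must contain exactly W groups")
        self.subsets = [np.asarray(s, dtype=int) for s in self.subsets]
        all_views = np.concatenate(self.subsets)
        if len(np.unique(all_views)) != all_views.size:
            raise ValueError("subsets must be pairwise disjoint")
        sizes = [s.size for s in self.subsets]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("subset sizes may differ by at most 1")

    @property
    def n_views(self) -> int:
        return sum(s.size for s in self.subsets)


def make_geometry(
    n_x: int,
    n_y: int,
    pixel_size: float,
    n_views: int,
    n_bins: int,
    bin_spacing: float,
    detector_offset: float = 0.0,
) -> ScanGeometry:
    """Build a parallel-beam geometry with equispaced angles ``k*pi/n_views``.

    The detector is centred on the image centre (up to ``detector_offset``)
    and must be at least as wide as the image diagonal.
    """
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    angles = tuple(k * math.pi / n_views for k in range(n_views))
    return ScanGeometry(
        n_x=n_x,
        n_y=n_y,
        pixel_size=pixel_size,
        view_angles=angles,
        n_bins=n_bins,
        bin_spacing=bin_spacing,
        detector_offset=detector_offset,
    )


def bit_reversal_order(W: int) -> list:
    """Visiting order 0..W-1 permuted by bit reversal.

    Indices are reversed over ``ceil(log2 W)`` bits; reversed values >= W are
    skipped, so the result is a permutation for any W. Decorrelates successive
    subset gradients, the usual motivation for bit-reversed OS orderings.
    """
    if W < 1:
        raise ValueError("W must be >= 1")
    nbits = max(1, int(math.ceil(math.log2(W)))) if W > 1 else 1
    order = []
    for k in range(1 << nbits):
        rev = int(format(k, f"0{nbits}b")[::-1], 2)
        if rev < W:
            order.append(rev)
    return order


def partition_subsets(
    geom: ScanGeometry, W: int, scheme: str = "bit_reversal"
) -> SubsetPartition:
    """Partition views into W interleaved subsets (views congruent mod W).

    ``scheme`` controls the visiting order of the residue-class groups:
    ``strided`` visits 0,1,...,W-1; ``bit_reversal`` visits them in
    bit-reversed index order.
    """
    if not 1 <= W <= geom.n_views:
        raise ValueError(f"W must satisfy 1 <= W <= n_views ({geom.n_views})")
    if scheme == "strided":
        order = list(range(W))
    elif scheme == "bit_reversal":
        order = bit_reversal_order(W)
    else:
        raise ValueError(f"unknown subset scheme: {scheme!r}")
    groups = [np.arange(geom.n_views)[np.arange(geom.n_views) % W == r] for r in order]
    return SubsetPartition(subsets=groups, W=W)
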