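"""Filtered back projection baseline reconstructor.

Each view is ramp-filtered in the frequency domain (physical frequency axis,
cycles/mm, so detector pitch enters correctly), optionally Hann-apodized,
then back-projected with linear interpolation onto pixel centres and scaled
by pi / n_views — the discrete Radon inversion. The interpolating back
projector here is deliberately *not* the adjoint of the Siddon pair: FBP is
a one-shot analytic baseline, not part of the iterative solvers.
"""

from __future__ import annotations

import numpy as np

from .geometry import Image, ScanGeometry, Sinogram

__all__ = ["fbp_reconstruct", "ramp_filter_sinogram"]


def ramp_filter_sinogram(values: np.ndarray, geom: ScanGeometry, filter_name: str) -> np.ndarray:
    """Apply the ramp (optionally Hann-windowed) filter to every view."""
    if filter_name not in ("ramlak", "hann"):
        raise ValueError(f"unknown FBP filter: {filter_name!r}")
    n = geom.n_bins
    n_pad = 1 << int(np.ceil(np.log2(max(2 * n, 4))))
    freqs = np.fft.rfftfreq(n_pad, d=geom.bin_spacing)
    H = np.abs(freqs)
    if filter_name == "hann":
        nyq = 1.0 / (2.0 * geom.bin_spacing)
        H = H * 0.5 * (1.0 + np.cos(np.pi * freqs / nyq))
    spec = np.fft.rfft(values, n=n_pad, axis=1)
    return np.fft.irfft(spec * H[None, :], n=n_pad, axis=1)[:, :n]


def fbp_reconstruct(
    sino: Sinogram,
    geom: ScanGeometry = None,
    filter_name: str = "ramlak",
    clip: bool = True,
) -> Image:
    """Reconstruct an image from a sinogram by filtered back projection.

    ``clip`` replaces negative output values by zero (attenuation is
    nonnegative); pass ``clip=False`` for linearity checks.
    """
    if geom is None:
        geom = sino.geometry
    vals = sino.values if isinstance(sino, Sinogram) else np.asarray(sino, dtype=float)
    if vals.shape != geom.shape:
        raise ValueError(f"sinogram shape {vals.shape} does not match geometry {geom.shape}")
    q = ramp_filter_sinogram(vals, geom, filter_name)
    X, Y = geom.pixel_centers()
    pos = geom.bin_positions()
    out = np.zeros(geom.image_shape)
    for v, phi in enumerate(geom.view_angles):
        t = X * np.cos(phi) + Y * np.sin(phi)
        out += np.interp(t, pos, q[v], left=0.0, right=0.0)
    out *= np.pi / geom.n_views
    if clip:
        np.maximum(out, 0.0, out=out)
    return Image(out, geom.pixel_size)
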