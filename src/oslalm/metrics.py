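"""Image fidelity metrics: PSNR and RMSD.

Reconstructions are attenuation-valued (1/mm) while the PSNR convention here
uses an 8-bit peak of 255. To keep the conventional peak meaningful both
images are put through the same affine map that sends the reference range to
``[0, peak]`` before the mean squared error is formed.
"""

from __future__ import annotations

import numpy as np

from .geometry import Image

__all__ = ["psnr", "rmsd"]


def _arr(x) -> np.ndarray:
    return x.values if isinstance(x, Image) else np.asarray(x, dtype=float)


def psnr(x, ref, peak: float = 255.0, rescale: bool = True) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` when the images coincide.

    With ``rescale`` (default) the affine map taking ``ref`` onto
    ``[0, peak]`` is applied to both images first; with a constant reference
    the raw difference is used.
    """
    x, ref = _arr(x), _arr(ref)
    if x.shape != ref.shape:
        raise ValueError("images must share a shape")
    if peak <= 0:
        raise ValueError("peak must be > 0")
    if rescale:
        rng = ref.max() - ref.min()
        if rng > 0:
            scale = peak / rng
            x = (x - ref.min()) * scale
            ref = (ref - ref.min()) * scale
    mse = float(np.mean((x - ref) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak * peak / mse)


def rmsd(x, ref) -> float:
    """Root-mean-square difference ||x - ref|| / sqrt(n_pixels)."""
    x, ref = _arr(x), _arr(ref)
    if x.shape != ref.shape:
        raise ValueError("images must share a shape")
    return float(np.linalg.norm(x - ref) / np.sqrt(x.size))
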