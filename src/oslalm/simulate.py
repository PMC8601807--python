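"""Noisy transmission sinogram simulation with per-ray statistical weights.

The measurement model is monoenergetic photon-counting transmission: for ray
``i`` with true line integral ``L_i = [Mx]_i`` the detector records

    m_i ~ Poisson(I0 * exp(-L_i)),

the log-transformed data is ``ybar_i = ln(I0 / m_i)`` and the plug-in
inverse-variance weight is ``w_i = m_i`` (the delta-method variance of the
log of a Poisson count is 1/mean). This is the canonical source of the
diagonal statistical weight matrix in the PWLS objective. Counts are clamped
at 1 before the log so the data stays finite at photon starvation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import Image, ScanGeometry, Sinogram
from .projector import forward_project

__all__ = ["NoiseModel", "simulate_sinogram", "NOISELESS"]

#: sentinel incident count for noiseless simulation
NOISELESS = math.inf


@dataclass
class NoiseModel:
    """Transmission noise description.

    ``incident_count`` (I0) is the unattenuated photon count per ray;
    ``math.inf`` selects noiseless mode (ybar = Mx, unit weights).
    ``electronic_variance`` adds zero-mean Gaussian detector noise (counts^2)
    on top of the Poisson counts; default 0.
    """

    incident_count: float = 1e5
    electronic_variance: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.incident_count > 0:
            raise ValueError("incident_count must be > 0")
        if self.electronic_variance < 0:
            raise ValueError("electronic_variance must be >= 0")


def simulate_sinogram(
    x_true: Image, geom: ScanGeometry, noise: NoiseModel
) -> tuple:
    """Simulate ``(ybar, weights)`` from a ground-truth image.

    Returns a pair of :class:`Sinogram` objects: the noisy log-transformed
    data and the per-ray statistical weights (diagonal of P). Deterministic
    given ``noise.seed``.
    """
    line = forward_project(x_true, geom).values
    I0 = noise.incident_count
    if math.isinf(I0):
        return Sinogram(line, geom), Sinogram(np.ones_like(line), geom)
    rng = np.random.default_rng(noise.seed)
    mean_counts = I0 * np.exp(-line)
    counts = rng.poisson(mean_counts).astype(float)
    if noise.electronic_variance > 0:
        counts = counts + rng.normal(
            0.0, math.sqrt(noise.electronic_variance), size=counts.shape
        )
    counts = np.maximum(counts, 1.0)  # photon-starvation clamp
    ybar = np.log(I0 / counts)
    return Sinogram(ybar, geom), Sinogram(counts, geom)
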