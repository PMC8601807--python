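"""Model/Results interface to the PWLS reconstruction machinery.

:class:`PWLSModel` holds the data (noisy sinogram, statistical weights,
geometry, regularizer) — the statistical model

    ybar_i ~ N( [M x]_i , 1 / w_i ),   x >= 0,   prior exp(-Q(x)),

whose MAP estimate is the PWLS minimizer. ``fit(method=...)`` dispatches to
a registered reconstructor (``fbp``, ``oslalm``, ``oslalm_ogm``) and
returns a :class:`ReconResults` carrying the estimate, the per-iteration
diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .fbp import fbp_reconstruct
from .geometry import Image, ScanGeometry, Sinogram
from .metrics import psnr, rmsd
from .phantoms import PhantomSpec, make_phantom
from .regularization import RegularizerSpec, reg_value
from .simulate import NoiseModel, simulate_sinogram
from .solvers import ReconResult, SolverConfig, pwls_cost, run_oslalm, run_oslalm_ogm

__all__ = ["PWLSModel", "ReconResults", "RECONSTRUCTORS"]


def _fit_fbp(ybar, weights, geom, spec, cfg):
    img = fbp_reconstruct(ybar, geom)
    return ReconResult(final=img, snapshots={}, trace=pd.DataFrame(), config=cfg)


RECONSTRUCTORS = {
    "fbp": _fit_fbp,
    "oslalm": run_oslalm,
    "oslalm_ogm": run_oslalm_ogm,
}


class PWLSModel:
    """Penalized weighted least-squares CT reconstruction model.

    Parameters
    ----------
    sinogram : Sinogram
        Log-transformed transmission data ybar.
    weights : Sinogram or array, optional
        Per-ray statistical weights (diagonal of P); default all ones.
    regularizer : RegularizerSpec, optional
        Edge-preserving penalty; default is the packaged benchmark spec.
    truth : Image, optional
        Ground-truth phantom when known (simulation studies); enables
        PSNR reporting in ``summary()``.
    """

    def __init__(self, sinogram: Sinogram, weights=None, regularizer=None, truth=None):
        self.sinogram = sinogram
        self.geometry: ScanGeometry = sinogram.geometry
        if weights is None:
            weights = Sinogram(np.ones(self.geometry.shape), self.geometry)
        elif not isinstance(weights, Sinogram):
            weights = Sinogram(np.asarray(weights, dtype=float), self.geometry)
        self.weights = weights
        self.regularizer = regularizer or RegularizerSpec()
        self.truth = truth

    @classmethod
    def from_simulation(
        cls,
        phantom: PhantomSpec = None,
        geometry: ScanGeometry = None,
        noise: NoiseModel = None,
        regularizer: RegularizerSpec = None,
    ) -> "PWLSModel":
        """Build a model from a simulated noisy scan of a phantom."""
        from .geometry import make_geometry

        phantom = phantom or PhantomSpec()
        geometry = geometry or make_geometry(phantom.n, phantom.n, phantom.pixel_size, 120, 185, 1.0)
        noise = noise or NoiseModel()
        truth = make_phantom(phantom)
        ybar, weights = simulate_sinogram(truth, geometry, noise)
        return cls(ybar, weights, regularizer, truth=truth)

    def cost(self, image) -> float:
        """PWLS objective at an image."""
        return pwls_cost(image, self.sinogram, self.weights, self.regularizer)

    def fit(self, method: str = "oslalm_ogm", cfg: SolverConfig = None, **kwargs) -> "ReconResults":
        """Reconstruct; ``kwargs`` populate :class:`SolverConfig` fields."""
        if method not in RECONSTRUCTORS:
            raise ValueError(
                f"unknown reconstructor {method!r}; registered: {sorted(RECONSTRUCTORS)}"
            )
        if cfg is None:
            cfg = SolverConfig(use_ogm=(method == "oslalm_ogm"), **kwargs)
        elif kwargs:
            cfg = replace(cfg, **kwargs)
        raw = RECONSTRUCTORS[method](
            self.sinogram, self.weights, self.geometry, self.regularizer, cfg
        )
        return ReconResults(self, method, raw)


class ReconResults:
    """Reconstruction estimate plus diagnostics, statsmodels-style."""

    def __init__(self, model: PWLSModel, method: str, raw: ReconResult):
        self.model = model
        self.method = method
        self.image: Image = raw.final
        self.snapshots = raw.snapshots
        self.trace: pd.DataFrame = raw.trace
        self.config = raw.config
        self.runtime = raw.runtime

    @property
    def final_cost(self) -> float:
        if len(self.trace):
            return float(self.trace["cost"].iloc[-1])
        return self.model.cost(self.image)

    def psnr(self, reference=None) -> float:
        ref = reference if reference is not None else self.model.truth
        if ref is None:
            raise ValueError("no reference image available for PSNR")
        return psnr(self.image, ref)

    def rmsd(self, reference) -> float:
        return rmsd(self.image, reference)

    def summary(self) -> str:
        g = self.model.geometry
        data_fit = self.model.cost(self.image) - reg_value(
            self.image, self.model.regularizer
        )
        lines = [
            "PWLS Reconstruction Results",
            "=" * 46,
            f"{'method:':<24}{self.method}",
            f"{'image grid:':<24}{g.n_y} x {g.n_x} @ {g.pixel_size:g} mm",
            f"{'views x bins:':<24}{g.n_views} x {g.n_bins}",
            f"{'objective Phi:':<24}{self.final_cost:.6g}",
            f"{'  data-fit term:':<24}{data_fit:.6g}",
            f"{'  penalty Q:':<24}{reg_value(self.image, self.model.regularizer):.6g}",
        ]
        if len(self.trace):
            lines += [
                f"{'iterations:':<24}{int(self.trace['iteration'].iloc[-1])}",
                f"{'subsets:':<24}{self.config.subsets}",
                f"{'final rho:':<24}{self.trace['rho'].iloc[-1]:.4g}",
            ]
        if self.model.truth is not None:
            lines.append(f"{'PSNR vs truth (dB):':<24}{self.psnr():.2f}")
        lines.append(f"{'runtime (s):':<24}{self.runtime:.2f}")
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        """Objective trace vs iteration (log scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if len(self.trace):
            ax.semilogy(self.trace["iteration"], self.trace["cost"], marker=".")
        ax.set_xlabel("outer iteration")
        ax.set_ylabel(r"PWLS objective $\Phi$")
        ax.set_title(f"{self.method} convergence")
        return ax

    def __repr__(self) -> str:
        return f"<ReconResults method={self.method!r} shape={self.image.shape}>"
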