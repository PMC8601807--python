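"""PWLS solvers: OS-LALM with downward continuation and OGM momentum.

The objective fitted to the data is penalized weighted least squares,

    Phi(x) = 1/2 ||ybar - M x||^2_W + Q(x),   x >= 0,

with per-ray statistical weights W (diagonal) and the edge-preserving
penalty Q of :mod:`oslalm.regularization`.

The iterative scheme is the split-gradient form of the linearized augmented
Lagrangian method, accelerated by ordered subsets: one subset update reads

    s      = rho * grad_k(x) + (1 - rho) * p          (search direction)
    x_new  = prox_{Q + ind(x>=0)} ( x - s / (rho D) )  (majorized step)
    p      = (rho * grad_k(x_new) + p) / (rho + 1)     (split-gradient memory)

where ``grad_k`` is the subset gradient scaled by the subset count W_s,
``D`` the separable-quadratic-surrogate diagonal majorizer and ``p`` carries
the gradient memory between subset updates. The penalty parameter follows
the deterministic downward continuation schedule

    rho(0) = 1;   rho(g) = max( pi/(g+1) * sqrt(1 - (pi/(2g+2))^2), rho_min )

with g counting completed outer iterations (full data passes). Advancing rho
once per subset update instead is unstable at large subset counts: the
1/(rho D) step then amplifies the ordered-subset gradient error faster than
the split-gradient memory can damp it.

The OGM variant (OS-LALM-OGM) adds momentum on the prox output,

    x <- z + rho * ((theta_prev - 1) / theta) * (z - z_prev),

with theta following the optimized-gradient-method coefficient recursion
(reset at each outer iteration) and a projection back onto the nonnegative
orthant. Two safeguards make the composition stable under ordered subsets:
the coefficient is damped by rho (the continuation itself behaves like
inertia, so extra momentum must fade as rho falls), and once the schedule
reaches the momentum floor (``momentum_rho_floor``, default 0.3) rho is
frozen there and momentum switches off. Driving rho far below that floor
buys nothing once momentum has finished the transient — it only grows the
ordered-subset limit cycle, the gradient-error accumulation the momentum
variant exists to avoid. The momentum terms vanish identically at
theta = 1, so the unaccelerated solver is the exact degenerate case.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .fbp import fbp_reconstruct
from .geometry import Image, ScanGeometry, Sinogram, SubsetPartition, partition_subsets
from .projector import system_matrix
from .regularization import RegularizerSpec, denoise_prox, reg_value

__all__ = [
    "ALL",
    "SolverConfig",
    "ReconResult",
    "pwls_cost",
    "data_gradient",
    "rho_schedule",
    "majorizer_diag",
    "ogm_momentum_coeff",
    "run_oslalm",
    "run_oslalm_ogm",
]

#: sentinel subset index requesting the full-data gradient
ALL = "all"


@dataclass
class SolverConfig:
    """Iteration plan for the OS-LALM family.

    ``subsets`` is the ordered-subset count W_s; ``rho_min`` the lower clamp
    of the continuation schedule; ``inner_iters`` the projected-gradient
    steps inside each prox evaluation; ``checkpoints`` the outer iterations
    at which the image is snapshotted. ``force_theta`` pins the momentum
    coefficient (used to verify the degenerate theta = 1 case; it also
    disables the momentum rho floor so the pinned run shares the plain
    solver's schedule exactly). ``momentum_rho_floor`` is the continuation
    freeze level of the OGM variant; it is ignored by the plain solver.
    """

    n_iter: int = 40
    subsets: int = 40
    rho_min: float = 1e-3
    use_ogm: bool = False
    inner_iters: int = 10
    nonneg: bool = True
    checkpoints: tuple = ()
    seed: int = 0
    scheme: str = "bit_reversal"
    momentum_rho_floor: float = 0.3
    force_theta: float = None
    track_omega: bool = True

    def __post_init__(self):
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.subsets < 1:
            raise ValueError("subsets must be >= 1")
        if not 0 < self.rho_min <= 1:
            raise ValueError("rho_min must be in (0, 1]")
        if self.inner_iters < 1:
            raise ValueError("inner_iters must be >= 1")
        self.checkpoints = tuple(sorted(int(c) for c in self.checkpoints))
        if any(c < 1 or c > self.n_iter for c in self.checkpoints):
            raise ValueError("checkpoints must lie in [1, n_iter]")

    def to_dict(self) -> dict:
        return {
            "n_iter": self.n_iter,
            "subsets": self.subsets,
            "rho_min": self.rho_min,
            "use_ogm": self.use_ogm,
            "inner_iters": self.inner_iters,
            "nonneg": self.nonneg,
            "checkpoints": list(self.checkpoints),
            "seed": self.seed,
            "scheme": self.scheme,
            "momentum_rho_floor": self.momentum_rho_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SolverConfig":
        d = dict(d)
        if "checkpoints" in d:
            d["checkpoints"] = tuple(d["checkpoints"])
        return cls(**d)


@dataclass
class ReconResult:
    """Output of an iterative reconstruction run."""

    final: Image
    snapshots: dict
    trace: pd.DataFrame
    config: SolverConfig
    runtime: float = 0.0


def rho_schedule(g: int, rho_min: float = 1e-3) -> float:
    """Deterministic downward continuation of the penalty parameter."""
    if g < 0:
        raise ValueError("g must be >= 0")
    if not 0 < rho_min <= 1:
        raise ValueError("rho_min must be in (0, 1]")
    if g == 0:
        return 1.0
    a = math.pi / (g + 1)
    return max(a * math.sqrt(1.0 - (math.pi / (2 * g + 2)) ** 2), rho_min)


def ogm_momentum_coeff(theta_prev: float, is_last: bool = False) -> float:
    """Optimized-gradient-method coefficient recursion.

    Intermediate updates use ``(1 + sqrt(1 + 4 theta^2)) / 2``; the final
    update uses the larger ``(1 + sqrt(1 + 8 theta^2)) / 2``.
    """
    if theta_prev < 1:
        raise ValueError("theta_prev must be >= 1")
    c = 8.0 if is_last else 4.0
    return (1.0 + math.sqrt(1.0 + c * theta_prev * theta_prev)) / 2.0


def _weights_array(w) -> np.ndarray:
    w = w.values if isinstance(w, Sinogram) else np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("statistical weights must be > 0")
    return w


def pwls_cost(x, ybar: Sinogram, w, spec: RegularizerSpec) -> float:
    """Objective Phi(x) = 1/2 ||ybar - Mx||^2_W + Q(x)."""
    geom = ybar.geometry
    xv = x.values if isinstance(x, Image) else np.asarray(x, dtype=float)
    if xv.shape != geom.image_shape:
        raise ValueError("image shape does not match geometry")
    wv = _weights_array(w)
    A = system_matrix(geom)
    r = A @ xv.ravel() - ybar.values.ravel()
    return 0.5 * float(r @ (wv.ravel() * r)) + reg_value(xv, spec)


def data_gradient(
    x,
    ybar: Sinogram,
    w,
    geom: ScanGeometry = None,
    partition: SubsetPartition = None,
    k=ALL,
) -> np.ndarray:
    """Gradient of the weighted data-fit term.

    ``k = ALL`` gives the exact gradient ``M' W (Mx - ybar)``; an integer
    subset index gives the ordered-subset approximation
    ``W_s * M_k' W_k (M_k x - ybar_k)`` (subset gradient scaled by the
    subset count).
    """
    if geom is None:
        geom = ybar.geometry
    xv = (x.values if isinstance(x, Image) else np.asarray(x, dtype=float)).ravel()
    wv = _weights_array(w).ravel()
    yv = ybar.values.ravel()
    A = system_matrix(geom)
    if k == ALL:
        return (A.T @ (wv * (A @ xv - yv))).reshape(geom.image_shape)
    if partition is None:
        raise ValueError("a SubsetPartition is required for subset gradients")
    if not 0 <= k < partition.W:
        raise ValueError(f"invalid subset index {k} for W={partition.W}")
    rows = (
        partition.subsets[k][:, None] * geom.n_bins + np.arange(geom.n_bins)[None, :]
    ).ravel()
    Ak = A[rows]
    g = Ak.T @ (wv[rows] * (Ak @ xv - yv[rows]))
    return (partition.W * g).reshape(geom.image_shape)


def majorizer_diag(geom: ScanGeometry, w, partition: SubsetPartition = None) -> np.ndarray:
    """Separable-quadratic-surrogate diagonal D = M' W M 1 (ones image).

    Since the system matrix is entrywise nonnegative, diag(D) dominates
    M' W M in the Loewner order; zeros (pixels no ray touches) are replaced
    by the smallest positive entry so steps 1/D stay finite. ``partition``
    is accepted for signature symmetry but the full-data majorizer is used
    for every subset, the standard OS practice.
    """
    wv = _weights_array(w).ravel()
    A = system_matrix(geom)
    D = A.T @ (wv * (A @ np.ones(geom.n_pixels)))
    pos = D[D > 0]
    if pos.size == 0:
        raise ValueError("system matrix is identically zero")
    D[D == 0] = pos.min()
    return D.reshape(geom.image_shape)


def _subset_operators(geom: ScanGeometry, partition: SubsetPartition, w: np.ndarray, y: np.ndarray):
    """Precompute per-subset CSR slices for the solver hot loop."""
    A = system_matrix(geom)
    ops = []
    for views in partition.subsets:
        rows = (views[:, None] * geom.n_bins + np.arange(geom.n_bins)[None, :]).ravel()
        Ak = A[rows].tocsr()
        ops.append((Ak, Ak.T.tocsr(), w[rows], y[rows]))
    return ops


def run_oslalm(
    ybar: Sinogram,
    w,
    geom: ScanGeometry = None,
    spec: RegularizerSpec = None,
    cfg: SolverConfig = None,
) -> ReconResult:
    """Run OS-LALM (or, with ``cfg.use_ogm``, OS-LALM-OGM) on PWLS data.

    Initialization: ``x0`` is the (nonnegativity-clipped) FBP image and the
    split gradient starts at the full data gradient at ``x0``. The trace
    records the objective, rho and the gradient-ratio diagnostic once per
    outer iteration; snapshots are taken at the configured checkpoints.
    """
    t_start = time.perf_counter()
    if geom is None:
        geom = ybar.geometry
    if spec is None:
        spec = RegularizerSpec()
    if cfg is None:
        cfg = SolverConfig()

    wv = _weights_array(w)
    y = ybar.values.ravel()
    wflat = wv.ravel()
    A = system_matrix(geom)
    part = partition_subsets(geom, cfg.subsets, cfg.scheme)
    ops = _subset_operators(geom, part, wflat, y)
    Ws = float(part.W)

    if not np.any(ybar.values):
        # degenerate all-zero data: the PWLS minimizer is the zero image
        zero = Image(np.zeros(geom.image_shape), geom.pixel_size)
        trace = pd.DataFrame(
            {"iteration": [], "cost": [], "rho": [], "omega": []}
        )
        snaps = {c: zero.copy() for c in cfg.checkpoints}
        return ReconResult(zero, snaps, trace, cfg, time.perf_counter() - t_start)

    x = fbp_reconstruct(ybar, geom, "ramlak", clip=True).values.ravel()
    full_grad = A.T @ (wflat * (A @ x - y))
    p = full_grad.copy()
    D = majorizer_diag(geom, wv).ravel()

    # the momentum variant freezes the continuation at its floor; the pinned
    # (force_theta) run must share the plain schedule to stay bit-identical
    if cfg.use_ogm and cfg.force_theta is None:
        rho_floor = max(cfg.rho_min, cfg.momentum_rho_floor)
    else:
        rho_floor = cfg.rho_min

    g_count = 0
    rho = rho_schedule(0, rho_floor)
    theta = 1.0
    z_prev = x.copy()
    prev_full_grad = full_grad
    shape = geom.image_shape

    rows = []
    snapshots = {}
    for it in range(1, cfg.n_iter + 1):
        rho_used = rho
        momentum_on = cfg.force_theta is not None or rho > rho_floor
        for Ak, ATk, wk, yk in ops:
            grad_k = Ws * (ATk @ (wk * (Ak @ x - yk)))
            s = rho * grad_k + (1.0 - rho) * p
            step = 1.0 / (rho * D)
            v = x - s * step
            z = denoise_prox(
                v.reshape(shape), step.reshape(shape), spec, cfg.nonneg, cfg.inner_iters
            ).ravel()
            if cfg.use_ogm and momentum_on:
                theta_new = (
                    cfg.force_theta
                    if cfg.force_theta is not None
                    else ogm_momentum_coeff(theta)
                )
                gamma = rho * (theta - 1.0) / theta_new
                x_new = z + gamma * (z - z_prev)
                if cfg.nonneg:
                    np.maximum(x_new, 0.0, out=x_new)
                theta = theta_new
                z_prev = z
            else:
                x_new = z
            grad_new = Ws * (ATk @ (wk * (Ak @ x_new - yk)))
            p = (rho * grad_new + p) / (rho + 1.0)
            x = x_new
        g_count += 1
        rho = rho_schedule(g_count, rho_floor)
        theta = 1.0  # continuation step: restart the momentum sequence
        z_prev = x.copy()

        r = A @ x - y
        cost = 0.5 * float(r @ (wflat * r)) + reg_value(x.reshape(shape), spec)
        if cfg.track_omega:
            full_grad = A.T @ (wflat * r)
            denom = np.linalg.norm(full_grad - prev_full_grad)
            omega = (
                float(np.linalg.norm(p - full_grad) / denom) if denom > 0 else np.nan
            )
            prev_full_grad = full_grad
        else:
            omega = np.nan
        rows.append((it, cost, rho_used, omega))
        if it in cfg.checkpoints:
            snapshots[it] = Image(x.reshape(shape).copy(), geom.pixel_size)

    trace = pd.DataFrame(rows, columns=["iteration", "cost", "rho", "omega"])
    final = Image(x.reshape(shape).copy(), geom.pixel_size)
    return ReconResult(final, snapshots, trace, cfg, time.perf_counter() - t_start)


def run_oslalm_ogm(
    ybar: Sinogram,
    w,
    geom: ScanGeometry = None,
    spec: RegularizerSpec = None,
    cfg: SolverConfig = None,
) -> ReconResult:
    """OS-LALM with OGM momentum on the prox output (see module docstring)."""
    cfg = replace(cfg, use_ogm=True) if cfg is not None else SolverConfig(use_ogm=True)
    return run_oslalm(ybar, w, geom, spec, cfg)
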