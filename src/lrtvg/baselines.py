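"""Comparison methods: interpolation, Fourier zero-padding, and
image-domain TV / LRTV super-resolution.

The TV and LRTV baselines minimize a squared-L2 image fidelity built
from the known forward model of each observation (slice-profile blur
plus decimation — the PSF is assumed known) with TV and, for LRTV,
tensor trace-norm regularization, using the same ADMM machinery and
proximal operators as the spectrum-domain solver but with no support
constraint and no spectrum variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.sparse.linalg import LinearOperator, cg

from .core_ops import (
    _svt_with_values,
    fold,
    gradient,
    gradient_adjoint,
    group_soft_threshold,
    idft3,
    total_variation,
    unfold,
)
from .phantom_sim import AssembledSpectrum, Observation, _gaussian_kernel
from .solver import SolverConfig

logger = logging.getLogger("lrtvg")

__all__ = [
    "ImageFidelityModel",
    "nn_upsample",
    "bicubic_upsample",
    "zero_pad_sr",
    "tv_sr",
    "lrtv_sr",
]


@dataclass
class ImageFidelityModel:
    """Linear forward model A_d of one observation: slice-profile blur
    along the through-slice axis followed by decimation by beta.  The
    adjoint satisfies the inner-product identity exactly."""

    observation: Observation
    shape: tuple[int, int, int]

    def forward(self, x: np.ndarray) -> np.ndarray:
        o = self.observation
        axis, beta = o.axis, o.beta
        n_hi = self.shape[axis]
        if o.profile.kind == "rectangular":
            moved = np.moveaxis(x, axis, 0)
            blocks = moved.reshape(n_hi // beta, beta, *moved.shape[1:])
            return np.moveaxis(blocks.mean(axis=1), 0, axis)
        fwhm = o.profile.width if o.profile.width is not None else float(beta)
        kernel = _gaussian_kernel(fwhm)
        blurred = ndimage.convolve1d(x, kernel, axis=axis, mode="wrap")
        sl = [slice(None)] * 3
        sl[axis] = slice(0, None, beta)
        return blurred[tuple(sl)]

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        o = self.observation
        axis, beta = o.axis, o.beta
        if o.profile.kind == "rectangular":
            return np.repeat(y, beta, axis=axis) / beta
        up = np.zeros(self.shape)
        sl = [slice(None)] * 3
        sl[axis] = slice(0, None, beta)
        up[tuple(sl)] = y
        fwhm = o.profile.width if o.profile.width is not None else float(beta)
        kernel = _gaussian_kernel(fwhm)
        # symmetric kernel with periodic boundary: the blur is self-adjoint
        return ndimage.convolve1d(up, kernel, axis=axis, mode="wrap")


# ---------------------------------------------------------------------------
# interpolation baselines


def nn_upsample(
    observations: list[Observation], target_shape: tuple[int, int, int]
) -> np.ndarray:
    """Voxel replication along each through-slice axis; observations
    averaged voxelwise."""
    if not observations:
        raise ValueError("at least one observation is required")
    acc = np.zeros(tuple(target_shape))
    for o in observations:
        acc += np.repeat(o.lowres, o.beta, axis=o.axis)
    return acc / len(observations)


def bicubic_upsample(
    observations: list[Observation], target_shape: tuple[int, int, int]
) -> np.ndarray:
    """Cubic-spline interpolation along each through-slice axis.

    Low-res sample j is treated as located at high-res coordinate
    j*beta + (beta-1)/2 (block center), consistent with block-mean
    decimation; natural boundary conditions with extrapolation at the
    edges.  Observations averaged voxelwise.
    """
    if not observations:
        raise ValueError("at least one observation is required")
    shape = tuple(target_shape)
    acc = np.zeros(shape)
    for o in observations:
        if o.beta == 1:
            acc += o.lowres
            continue
        n_lo = o.lowres.shape[o.axis]
        positions = np.arange(n_lo) * o.beta + (o.beta - 1) / 2.0
        spline = CubicSpline(positions, o.lowres, axis=o.axis,
                             bc_type="natural", extrapolate=True)
        acc += spline(np.arange(shape[o.axis], dtype=np.float64))
    return acc / len(observations)


def zero_pad_sr(data: AssembledSpectrum) -> np.ndarray:
    """Zero-filled reconstruction: inverse DFT of the measured spectrum
    with unmeasured coefficients set to zero."""
    return idft3(np.where(data.omega, data.f0_prime, 0.0))


# ---------------------------------------------------------------------------
# regularized baselines (image-domain fidelity)


def _image_admm(
    observations: list[Observation],
    target_shape: tuple[int, int, int],
    cfg: SolverConfig,
    low_rank: bool,
) -> np.ndarray:
    """Shared ADMM loop of tv_sr / lrtv_sr.

    minimize_x 1/2 sum_d ||A_d x - x0_d||^2 + lambda_tv ||x||_TV
               [+ (lambda_lr/3) sum_i ||unfold_i(M_i)||_*
                + (eps/2) sum_i (||x - m_i + v_i||^2 - ||v_i||^2)]
    """
    if not observations:
        raise ValueError("at least one observation is required")
    shape = tuple(target_shape)
    models = [ImageFidelityModel(o, shape) for o in observations]
    rho = cfg.rho
    use_slack = low_rank and cfg.lambda_lr > 0
    if use_slack and cfg.epsilon <= 0:
        raise ValueError("epsilon must be positive when lambda_lr > 0")
    eps_n = 3.0 * cfg.epsilon if use_slack else 0.0

    x = nn_upsample(observations, shape)
    y = gradient(x)
    z = np.zeros_like(y)
    m = [x.copy() for _ in range(3)]
    v = [np.zeros(shape) for _ in range(3)]
    n = int(np.prod(shape))

    def matvec(w):
        wv = w.reshape(shape)
        out = eps_n * wv + rho * gradient_adjoint(gradient(wv))
        for mod in models:
            out += mod.adjoint(mod.forward(wv))
        return out.ravel()

    a_op = LinearOperator((n, n), matvec=matvec, dtype=np.float64)
    atb = np.zeros(shape)
    for mod, o in zip(models, observations):
        atb += mod.adjoint(o.lowres)

    def cost(sv_sum: float) -> float:
        c = 0.0
        for mod, o in zip(models, observations):
            r = mod.forward(x) - o.lowres
            c += 0.5 * float(np.sum(r * r))
        if cfg.lambda_tv > 0:
            c += cfg.lambda_tv * total_variation(x)
        if use_slack:
            c += (cfg.lambda_lr / 3.0) * sv_sum
            for mi, vi in zip(m, v):
                d = x - mi + vi
                c += (cfg.epsilon / 2.0) * (float(np.sum(d * d)) - float(np.sum(vi * vi)))
        return c

    j_prev = cost(sum(float(np.linalg.svd(unfold(mi, i), compute_uv=False).sum())
                      for i, mi in enumerate(m)) if use_slack else 0.0)
    j_init = max(abs(j_prev), 1.0)
    x_tol = np.sqrt(cfg.tol)

    for it in range(1, cfg.max_iter + 1):
        x_prev = x
        rhs = atb + gradient_adjoint(z + rho * y)
        if use_slack:
            acc = np.zeros(shape)
            for mi, vi in zip(m, v):
                acc += mi - vi
            rhs += cfg.epsilon * acc
        sol, info = cg(a_op, rhs.ravel(), x0=x.ravel(), rtol=cfg.cg_tol,
                       atol=0.0, maxiter=cfg.cg_max_iter)
        if info > 0:
            logger.warning("image-ADMM CG reached maxiter without tolerance")
        x = sol.reshape(shape)
        y = group_soft_threshold(gradient(x) - z / rho, cfg.lambda_tv / rho)
        sv_sum = 0.0
        if use_slack:
            tau = cfg.lambda_lr / (3.0 * cfg.epsilon)
            new_m = []
            for i in range(3):
                shrunk, s = _svt_with_values(unfold(x + v[i], i), tau)
                new_m.append(fold(shrunk, i, shape))
                sv_sum += float(s.sum())
            m = new_m
            for vi, mi in zip(v, m):
                vi += x - mi
        z += rho * (y - gradient(x))

        j = cost(sv_sum)
        if abs(j) > 1e6 * j_init:
            raise RuntimeError(f"image-domain ADMM diverged at iteration {it}")
        x_change = np.linalg.norm(x - x_prev) / max(np.linalg.norm(x), 1e-30)
        # never stop at iteration 1: with the warm start y = Lx the first
        # x-solve is a fixed point and the duals have not yet acted
        if (it > 1 and abs(j - j_prev) / max(abs(j_prev), 1.0) < cfg.tol
                and x_change < x_tol):
            break
        j_prev = j
    return x


def tv_sr(
    observations: list[Observation],
    target_shape: tuple[int, int, int],
    cfg: SolverConfig,
) -> np.ndarray:
    """TV-regularized super-resolution with the known forward model."""
    return _image_admm(observations, target_shape, cfg, low_rank=False)


def lrtv_sr(
    observations: list[Observation],
    target_shape: tuple[int, int, int],
    cfg: SolverConfig,
) -> np.ndarray:
    """LRTV: TV plus weighted tensor trace norm via mode-wise slacks."""
    return _image_admm(observations, target_shape, cfg, low_rank=True)
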