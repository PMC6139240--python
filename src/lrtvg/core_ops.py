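"""Shared mathematical operators.

Unitary 3D DFT pair, periodic finite differences, isotropic total
variation, tensor mode folding/unfolding, singular value thresholding
(SVT), the weighted tensor trace norm, and the group (l_{1,2}) soft
threshold.  Every linear operator here is used in matrix-free form by the
solvers; the adjoint of each one satisfies the inner-product identity,
which the test suite checks numerically.

Conventions
-----------
* The DFT is unitary (1/sqrt(N) both ways), so the inverse equals the
  conjugate-transpose adjoint and Parseval holds exactly.  Spectra are
  stored in unshifted (numpy) frequency order.
* Finite differences are forward differences with periodic (circular)
  boundary, so D^T D is circulant and diagonalised by the DFT.
* Tensor modes and volume axes are 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as _fft

logger = logging.getLogger("lrtvg")

__all__ = [
    "ModeWeights",
    "dft3",
    "idft3",
    "forward_diff",
    "forward_diff_adjoint",
    "gradient",
    "gradient_adjoint",
    "total_variation",
    "unfold",
    "fold",
    "svt",
    "tensor_trace_norm",
    "group_soft_threshold",
    "is_conjugate_symmetric",
]


@dataclass(frozen=True)
class ModeWeights:
    """Nonnegative weights (alpha_1, alpha_2, alpha_3) of the tensor trace
    norm, one per unfolding mode.  They must sum to 1; the default is the
    uniform 1/3 used for 3D images."""

    weights: tuple[float, float, float] = field(
        default=(1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
    )

    def __post_init__(self) -> None:
        w = tuple(float(v) for v in self.weights)
        if len(w) != 3 or any(v < 0 for v in w):
            raise ValueError("mode weights must be three nonnegative reals")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"mode weights must sum to 1, got {sum(w)!r}")
        object.__setattr__(self, "weights", w)


def _check_finite(a: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")


def dft3(v: np.ndarray) -> np.ndarray:
    """Unitary 3D DFT of a real volume.

    Returns a complex spectrum with ``dft3(v).conj()`` at index ``-k``
    equal to the value at ``k`` (conjugate symmetry of real signals).
    """
    v = np.asarray(v, dtype=np.float64)
    _check_finite(v, "volume")
    return _fft.fftn(v, norm="ortho")


def idft3(s: np.ndarray) -> np.ndarray:
    """Inverse unitary 3D DFT, returning the real part.

    For a conjugate-symmetric spectrum the imaginary part of the inverse
    transform is numerically zero and silently discarded; otherwise the
    discarded magnitude is reported at debug level.
    """
    s = np.asarray(s, dtype=np.complex128)
    _check_finite(s, "spectrum")
    out = _fft.ifftn(s, norm="ortho")
    scale = np.linalg.norm(out.ravel())
    imag = np.linalg.norm(out.imag.ravel())
    if scale > 0 and imag > 1e-8 * scale:
        logger.debug(
            "idft3: discarded imaginary part of relative magnitude %.3e",
            imag / scale,
        )
    return np.ascontiguousarray(out.real)


def is_conjugate_symmetric(s: np.ndarray, rtol: float = 1e-10) -> bool:
    """True when s[k] == conj(s[-k mod N]) to relative tolerance."""
    s = np.asarray(s)
    flipped = s
    for ax in range(s.ndim):
        flipped = np.roll(np.flip(flipped, axis=ax), 1, axis=ax)
    err = np.linalg.norm((s - flipped.conj()).ravel())
    ref = np.linalg.norm(s.ravel())
    return err <= rtol * max(ref, 1.0)


def forward_diff(v: np.ndarray, axis: int) -> np.ndarray:
    """Periodic forward first difference along ``axis`` (0, 1 or 2)."""
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    return np.roll(v, -1, axis=axis) - v


def forward_diff_adjoint(w: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint of :func:`forward_diff` (negative backward difference)."""
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    return np.roll(w, 1, axis=axis) - w


def gradient(v: np.ndarray) -> np.ndarray:
    """Stacked periodic forward differences, shape (3, N1, N2, N3)."""
    return np.stack([forward_diff(v, d) for d in range(3)])


def gradient_adjoint(g: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`gradient`: sum of per-axis adjoint differences."""
    return sum(forward_diff_adjoint(g[d], d) for d in range(3))


def total_variation(v: np.ndarray) -> float:
    """Isotropic total variation: the sum over voxels of the Euclidean
    norm of the 3-vector of forward differences."""
    g = gradient(np.asarray(v, dtype=np.float64))
    return float(np.sqrt((g * g).sum(axis=0)).sum())


def unfold(t: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` unfolding: rows indexed by that mode, the remaining
    modes flattened into columns."""
    t = np.asarray(t)
    if t.ndim != 3:
        raise ValueError(f"expected a 3D array, got ndim={t.ndim}")
    if mode not in (0, 1, 2):
        raise ValueError(f"mode must be 0, 1 or 2, got {mode}")
    return np.moveaxis(t, mode, 0).reshape(t.shape[mode], -1)


def fold(m: np.ndarray, mode: int, shape: tuple[int, int, int]) -> np.ndarray:
    """Exact inverse of :func:`unfold` for the given tensor ``shape``."""
    if mode not in (0, 1, 2):
        raise ValueError(f"mode must be 0, 1 or 2, got {mode}")
    shape = tuple(shape)
    if len(shape) != 3:
        raise ValueError("shape must be a triple")
    moved = (shape[mode],) + tuple(s for i, s in enumerate(shape) if i != mode)
    m = np.asarray(m)
    if m.shape != (moved[0], moved[1] * moved[2]):
        raise ValueError(
            f"matrix shape {m.shape} inconsistent with mode-{mode} "
            f"unfolding of {shape}"
        )
    return np.moveaxis(m.reshape(moved), 0, mode)


def svt(m: np.ndarray, tau: float) -> np.ndarray:
    """Singular value soft-thresholding, the proximal operator of
    ``tau * nuclear norm``.

    Singular values are shrunk to ``max(sigma - tau, 0)``; singular
    vectors are unchanged.  Real matrices only.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    m = np.asarray(m)
    if np.iscomplexobj(m):
        raise TypeError("svt is defined for real matrices only")
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (u * s) @ vt


def _svt_with_values(m: np.ndarray, tau: float) -> tuple[np.ndarray, np.ndarray]:
    """svt plus the shrunk singular values (the output's own spectrum),
    reused by the solver to evaluate nuclear norms at no extra cost."""
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (u * s) @ vt, s


def tensor_trace_norm(t: np.ndarray, w: ModeWeights | None = None) -> float:
    """Weighted sum over modes of the nuclear norms of the unfoldings —
    the convex surrogate of multilinear rank for 3D tensors."""
    if w is None:
        w = ModeWeights()
    total = 0.0
    for mode, alpha in enumerate(w.weights):
        if alpha == 0.0:
            continue
        total += alpha * float(np.linalg.svd(unfold(t, mode), compute_uv=False).sum())
    return total


def group_soft_threshold(g: np.ndarray, kappa: float) -> np.ndarray:
    """Per-voxel shrinkage of a 3-vector field (shape (3, N1, N2, N3)):
    each voxel's vector w is mapped to max(1 - kappa/||w||, 0) * w.

    This is the proximal operator of ``kappa * ||.||_{1,2}``.
    """
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    g = np.asarray(g, dtype=np.float64)
    if g.ndim != 4 or g.shape[0] != 3:
        raise ValueError("expected a (3, N1, N2, N3) vector field")
    if kappa == 0.0:
        return g.copy()
    norms = np.sqrt((g * g).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(norms > 0, np.maximum(1.0 - kappa / norms, 0.0), 0.0)
    return g * scale[None]
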