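"""Gerchberg POCS super-resolution.

The classic two-projection scheme: alternately (I) zero the image
outside the known object support Gamma and (II) restore the measured
Fourier coefficients on the observed band Omega.  Both constraint sets
are convex, so the iterates are Fejer monotone with respect to any
consistent solution, and for a consistent instance they converge to the
point of the intersection.  Used both as a baseline method and as the
correctness oracle for the zero-regularization limit of the LRTVG
solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_ops import dft3, idft3

__all__ = ["PocsResult", "gerchberg"]


@dataclass
class PocsResult:
    volume: np.ndarray
    iterations: int
    residual_history: list[float] = field(default_factory=list)
    converged: bool = False


def gerchberg(
    f0: np.ndarray,
    omega: np.ndarray,
    gamma: np.ndarray,
    max_iter: int = 10000,
    tol: float = 1e-7,
) -> PocsResult:
    """Run the Gerchberg algorithm from F = F0.

    Parameters
    ----------
    f0
        observed spectrum, zero outside ``omega``
    omega
        boolean measured-frequency mask (conjugate-symmetric)
    gamma
        binary object-support mask
    max_iter, tol
        stop when the relative L2 change of the image between iterations
        falls below ``tol``

    The returned volume satisfies the support constraint exactly by
    construction (it is produced by projection I).
    """
    omega = np.asarray(omega, dtype=bool)
    gamma_f = np.asarray(gamma, dtype=np.float64)
    if not set(np.unique(gamma_f)).issubset({0.0, 1.0}):
        raise ValueError("gamma must be binary")
    f0 = np.asarray(f0, dtype=np.complex128)
    if np.abs(f0[~omega]).max(initial=0.0) > 1e-12 * max(np.abs(f0).max(), 1.0):
        raise ValueError("f0 must be zero outside omega")

    f = f0.copy()
    x = gamma_f * idft3(f)
    history: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        f = np.where(omega, f0, dft3(x))
        x_new = gamma_f * idft3(f)
        denom = max(np.linalg.norm(x_new.ravel()), 1e-30)
        change = float(np.linalg.norm((x_new - x).ravel()) / denom)
        history.append(change)
        x = x_new
        if change < tol:
            converged = True
            break
    return PocsResult(volume=x, iterations=iterations,
                      residual_history=history, converged=converged)
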