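"""Synthetic phantoms and the anisotropic MR observation model.

A phantom is a piecewise-constant volume of nested ellipsoidal shells
with compact support (the object region Gamma), standing in for a brain
phantom.  An observation is what a scanner with slice selection along one
axis would measure: the ideal volume blurred by the slice profile along
the through-slice axis, decimated by the scale factor beta, and
contaminated by Gaussian noise at a stated percentage of the peak
intensity.

Each observation measures only a band of frequencies along its
through-slice axis (the lowest N/beta signed frequencies); the union of
the bands of all observations is the measured region Omega of 3D
frequency space, which never covers the diagonal high-frequency corners.
``assemble_spectrum`` embeds every observation's spectrum on the
high-resolution grid, divides out the slice-profile response (spectrum
deconvolution, with a floor that drops near-zero response indices from
Omega instead of amplifying noise), and fuses overlapping coefficients by
averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_ops import dft3

__all__ = [
    "SliceProfile",
    "Phantom",
    "Observation",
    "AssembledSpectrum",
    "make_phantom",
    "degrade",
    "slice_profile_spectrum",
    "observed_spectrum",
    "assemble_spectrum",
    "band_frequencies",
]

#: indices with profile response below this magnitude are dropped from
#: Omega instead of being divided (bounded noise amplification)
PROFILE_FLOOR = 0.05

_GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SliceProfile:
    """Slice-excitation kernel along the through-slice axis.

    kind
        "rectangular": length-beta boxcar (uniform excitation, the
        average kernel); "gaussian": discretized Gaussian whose FWHM in
        voxels equals ``width`` (defaults to beta).
    """

    kind: str = "rectangular"
    width: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("rectangular", "gaussian"):
            raise ValueError(f"unknown slice profile kind {self.kind!r}")


@dataclass
class Phantom:
    """Ground-truth volume plus its support mask Gamma."""

    truth: np.ndarray
    support: np.ndarray
    seed: int

    @property
    def shape(self) -> tuple[int, ...]:
        return self.truth.shape


@dataclass
class Observation:
    """One anisotropic acquisition of a phantom."""

    lowres: np.ndarray
    axis: int
    beta: int
    noise_pct: float
    profile: SliceProfile = field(default_factory=SliceProfile)


@dataclass
class AssembledSpectrum:
    """Measured data on the high-resolution grid.

    f0_prime
        complex spectrum F0' (profile-deconvolved), zero outside omega
    omega
        boolean measured-frequency mask P_Omega (conjugate-symmetric)
    profile_spectrum
        product over observations of the per-axis profile responses P_Xi
        (diagnostic; the deconvolution itself is applied per observation)
    """

    f0_prime: np.ndarray
    omega: np.ndarray
    profile_spectrum: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return self.f0_prime.shape


# ---------------------------------------------------------------------------
# phantom generation


def make_phantom(
    shape: tuple[int, int, int],
    style: str = "t1like",
    lesion: bool = False,
    seed: int = 0,
) -> Phantom:
    """Nested-ellipsoid piecewise-constant phantom.

    Three concentric ellipsoidal shells with contrast ordering inverted
    between the two styles (t1like: bright middle shell on a dark rim,
    the way white matter dominates T1 weighting; t2like: the inverse).
    ``lesion`` adds two small blobs strictly inside the support, bright
    for t2like and dark for t1like.  Deterministic given ``seed``; the
    support is the outermost shell, a single connected region at least 2
    voxels away from the grid boundary.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 16 for s in shape):
        raise ValueError(f"each extent must be >= 16, got {shape}")
    if style not in ("t1like", "t2like"):
        raise ValueError(f"unknown style {style!r}")
    rng = np.random.default_rng(seed)

    # semi-axes in voxels, bounded so the support keeps a >=2 voxel margin
    semi = np.array(
        [(s / 2.0 - 2.5) * rng.uniform(0.92, 1.0) for s in shape]
    )
    center = np.array(
        [s / 2.0 - 0.5 + rng.uniform(-0.5, 0.5) for s in shape]
    )
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                        indexing="ij")
    r = np.sqrt(sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi)))

    if style == "t1like":
        shell_values = (0.45, 1.0, 0.7)   # rim, middle, core
        lesion_value = 0.25
    else:
        shell_values = (1.0, 0.45, 0.7)
        lesion_value = 1.2

    truth = np.zeros(shape, dtype=np.float64)
    support = r <= 1.0
    truth[support] = shell_values[0]
    truth[r <= 0.72] = shell_values[1]
    truth[r <= 0.42] = shell_values[2]

    if lesion:
        for _ in range(2):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            radius_frac = rng.uniform(0.15, 0.5)
            blob_center = center + direction * radius_frac * semi
            blob_semi = np.maximum(0.06 * semi, 1.5)
            rb = np.sqrt(sum(((g - c) / a) ** 2
                             for g, c, a in zip(grids, blob_center, blob_semi)))
            truth[(rb <= 1.0) & support] = lesion_value

    truth[~support] = 0.0
    return Phantom(truth=truth, support=support.astype(np.uint8), seed=seed)


# ---------------------------------------------------------------------------
# degradation


def _gaussian_kernel(fwhm: float) -> np.ndarray:
    sigma = max(fwhm, 1e-6) * _GAUSS_FWHM_TO_SIGMA
    radius = max(1, int(np.ceil(3.0 * sigma)))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def degrade(
    p: Phantom,
    axis: int,
    beta: int,
    noise_pct: float = 0.0,
    profile: SliceProfile | None = None,
    seed: int = 0,
) -> Observation:
    """Simulate one anisotropic acquisition.

    Rectangular profile: non-overlapping block means of length ``beta``
    along ``axis`` (the average kernel, block-aligned).  Gaussian
    profile: zero-phase periodic Gaussian blur of FWHM ``width`` voxels
    followed by taking every beta-th sample.  Then i.i.d. Gaussian noise
    with standard deviation (noise_pct/100) * max(truth) is added.
    """
    if profile is None:
        profile = SliceProfile()
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    beta = int(beta)
    if beta < 1:
        raise ValueError("beta must be >= 1")
    n_hi = p.truth.shape[axis]
    if n_hi % beta != 0:
        raise ValueError(f"extent {n_hi} along axis {axis} not divisible by beta={beta}")

    if profile.kind == "rectangular":
        moved = np.moveaxis(p.truth, axis, 0)
        blocks = moved.reshape(n_hi // beta, beta, *moved.shape[1:])
        low = np.moveaxis(blocks.mean(axis=1), 0, axis)
    else:
        fwhm = profile.width if profile.width is not None else float(beta)
        kernel = _gaussian_kernel(fwhm)
        blurred = ndimage.convolve1d(p.truth, kernel, axis=axis, mode="wrap")
        sl = [slice(None)] * 3
        sl[axis] = slice(0, None, beta)
        low = blurred[tuple(sl)]

    rng = np.random.default_rng(seed)
    sigma = (float(noise_pct) / 100.0) * float(p.truth.max())
    if sigma > 0:
        low = low + rng.normal(0.0, sigma, size=low.shape)
    return Observation(lowres=np.ascontiguousarray(low), axis=axis, beta=beta,
                       noise_pct=float(noise_pct), profile=profile)


# ---------------------------------------------------------------------------
# spectrum assembly


def band_frequencies(n_hi: int, beta: int) -> np.ndarray:
    """Signed frequencies measured along a through-slice axis.

    The lowest ``n_hi/beta`` signed frequencies; when the band size is
    even its Nyquist bin is excluded so the index set stays
    conjugate-symmetric.
    """
    if n_hi % beta != 0:
        raise ValueError(f"{n_hi} not divisible by beta={beta}")
    n_lo = n_hi // beta
    if beta == 1:
        # lossless case: the band is the whole axis, Nyquist included
        # (the full index set is conjugate-symmetric as a whole)
        return np.rint(np.fft.fftfreq(n_hi) * n_hi).astype(int)
    half = (n_lo - 1) // 2
    return np.arange(-half, half + 1)


def _profile_response_1d(profile: SliceProfile, beta: int, n_hi: int) -> np.ndarray:
    """Real frequency response of the unit-sum slice kernel on the
    high-res axis, in unshifted DFT order.

    The rectangular (boxcar) kernel's response is the Dirichlet kernel;
    the phase ramp from block positioning is removed by the matching
    half-kernel shift applied in :func:`observed_spectrum`, so the
    response used for deconvolution is real.
    """
    k = np.fft.fftfreq(n_hi, d=1.0) * n_hi  # signed integer frequencies
    if profile.kind == "rectangular":
        if beta == 1:
            return np.ones(n_hi)
        # sum_{p=0}^{beta-1} e^{2 pi i k p / N} / beta, phase removed
        num = np.sin(np.pi * k * beta / n_hi)
        den = beta * np.sin(np.pi * k / n_hi)
        with np.errstate(divide="ignore", invalid="ignore"):
            resp = np.where(np.abs(den) > 1e-12, num / den, 1.0)
        return resp
    fwhm = profile.width if profile.width is not None else float(beta)
    kernel = _gaussian_kernel(fwhm)
    radius = (len(kernel) - 1) // 2
    padded = np.zeros(n_hi)
    for offset, value in zip(range(-radius, radius + 1), kernel):
        padded[offset % n_hi] += value
    resp = np.fft.fft(padded)
    assert np.abs(resp.imag).max() < 1e-10
    return resp.real


def slice_profile_spectrum(
    profile: SliceProfile,
    axis: int,
    beta: int,
    shape: tuple[int, int, int],
) -> np.ndarray:
    """Profile response P_Xi broadcast over the full grid (real array)."""
    resp = _profile_response_1d(profile, beta, shape[axis])
    full_shape = [1, 1, 1]
    full_shape[axis] = shape[axis]
    return np.broadcast_to(resp.reshape(full_shape), shape).copy()


def observed_spectrum(
    o: Observation,
    target_shape: tuple[int, int, int],
    deconvolve: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Embed one observation's spectrum on the high-resolution grid.

    Returns ``(spectrum, omega_d)`` where ``omega_d`` is the band of the
    lowest N/beta signed frequencies along the through-slice axis (times
    all frequencies in-plane) and ``spectrum`` carries the low-res DFT
    coefficients placed on those indices, scaled by sqrt(beta) so a
    noise-free beta=1 observation reproduces ``dft3(truth)`` exactly
    under the unitary convention.  The half-kernel phase of block
    positioning is removed, and (by default) each coefficient is divided
    by the slice-profile response; indices where the response magnitude
    falls below ``PROFILE_FLOOR`` are dropped from the band instead.
    Aliasing of out-of-band truth energy is part of the measurement
    model.
    """
    shape = tuple(int(s) for s in target_shape)
    axis, beta = o.axis, o.beta
    n_hi = shape[axis]
    n_lo = n_hi // beta
    expected = list(shape)
    expected[axis] = n_lo
    if o.lowres.shape != tuple(expected):
        raise ValueError(
            f"observation shape {o.lowres.shape} inconsistent with target "
            f"{shape} at beta={beta} on axis {axis}"
        )

    y = dft3(o.lowres)
    qs = band_frequencies(n_hi, beta)
    resp = _profile_response_1d(o.profile, beta, n_hi)

    spectrum = np.zeros(shape, dtype=np.complex128)
    omega = np.zeros(shape, dtype=bool)
    # phase of the block-aligned boxcar positions (rectangular only);
    # the gaussian blur is applied zero-phase and sampled at 0 offset
    if o.profile.kind == "rectangular":
        phase = np.exp(-1j * np.pi * qs * (beta - 1) / n_hi)
    else:
        phase = np.ones(len(qs), dtype=np.complex128)

    idx_hi = [slice(None)] * 3
    idx_lo = [slice(None)] * 3
    for q, ph in zip(qs, phase):
        r = resp[int(q) % n_hi]
        if deconvolve and abs(r) < PROFILE_FLOOR:
            continue
        idx_hi[axis] = int(q) % n_hi
        idx_lo[axis] = int(q) % n_lo
        val = np.sqrt(beta) * y[tuple(idx_lo)] * ph
        if deconvolve:
            val = val / r
        spectrum[tuple(idx_hi)] = val
        omega[tuple(idx_hi)] = True
    return spectrum, omega


def assemble_spectrum(
    observations: list[Observation],
    target_shape: tuple[int, int, int],
) -> AssembledSpectrum:
    """Fuse one or more observations into (F0', P_Omega, P_Xi).

    Each observation is embedded and profile-deconvolved on the shared
    grid; coefficients measured by several observations are averaged.
    """
    if not observations:
        raise ValueError("at least one observation is required")
    shape = tuple(int(s) for s in target_shape)
    total = np.zeros(shape, dtype=np.complex128)
    count = np.zeros(shape, dtype=np.int32)
    profile = np.ones(shape, dtype=np.float64)
    for o in observations:
        spec, om = observed_spectrum(o, shape, deconvolve=True)
        total[om] += spec[om]
        count += om
        profile *= slice_profile_spectrum(o.profile, o.axis, o.beta, shape)
    omega = count > 0
    f0_prime = np.zeros(shape, dtype=np.complex128)
    f0_prime[omega] = total[omega] / count[omega]
    return AssembledSpectrum(f0_prime=f0_prime, omega=omega,
                             profile_spectrum=profile)
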