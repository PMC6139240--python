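# Methods

## Problem setting

MR volumes are usually anisotropic: the through-slice voxel size is a
factor β (typically 3–12) coarser than the in-plane size, because slice
thickness buys signal-to-noise. In frequency space this means each
acquisition measures only a band of the 3D spectrum — all in-plane
frequencies, but only the lowest N/β signed frequencies along its
through-slice axis. Even with two acquisitions whose slice-selection
axes are orthogonal, the union Ω of the two bands leaves the diagonal
high-frequency corners unmeasured. Super-resolution in this setting is
spectrum extrapolation: estimate the coefficients on the complement Ω̄
and invert.

Two classical pieces of prior knowledge make the extrapolation
well-posed:

1. **Object support (Γ)**: the imaged object occupies a known compact
   region; the background is exactly zero. A signal of finite support
   cannot be band-limited, so the measured band constrains the missing
   band.
2. **Measured-spectrum fidelity**: on Ω the estimated spectrum must stay
   near the observed coefficients.

The Gerchberg algorithm alternates projections onto these two convex
sets; it provably converges to the intersection when the data are
consistent, but it is brittle under noise and prone to ringing. The
solver implemented here embeds the same two constraints in a convex
program with two image regularizers:

```
minimize_f   λ_TV ‖x‖_TV  +  (λ_LR/3) Σ_i ‖unfold_i(M_i)‖_*
           + ½ ‖f0′ − R_Ω f‖²
           + (ε/2) Σ_i ( ‖x − m_i + v_i‖² − ‖v_i‖² )
subject to   x = G f ,    R_Γ̄ x = 0
```

where `f` is the (vectorized) spectrum, `G` the unitary inverse DFT,
`x` the image, `R_Ω`/`R_Γ̄` diagonal restrictions to the measured band
and the background, ‖·‖_TV the isotropic total variation, and the
`M_i` are per-mode slack tensors carrying the weighted tensor trace
norm (the convex surrogate of multilinear rank; mode weights fixed at
1/3 each for 3D volumes). `f0′` is the observed spectrum after
slice-profile deconvolution (below). Setting λ_LR = ε = 0 gives the
TV-only variant (TVG); setting additionally λ_TV = 0 reduces the
program to the Gerchberg model, and the solver's limit then coincides
with the POCS solution on consistent data (verified against the POCS
iteration and, on one-axis instances, against a dense linear solve).

## Observation model

The simulator degrades an isotropic ground truth along one axis per
observation: slice-profile blur, decimation by β, then i.i.d. Gaussian
noise with σ = (noise level in % / 100) × max(truth) — the
percent-of-peak convention of the standard simulated brain phantoms.
Two profiles are implemented:

* **rectangular** (default): non-overlapping block means of length β —
  uniform slice excitation with thickness equal to spacing;
* **gaussian**: zero-phase periodic Gaussian of FWHM β voxels, then
  every-β-th sampling.

The embedding of a low-resolution spectrum on the high-resolution grid
is scaled by √β (exactness at β = 1 under the unitary DFT convention)
and phase-corrected for the half-kernel offset of block-aligned
averaging, so that each axis response P_Ξ is real (a Dirichlet kernel
for the boxcar). Each observation's coefficients are divided by its own
response (spectrum deconvolution `F0′ = F0 ⊘ P_Ξ`) *before* fusing
observations, so that two observations of the same object agree on the
overlap of their bands and are simply averaged there. Deconvolution is
guarded by a floor: indices where |P_Ξ| < 0.05 are dropped from Ω
rather than amplified. When the band size N/β is even its Nyquist bin
is excluded so Ω stays conjugate-symmetric. Aliasing of out-of-band
truth energy into the band is part of the measurement model, not an
error: it is exactly what a real block-averaged acquisition does.

## ADMM

The augmented Lagrangian adds duals z (TV split y = Lx), α (spectrum
consensus x = Gf) and γ (support), all with one fixed penalty ρ
(default 1, no residual balancing), plus scaled duals v_i for the
slack coupling. Each block update is the exact minimizer of the
augmented Lagrangian over its block:

* **f**: per-coefficient diagonal solve, denominator 1+ρ on Ω and ρ on
  Ω̄ (the unitary DFT makes Gᴴ the inverse, so no scale factors);
* **x**: conjugate gradients on the SPD system
  (3εI + ρI + ρR_Γ̄ + ρLᵀL), preconditioned by the Fourier diagonal of
  the circulant part with R_Γ̄ replaced by its mean, warm-started from
  the previous iterate;
* **y**: group soft-threshold (prox of the l_{1,2} norm) at λ_TV/ρ;
* **M_i**: singular value thresholding of unfold_i(x + v_i) at
  λ_LR/(3ε) — the shrunk singular values double as the nuclear norms
  in the cost, so the objective costs no extra SVDs;
* duals: v_i with unit step, z, α, γ with step ρ.

The update expressions are derived from stationarity of the augmented
Lagrangian itself; the test suite verifies each block by
finite-difference gradients and random-perturbation optimality, which
pins down the ρ factors and signs unambiguously.

Finite differences use periodic boundaries, so LᵀL is circulant and
diagonal in the DFT basis — this is what makes the preconditioner and
the x-system analysis cheap. The periodic wrap-around has no visible
effect here because the phantom support never touches the grid
boundary (generation enforces a ≥2-voxel margin).

### Initialization, stopping, degenerate cases

* x starts at the zero-filled reconstruction idft3(f0′), f at f0′, all
  splits and duals at zero.
* Stopping: relative objective change < tol (default 1e-7) **and**
  relative image change < √tol. The second condition exists because in
  the zero-regularization limit on noise-free data the objective starts
  at exactly zero and its change alone would stop the run before the
  support constraint has acted.
* The cost reported for iteration 1 is computed while all duals are
  still zero, which suppresses the constraint-coupling terms; the
  descent property therefore applies from the second sweep onward, and
  `diagnostics["initial_objective"]` records that value.
* λ_LR > 0 with ε = 0 is rejected at configuration time (the low-rank
  slacks couple to x only through ε).
* The support constraint holds exactly only in the limit, so the
  returned volume is hard-projected (background zeroed) at the end;
  diagnostics report the pre-projection residuals.
* Divergence (objective exceeding 10⁶ × its initial value) raises with
  the history attached. No randomness anywhere: identical inputs give
  bit-identical outputs.

## Baselines

Nearest-neighbour and cubic-spline interpolation act along each
through-slice axis (low-res sample j sits at block center
jβ + (β−1)/2) and average multiple observations voxelwise. Zero-padding
(ZP) inverts the measured spectrum with Ω̄ set to zero. The TV and LRTV
baselines minimize an image-domain fidelity ½Σ_d‖A_d x − x0_d‖² built
from the known forward operator of each observation (the PSF is assumed
known) with the same TV / trace-norm machinery; they have no support
constraint and no spectrum variable.

## Evaluation protocol

PSNR = 10·log10(MAX²/MSE) with the MSE averaged over the object region
Γ only and MAX the global maximum of the ground truth (the peak
convention is stated because the score is otherwise ill-defined); a
zero-error reconstruction reports the 300 dB cap. Boundary-sensitivity
experiments perturb Γ by thresholding the signed Euclidean distance
transform at ±d voxels (half-voxel boundary offset, so d = 0 is the
identity) and always score inside the *true* Γ. The experiment driver
runs style × lesion × β × noise × method grids, with a log-spaced λ
grid search (4 decades, 5 points per parameter) standing in for the
per-image manual tuning that spectrum-fitting methods need in practice;
results stream to CSV and interrupted runs resume.

## Synthetic phantoms, and what the tests do not show

The phantom is three nested ellipsoidal shells with piecewise-constant
intensities (contrast ordering inverted between the T1-like and T2-like
styles, optional lesion blobs strictly inside the support), compact
support with a ≥2-voxel margin, deterministic per seed. It reproduces
the features the method's priors address — compact support, sharp
edges, low effective rank, percent-of-peak Gaussian noise — but none of
the features that make real MR hard: no partial-volume ramps, no bias
field, no Rician noise floor, no anatomical texture, and the support
label is exact by construction rather than segmented. Passing tests
therefore validate the optimization and the measurement model, not
clinical performance; the boundary-perturbation experiment is the only
probe of label error.

Default problem sizes are chosen for desk-scale runs: 48³ for grid
experiments, 32³ for convergence studies, 16³ for oracle comparisons
(single reconstructions at 128³ remain practical). At 48³ a ±2-voxel
boundary perturbation is a several-fold larger relative label error
than the same perturbation on a 220³ clinical volume, which compresses
the dilation side of the boundary experiment toward its tolerance.

## Known limitations

* The blur kernel must be known (no blind deconvolution) and noise is
  modeled Gaussian; both are inherited from the data-fidelity term.
* An underestimated support label is catastrophic by design: true
  signal outside Γ is treated as noise and projected away.
* λ_TV and λ_LR require per-image tuning; the grid search automates
  but does not remove this.
* ρ is fixed; no adaptive penalty or acceleration is attempted.
* Tensor modes are fixed at 3; SVT is restricted to real matrices.
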