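# lrtvg — spectrum-fidelity MRI super-resolution

Clinical MR volumes are anisotropic: slice thickness is set several
times the in-plane voxel size to buy signal-to-noise, so the
through-slice resolution is a factor β coarser. Each such acquisition
measures only a low-frequency band of the 3D spectrum along its
through-slice axis; even two orthogonal acquisitions leave the diagonal
high-frequency corners of k-space unmeasured. This package reconstructs
an isotropic volume by **extrapolating the unmeasured spectrum** under
convex priors, for researchers who want a model-based (non-learned)
super-resolution method whose assumptions are explicit and checkable.

## The model

With `f` the spectrum estimate, `x = G f` its image (G the unitary
inverse DFT), `R_Ω` the restriction to the measured band, `R_Γ̄` the
restriction to the known background, and mode-wise slack tensors `M_i`:

```
minimize_f   λ_TV ‖x‖_TV  +  (λ_LR/3) Σ_i ‖unfold_i(M_i)‖_*
           + ½ ‖f0′ − R_Ω f‖²
           + (ε/2) Σ_i ( ‖x − m_i + v_i‖² − ‖v_i‖² )
subject to   x = G f ,    R_Γ̄ x = 0
```

i.e. measured-spectrum fidelity (after slice-profile deconvolution
`f0′ = f0 ⊘ P_Ξ`), isotropic total variation, a weighted tensor trace
norm as a convex low-rank surrogate, and an exact object-support
constraint — the two constraints of the classic Gerchberg POCS
algorithm, which this program generalizes: with λ_TV = λ_LR = 0 the
solver's limit is the Gerchberg reconstruction (`LRTVG`); λ_LR = ε = 0
gives the TV-only variant (`TVG`). The program is solved by ADMM with
closed-form block updates (diagonal spectrum solve, preconditioned CG
for the image, group soft-thresholding for TV, singular value
thresholding for the trace norm). See `docs/methods.md` for the full
derivation, parameter semantics and limitations.

Also included: a synthetic phantom generator with the full anisotropic
observation model (slice-profile blur, decimation, percent-of-peak
Gaussian noise, spectrum assembly from multiple orientations), the
Gerchberg baseline, interpolation/zero-padding/TV/LRTV baselines,
region-restricted PSNR scoring, boundary-label perturbation, and an
experiment grid driver.

## Worked example

Simulate a 32³ phantom observed twice (orthogonal through-slice axes,
β = 4, 1% noise), reconstruct, and score:

```sh
lrtvg simulate --shape 32 --beta 4 --noise 1 --seed 7 -o demo/
lrtvg reconstruct --method lrtvg \
    --spectrum-prefix demo/spectrum --support demo/support.nii.gz \
    --lambda-tv 0.01 --lambda-lr 0.01 --max-iter 400 --tol 1e-7 \
    -o demo/lrtvg.nii.gz --diagnostics demo/diag.json
lrtvg reconstruct --method zp \
    --spectrum-prefix demo/spectrum --support demo/support.nii.gz \
    -o demo/zp.nii.gz
lrtvg evaluate --estimate demo/lrtvg.nii.gz \
    --truth demo/truth.nii.gz --mask demo/support.nii.gz
lrtvg evaluate --estimate demo/zp.nii.gz \
    --truth demo/truth.nii.gz --mask demo/support.nii.gz
```

prints

```
PSNR: 23.7582 dB
PSNR: 20.4896 dB
```

— the regularized spectrum extrapolation gains ≈3.3 dB inside the
object region over zero-padded inversion of the same measured
spectrum, converging in 346 ADMM iterations (`demo/diag.json` holds the
cost and residual histories). `simulate` writes the ground truth,
support mask, the two low-resolution observations (β mm slice spacing
recorded in the NIfTI affine) and the assembled spectrum as a
real/imaginary/mask NIfTI triple.

The same pipeline is available as a library:

```python
from lrtvg import (make_phantom, degrade, assemble_spectrum,
                   SolverConfig, solve, psnr_in_region)

p = make_phantom((48, 48, 48), style="t1like", seed=0)
obs = [degrade(p, axis=2, beta=4, noise_pct=1.0, seed=1),
       degrade(p, axis=1, beta=4, noise_pct=1.0, seed=2)]
data = assemble_spectrum(obs, p.shape)
res = solve(data, p.support, SolverConfig(lambda_tv=0.01, lambda_lr=0.01))
print(psnr_in_region(res.volume, p.truth, p.support))
```

Grid experiments are driven by YAML descriptions
(`lrtvg experiment grid.yaml -o results.csv`); see
`lrtvg --help` and `lrtvg experiment --help`.

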