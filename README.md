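# tvdti

Noise-adaptive total-variation regularization of the diffusion tensor, with
ICA-based noise extraction, a software phantom and deterministic streamline
tractography.

## The problem

High-resolution diffusion tensor imaging (DTI) — e.g. readout-segmented EPI
at 1 × 1 × 2.5 mm³ — trades signal-to-noise for resolution: a
clinically feasible single-average acquisition is too noisy for reliable
fiber tractography, while averaging to acceptable SNR multiplies scan time.
`tvdti` implements a denoising pipeline that operates **on the diffusion
tensor field itself**, with the regularization strength chosen
**automatically and per voxel** from the measured noise level, so that deep
regions (low coil sensitivity, high g-factor noise) are smoothed more than
cortical regions, without user tuning.

The pipeline:

1. **ICA noise extraction** — each axial slice of the N-direction DWI
   series is decomposed into N independent spatial components (FastICA).
   Components with high lag-1 spatial autocorrelation carry tissue and
   directed-diffusion information (six of them, one per independent tensor
   element); spatially white components carry noise. Zeroing one group and
   inverting the mixing yields a denoised series `Ŝ` and a matched noise
   series `ε = S − Ŝ`.
2. **Tensor fit and noise projection** — the Stejskal–Tanner model
   `S_i = S₀·exp(−b gᵢᵀ D gᵢ)` is log-linearized, `yᵢ = ln(S₀/Sᵢ)/b = Bᵢ·d`,
   and solved by linear least squares `d = (BᵀB)⁻¹Bᵀy`. The same
   pseudoinverse projects the noise series into tensor space
   (`d_ε = (BᵀB)⁻¹Bᵀ(−ε/(b Ŝ))`), giving per-element noise maps.
3. **Adaptive TV regularization** — per axial slice, the tensor field is
   denoised by minimizing a channel-coupled total-variation seminorm (the
   Frobenius norm of the stacked element gradients, off-diagonals counted
   twice) plus a weighted fidelity term. The solver is the Chambolle dual
   projection scheme (stable for dual step τ ≤ 1/8); the scalar
   regularization parameter is replaced by a **regularization tensor** —
   one fidelity weight per voxel per element — updated every outer
   iteration so the local residual RMS (5 × 5 window) matches the local
   noise standard deviation estimated from the projected noise tensor
   (the discrepancy principle, localized).
4. **PSD repair and tractography** — negative eigenvalues are clamped to
   zero, then deterministic FACT-style streamlining (45° angle threshold,
   FA seed threshold 0.15) produces tracts and the four summary metrics:
   mean length ML (mm), track count TC, volume V (ml), voxel count VC.

Because no suitable public dataset accompanies the method, the package
ships a first-class software phantom: axis-aligned fiber bundles with
white-matter eigenvalues built directly in tensor space, Stejskal–Tanner
forward synthesis, and tensor-space noise whose standard deviation rises
toward the grid center (as coil-array noise does in vivo).

## Worked example

```python
import numpy as np
from tvdti import (
    reference_phantom, reference_noise_model, make_noise_tensor_field,
    add_tensor_noise, regularize_tensor_field, TVSolveOptions,
    enforce_psd, track, tract_metrics,
)

tensors, labels = reference_phantom()          # 60x60x20, three bundles
noise = make_noise_tensor_field(tensors.grid, reference_noise_model(seed=1))
noisy = add_tensor_noise(tensors, noise)

reg = regularize_tensor_field(noisy, noise, TVSolveOptions(), psd_after=True)

for name, field in [("noise-free", tensors),
                    ("noisy", enforce_psd(noisy)),
                    ("regularized", reg)]:
    m = tract_metrics(track(field, min_length_mm=20.0))
    print(f"{name:12s} ML {m.mean_length:6.1f} mm  TC {m.track_count:5d}  "
          f"V {m.volume:6.2f} ml  VC {m.voxel_count}")
```

prints

```
noise-free   ML   46.4 mm  TC  4160  V  10.40 ml  VC 4160
noisy        ML   28.4 mm  TC   625  V   5.65 ml  VC 2260
regularized  ML   45.5 mm  TC  4901  V  14.62 ml  VC 5849
```

Noise breaks the tracts (mean length collapses, most seeds lost); the
adaptive regularization restores the mean fiber length to within ~2% of the
noise-free gold standard. The same experiment over ten noise realizations,
with means and standard deviations per condition, is available as
`run_phantom_experiment` / `tvdti phantom-experiment`.

## Command line

```bash
tvdti phantom --config phantom.yaml --out-prefix P
tvdti denoise --dwi dwi.nii.gz --bval dwi.bval --bvec dwi.bvec \
      --seed 17 --out-denoised D.nii.gz --out-noise E.nii.gz
tvdti fit --dwi ... --bval ... --bvec ... --out-tensor T.nii.gz \
      --out-noise-tensor NT.nii.gz --out-fa FA.nii.gz
tvdti regularize --tensor T.nii.gz --noise-tensor NT.nii.gz --out T_reg.nii.gz
tvdti track --tensor T_reg.nii.gz --angle 45 --fa-thresh 0.15 \
      --out tracks.trk --metrics metrics.json
tvdti pipeline --config run.yaml
tvdti phantom-experiment --realizations 10 --out report.json
```

Inputs are 4D NIfTI-1 volumes with FSL-style `.bval`/`.bvec` tables
(eddy-current-corrected and brain-extracted upstream); streamlines are
written as TrackVis `.trk`.

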