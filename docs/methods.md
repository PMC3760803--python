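# Methods

This note documents the models, numerical choices and defaults behind
`tvdti`, what the synthetic data emulate, and what the tests do and do not
establish about real data.

## Signal model and tensor estimation

The diffusion-weighted signal follows the Stejskal–Tanner equation
`S_i = S₀ exp(−b gᵢᵀ D gᵢ)` with a single b-value (s/mm²), unit encoding
directions `gᵢ` and a symmetric positive-semidefinite tensor `D` (mm²/s).
Taking logs gives `yᵢ = ln(S₀/Sᵢ)/b = Bᵢ·d`, where row `i` of the design
matrix is `(g_x², g_y², g_z², 2g_xg_y, 2g_xg_z, 2g_yg_z)` and
`d = (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)` — this channel order is fixed
project-wide. The least-squares solution `d = (BᵀB)⁻¹Bᵀy` requires rank-6
`B`, hence at least six well-spread directions; the reference configuration
is 12 directions at b = 1000 s/mm² (a Fibonacci hemisphere lattice,
condition number ≈ 1.7).

Numerical guards: signals are floored at `1e-6·S₀` before the log; voxels
with `S₀ ≤ 0` get a zero tensor and a cleared mask flag.

**Noise projection.** Additive DWI noise `ε` on a denoised signal `Ŝ`
perturbs the log-linearization, to first order, by `y_ε = −ε/(b Ŝ)`;
applying the cached pseudoinverse yields the *noise tensor*
`d_ε = (BᵀB)⁻¹Bᵀ y_ε`. The sign makes the first-order identity
`fit(Ŝ+ε) − fit(Ŝ) ≈ d_ε` hold exactly in the linearized regime (verified
to < 5% relative error at ε = 0.5% of Ŝ); for the downstream use — local
noise *variance* per tensor element — the sign is immaterial. The b = 0
image is treated as noise-free: noise is extracted only from the N
weighted volumes.

**PSD repair.** Negative eigenvalues (possible after noise addition or
regularization) are clamped to zero, keeping eigenvectors. The repair is
applied *after* regularization and before tractography (exposed as
`psd_after`); a rounding-scale tolerance (`1e-13` × spectral radius) makes
it exactly idempotent.

## ICA noise extraction

Each axial slice's N direction images are modeled as N linear mixtures of
N independent spatial source maps and unmixed with FastICA (real-valued,
magnitude data; unit-variance whitening; seeded, hence deterministic).
Components are classified by lag-1 spatial autocorrelation (mean of the
x- and y-shift Pearson correlations): above 0.2 → signal, else noise.
Noise components of an MR acquisition are spatially white (autocorrelation
≈ 0) while tissue/diffusion components are smooth (≈ 0.7–0.9 on the
synthetic data), so the threshold sits in a wide gap; crucially the
classifier depends on component *content*, never on component order, which
keeps the six-signal-component outcome a testable prediction rather than
an assumption. Six components carry signal because a symmetric tensor has
six independent elements, independent of the direction count.

The denoised series is `Ŝ = A·(signal components) + mean`; the noise
series is defined as `ε = S − Ŝ`, so completeness `Ŝ + ε = S` holds
exactly by construction. The removed per-image mean is assigned to the
signal share (it is the mean anatomy). Slices with no content pass through
unchanged. FastICA's convergence warning is suppressed inside
`decompose_slice`: on data whose noise subspace is i.i.d. Gaussian the
within-subspace rotation is indeterminate, which FastICA reports as
non-convergence although the factorization and reconstruction are
unaffected.

Limitations: the ICA operates on magnitude data (complex raw data are out
of scope), and residual motion/distortion artifacts would appear as extra
structured components — input data must be corrected upstream.

## Adaptive total-variation regularization

**Scalar core (ROF).** `min_u TV(u) + 1/(2λ)‖u−f‖²` is solved on the dual
by the Chambolle fixed-point projection: forward-difference gradient,
matching negative-adjoint (backward-difference) divergence, Neumann
boundaries, semi-implicit update
`p ← (p + τ∇u)/(1 + τ|∇u|)` with `u = f + λ div p`, stable for τ ≤ 1/8
in 2D (the dual energy is checked to be non-increasing in tests). When the
noise level σ is known, λ is re-locked every outer iteration from the
discrepancy principle, `λ ← σ√N/‖div p‖`, driving `‖u−f‖ → σ√N`
(converged to within 0.5%, contract 2%). Because the dual fixed point
converges at O(1/k), a polishing budget (default 10 000 extra dual steps,
interleaved with λ re-locking) tightens the solution to < 1e-3 of the
image range against an independently coded projected-gradient ROF
minimizer; σ = 0 returns the input unchanged, and a constant image is its
own solution for any σ.

**Tensor extension.** The six element channels are scaled by
`√w, w = (1,1,1,2,2,2)` (so the channel-coupled TV is the true
symmetric-matrix Frobenius seminorm and the fidelity the Frobenius
distance) and denoised jointly: the dual projection couples channels
through the joint gradient norm (a channel-decoupled mode is available for
ablation). The scalar λ becomes a *regularization tensor* — an independent
reciprocal-fidelity scale `L_e(x)` per voxel per element:

* initialization `L⁰ = σ_loc` (equivalently Λ⁰ ∝ 1/σ_loc), where
  `σ_loc` is the local noise std from the variance tensor — the per-element
  sample variance of the projected noise tensor in a 5 × 5 in-slice moving
  window (shrinking at the edges);
* each outer iteration multiplies `L_e(x)` by
  `clip(σ_loc/RMS_loc(u−f), 0.5, 2)` — the localized discrepancy
  principle, computed over the same 5 × 5 window;
* `L` is capped at 5 × σ_loc: in flat regions the local discrepancy
  equation has no solution (the residual RMS stays below the estimated σ
  no matter how strong the smoothing), so the multiplicative update would
  diverge, and beyond a few times the noise scale additional smoothing
  only erodes structure;
* zero-variance elements keep `L = 0`, i.e. infinite fidelity weight — the
  input passes through exactly;
* dual steps are taken per pixel at `τ/L` (the dual constraint set is
  separable per pixel; the local bound covers the 3 × 3 neighborhood a
  dual component feeds through the divergence). A global step `τ/max L`
  would let a handful of high-L voxels stall the entire slice.

The outer loop stops when the relative change of the solution drops below
1e-4 or after 50 iterations (then a `ConvergenceWarning` is emitted and
the last iterate returned). Regularization is strictly per axial slice —
in-plane voxels are isotropic (1 × 1 mm) so no grid-spacing weights are
needed, and the anisotropic through-plane direction never enters; 3D
regularization is out of scope. Converged behavior: in interior
homogeneous regions the per-element local residual RMS matches the local
noise std within 10%, the final Λ is smaller (stronger smoothing) where
the noise is higher, and the result is insensitive to the Λ⁰ scale
(residual varies < 3% over a 10× initialization range).

## Software phantom

The phantom is built directly in tensor space on a 60 × 60 × 20 grid of
1 × 1 × 2.5 mm³ voxels (the in-vivo voxel geometry at desk scale): three
orthogonal, non-overlapping bundles with white-matter eigenvalues
(1.7e-3, 3e-4, 3e-4) mm²/s (FA 0.799) in an isotropic 0.7e-3 mm²/s
background. The in-plane bundles are 40 and 50 voxels long; the
through-plane bundle spans the full 20 slices — with 2.5 mm slices all
three are 40–50 mm of physical fiber, the same scale in every direction
(the z extent of the grid cannot hold 40 voxels).

**Noise.** Tensor-space noise is zero-mean Gaussian per element with
standard deviation `base_sigma × gain(r)`, where the gain falls linearly
in physical radius from `center_gain` at the grid center to 1 at the
corner — a monotone surrogate for the center-heavy noise of multi-channel
head-coil acquisitions. Reference conditions: `base_sigma = 2e-4` mm²/s
(the scale implied by ~5% signal noise at b = 1000 propagated through the
log-linearized fit, i.e. a single-average high-resolution acquisition) and
`center_gain = 3`, so central noise reaches 6e-4 ≈ 2× the transverse
eigenvalue. This is the regime the method targets: centrally the noise
collapses streamline tractography (the mean tract length drops by ~40%
and most seeds are lost) and produces negative eigenvalues, yet the spatially adaptive
regularization restores tract metrics to within a few percent of the
noise-free gold standard. Signal-space Gaussian noise on the DWI
magnitudes is available separately (reference SNR 20, σ = 5% of S₀) and is
the path the ICA stage is tested on.

What the phantom does *not* emulate: Rician magnitude bias, crossing
fibers, partial-volume gradients at bundle boundaries, anatomical
curvature, and spatially correlated (physiological) noise. Passing tests
therefore demonstrate correctness of the algorithms under the stated
model, not clinical performance.

The smooth random tensor field used in the ICA tests applies a signed
square to Gaussian-filtered white noise per element: element maps become
heavy-tailed (sparse, bundle-like), which matches anatomy better than a
Gaussian field and is required for blind source separation to resolve the
signal subspace (ICA cannot separate jointly Gaussian sources).

## Tractography

FACT-style deterministic streamlining: one seed at the center of every
voxel with FA ≥ 0.15, bidirectional integration at step = half the
smallest voxel dimension, nearest-neighbor principal-eigenvector lookup
with sign alignment to the previous step, termination on FA below
threshold, grid exit, or turning angle > 45° (the one convention fixed by
the protocol); length capped at 10× the grid diagonal. No randomness
anywhere — identical inputs give identical streamline sets. Metrics:
ML = mean polyline arc length (mm), TC = streamline count, VC = distinct
voxels intersected (dense segment sampling at a quarter voxel, validated
against brute-force rasterization), V = VC × voxel volume (ml).

The pipeline applies a minimum tract length of 20 mm — half the shortest
phantom bundle and within the 10–30 mm range standard in whole-brain
tract analysis. Without it, sub-centimeter fragments dominate TC/ML in the
noisy condition: additive tensor noise makes isotropic voxels spuriously
anisotropic (FA of a noise-perturbed isotropic tensor easily exceeds
0.15), seeding one-to-three-voxel tracks that no published tract analysis
would count. `track()` itself defaults to no filter. Absolute metric
values are implementation-dependent (step size, interpolation and seeding
conventions differ between trackers); the phantom experiment is therefore
evaluated on the *pattern* — noisy ≪ noise-free, regularized within a few
percent of noise-free — not on absolute numbers.

## Pipeline and reproducibility

`run_pipeline` chains ICA denoise → tensor fit → noise projection →
variance tensor → adaptive regularization → PSD repair → tracking →
metrics, writing every intermediate volume, the resolved YAML config and
the metrics JSON. A single config seed fans out deterministically to
per-stage seeds via stage-name hashing (all derived seeds < 2³¹), so any
stage can be rerun in isolation; every stage logs parameters, duration and
content hashes. `run_phantom_experiment` evaluates noise-free, noisy
(mean ± std over n realizations, default 10) and noisy + regularized
conditions on the reference phantom.

Problem sizes used by the test suite and the acceptance script: 32 × 32
images for the scalar-solver oracles, 40 × 40 slices for the ICA checks,
and the full 60 × 60 × 20 phantom with 10 noise realizations for the
tract-metric experiment — small enough to run on a laptop in minutes while
leaving every statistical contract comfortably powered.

## Known limitations

* 2D (per-slice) regularization only; through-plane discontinuities are
  untouched.
* Real-valued ICA on magnitudes; complex scanner data are not modeled.
* Single-shell acquisitions only; no weighted/iterative or constrained
  (Cholesky) tensor fitting — PSD is restored by eigenvalue clamping.
* The tracker is intentionally minimal (nearest-neighbor, fixed step); it
  is an evaluation surface, not a clinical tractography tool.
* The local-residual matching is statistical: in voxels where the windowed
  variance estimate is badly off (≈30% relative error at 5 × 5), the
  per-voxel regularization weight inherits that error; only its cap keeps
  the update bounded.
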