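# Methods

## Acquisition model

One multi-band slice group is modelled at a time. The per-shot forward model
maps shot images `x[q,s,z]` (diffusion encoding `q`, shot `s`, band `z`) to
collapsed multi-coil k-space

```
y[c,q,s] = P[q,s] · Σ_z · Θ_z · F · S[c,z] · x[q,s,z]          (E1)
```

with `S` the coil sensitivities, `F` a centered orthonormal 2-D DFT
(image → k-space; with full sampling, one band and RSS-normalized coils the
chain is an isometry, which the tests exploit), `Θ_z` the CAIPI modulation
`exp(i 2π z ky / MB)` along the phase-encode index (an image-domain circular
shift of band `z` by `−ny·z/MB` pixels under this sign convention), `Σ_z` the
band collapse, and `P` the binary ky mask of shot `s` at encoding `q`. The
readout axis is always fully sampled (EPI). Shot-combined encoding is
`E2 = E1 Φ`, where `Φ[q,s,z]` is a unit-modulus shot-phase map multiplying
the shot-combined image `x̃[q,z]`.

Sampling follows the interleave rule
`ky = Δ(q) + s·R + j·(R·N_shot)` with `Δ(q) = q mod R` under ky-shift
encoding (`Δ ≡ 0` otherwise), where `q` counts diffusion-weighted volumes
only — interspersed b0 volumes reuse the current shift. ky indices are
0-based with DC at `ny/2`. The segment undersampling factor is `R·N_shot`
and the effective echo spacing `ESP/(R·N_shot)`.

## Three-step reconstruction

**Step I — navigator images.** Per-shot navigator k-space (own grid, in-plane
factor `R`) is reconstructed by CG on `(E1ᴴE1 + λ_nav I) x = E1ᴴ y`. Default
`λ_nav = 1e-4` with up to 300 CG iterations (tolerance 1e-6): the navigator
problem is small, so a near-unregularized solve is affordable and keeps phase
bias low. For **self-navigated** acquisitions the central quarter (per axis)
of each segment's k-space stands in for the navigator; because a segment
carries the full `R·N_shot` undersampling there, the plain l2 solve degrades
badly, and Step I instead reuses the joint LLR-ADMM solve of Step III with
the shot axis folded into the diffusion axis and unit shot phases. Coil maps
are transferred to the navigator grid by central k-space cropping and RSS
renormalization.

**Step II — phase smoothing.** Each navigator image is filtered by
`F⁻¹ H_K F` with a separable raised-cosine window, unity at DC, half-width
`N/(K+1)` grid points per axis; larger `K` narrows the passband, and `K = 0`
returns the input unchanged. The adaptivity (window width tied to grid size
and a single integer `K`) is this package's parameterization; it reproduces
the qualitative behaviour that moderate `K` removes reconstruction ripple
while `K ≈ 20` oversmooths genuine phase variation. The smoothed navigator
k-space is zero-padded to the imaging grid and only the phase is kept,
`Φ = exp(i·arg(·))` (pixels of exactly zero magnitude get phase 0). Shot 0 of
each encoding is pinned as the zero-phase reference; only shot-relative phase
is observable.

**Step III — joint ADMM.** All encodings of the group are reconstructed
jointly:

```
argmin_x̃  ‖y − E2 x̃‖₂² + λ‖T(x̃)‖*
```

`T` slides a `b×b` window (anchors on the stride grid plus an edge-flush
final anchor per axis; fixed across iterations) over all DW images of a band
and stacks each patch set into a `(b², Q)` spatial-diffusion matrix. Patch
matrices are built per band. Scaled ADMM iterates

1. x-update: CG on `‖y − E2 x‖² + (ρ/2)‖x − T̃ᴴ(v − u)‖²`, warm-started
   (10 inner iterations or relative residual 1e-6). `T̃ᴴ` is the
   overlap-normalized adjoint `Tᴴ(·)/Tᴴ(T(1))`, an exact left inverse of
   `T`; using it makes the coupling a plain Tikhonov term in the x-update.
2. v-update: width-normalized SVT of `T(x) + u` — singular values are
   divided by `b`, soft-thresholded at `λ/ρ`, and rescaled by `b` (equal to
   the nuclear-norm prox with effective threshold `λb/ρ`). The
   normalization keeps a given `λ` comparable across block widths.
3. u-update: `u ← u + T(x) − v`.

Defaults: 15 outer iterations, `ρ = 0.05`, `λ = 0.01`, block width 6,
stride 1. With `λ = 0` the v/u updates are inert and the iteration converges
to the plain CG-SENSE solution (verified to 1e-4 relative on a well-posed
system). Inside `admm_solve` the data are scaled by the peak magnitude of the
zero-filled adjoint image and scaled back on return, so the default
`λ, ρ` act on an O(1) image scale regardless of input units. The per-iteration
history records data consistency, the summed singular values of `T(x)`, and
the composite objective; because the x-update is inexact, the objective may
show a ≲1e-4-relative transient in the first iterations before decreasing.
Long series can be split into contiguous batches along `q` reconstructed
independently (remainder to the last batch); with `λ = 0` the split is
exactly equivalent to the joint solve since the data term separates over `q`.

Complex arithmetic is double precision by default; the CLI offers a
single-precision mode for memory-limited runs.

## Synthetic acquisitions

The simulator emulates three desk-scale protocol styles on 48×48 (or 40×40)
grids: a four-shot fully sampled (union) single-shell navigator-based
acquisition used for the retrospective ky-shift study; a two-shot, R = 2,
MB = 2 three-shell (6/6/8 directions at b = 1000/2000/3000 s/mm²)
self-navigated acquisition; and a five-shot, R = 2 navigator-based trace
acquisition. One b0 volume is interspersed ahead of every block of ten
diffusion volumes. Diffusion directions are spherical-Fibonacci sets rotated
by a seeded random rotation per shell — approximately uniform and exactly
reproducible; partial Fourier is not modelled.

Ground truth is an ellipse phantom with labelled compartments: strongly
anisotropic (eigenvalues 1.7/0.2/0.2 ×10⁻³ mm²/s, FA ≈ 0.87), isotropic
(0.8×10⁻³, FA = 0), moderately anisotropic (1.2/0.4/0.3 ×10⁻³), and isotropic
background (1.0×10⁻³), with gentle smooth shading on S0 and band-dependent
layout. Signals follow the monoexponential tensor model
`S = S0 · exp(−b gᵀ D g)`. Coil sensitivities are Gaussian lobes around the
FOV with low-order polynomial phase, RSS-normalized; lobe geometry varies
with the band, since multi-band separation is impossible when simultaneously
excited slices see identical sensitivities. Shot phases are random 2-D
polynomials (default order 2, coefficient RMS 0.8 rad — a moderate
physiological level), with shot 0 of each encoding as zero-phase reference.
Noise is i.i.d. circular complex Gaussian added only at sampled k-space
entries; with orthonormal FFT scaling and unit-RSS coils, `σ` equals the
image-domain noise level, so `σ = S0/SNR` targets a given b0 image SNR.
Navigator echoes are simulated by central k-space truncation of the phased
shot images to the navigator grid, with per-shot offset `s mod R` for the
navigator's own in-plane undersampling.

What the simulator does **not** emulate: T2*/T2 decay during readout,
off-resonance distortion, eddy currents, ghosting, bulk motion beyond smooth
shot phases, coil noise correlation, and Rician effects beyond those induced
by taking magnitudes after reconstruction. Passing tests therefore establish
algorithmic correctness and the expected qualitative behaviours (ky-shift
benefit, LLR denoising, phase-navigation accuracy), not robustness to
scanner non-idealities.

## Diffusion tensor fit and ROI statistics

`tensor_fit` is a per-voxel ordinary least-squares fit of
`log S = log S0 − b gᵀ D g` over all volumes (≥ 6 directions plus ≥ 1 b0
required); voxels with non-positive signal or outside the support are
skipped. FA is computed from the eigenvalues. For compartment-level checks
the package reports the FA of the ROI-mean tensor (tensors averaged over the
compartment, FA of the average): at moderate SNR the voxelwise mean of FA is
dominated by the well-known noise-floor inflation of the magnitude OLS
estimator (an oracle check shows a perfect reconstruction at SNR 20 inflates
an isotropic compartment's voxelwise mean FA by ≈ 0.2), whereas the mean
tensor cancels zero-mean errors and reflects reconstruction quality.

## Study sizes and numerical choices

Simulated studies use 48×48 matrices, 8 coils, and 20–22 volumes — sizes
chosen so each full pipeline run completes in tens of seconds while keeping
every acceleration mechanism (interleaving, in-plane undersampling,
multi-band, ky shift) active. SSIM uses Gaussian weighting (σ = 1.5),
K1 = 0.01, K2 = 0.03, dynamic range set by the reference maximum, on
magnitude images normalized to the reference. Degenerate inputs are handled
explicitly: zero k-space returns a zero reconstruction; `arg(0) := 0` in
phase maps; anchors always cover every pixel or the scaling map construction
raises.

## Known limitations

* Self-navigated phase estimation remains the accuracy bottleneck
  (≈ 0.18 rad RMS at 4× segment undersampling on a 12×12 self-navigator
  versus ≈ 0.07 rad with a true navigator echo); acquisitions designed for
  self-navigation at high shot counts will show residual shot-combination
  error.
* LLR patch matrices are formed per band; stacking bands into the diffusion
  dimension is a possible variant not enabled by default.
* The CAIPI modulation is a pure linear-phase (image-shift) model; blip-wise
  phase history effects are not modelled.
* No Rician bias correction is applied before the tensor fit.
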