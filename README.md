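# msdwi — joint k-q-slice reconstruction of multi-shot diffusion EPI

`msdwi` reconstructs diffusion-weighted MRI acquired with **ky-shift-encoded
interleaved multi-shot EPI**, optionally with simultaneous multi-slice (CAIPI)
excitation. It is aimed at MR-physics and image-reconstruction researchers who
want a compact, fully testable reference implementation of:

* interleaved-EPI sampling design with **ky-shift encoding** — the interleave
  pattern advances by one phase-encode line per diffusion encoding (cycling
  period `R_inplane`), so neighbouring encodings sample complementary k-space
  and a joint reconstruction across the diffusion dimension becomes effective
  at one shot per encoding;
* the multi-band multi-shot **SENSE forward models** with exact adjoints
  — per shot `y[c,q,s] = P_{q,s} Σ_z Θ_z F S_{c,z} x[q,s,z]` (`E1`), and
  shot-combined `E2 = E1 Φ` where `Φ` carries the unit-modulus shot-to-shot
  phase maps;
* **navigator-based shot-phase estimation** with adaptive Hanning smoothing
  `x ← F⁻¹ H_K F x` (window half-width `N/(K+1)` per axis; `K = 0` is the
  identity), including central-k-space self-navigation;
* joint reconstruction of all diffusion encodings by **ADMM** on

  ```
  argmin_x̃  ‖y − E2 x̃‖₂² + λ ‖T(x̃)‖*
  ```

  where `T` is the **overlapping locally-low-rank transform**: b×b patches of
  all DW images stacked into (b², Q) spatial-diffusion matrices, proximal step
  by width-normalized singular value thresholding at threshold `λ/ρ`, overlap
  handled by the exact scaling identity `T̃ᴴ(T(x)) = x` with
  `T̃ᴴ = T^H / T^H(T(1))`. Defaults: 15 iterations, ρ = 0.05, λ = 0.01,
  block width 6, stride 1.

Everything runs end-to-end on a bundled synthetic acquisition simulator
(tensor phantom, coil maps, smooth random shot phases, k-space synthesis
through `E1`, complex Gaussian noise), so all claims are verifiable without
scanner data.

## Worked example

```python
import numpy as np
from msdwi import (JointReconstruction, LLRConfig, SimulationConfig,
                   nrmse, protocol1_analog, simulate_acquisition)

# four-shot fully sampled (union) acquisition, 8 coils, noiseless
data = simulate_acquisition(SimulationConfig(protocol=protocol1_analog(),
                                             n_coils=8, noise_sigma=0.0, seed=0))
model = JointReconstruction(data, LLRConfig())   # estimates shot phases itself
res = model.fit()
print(res.summary())
print("NRMSE vs phantom:", round(nrmse(res.magnitude, np.abs(data.truth["dwis"])), 4))
```

prints

```
Joint k-q-slice reconstruction results
==============================================
diffusion encodings (q)                   22
bands (z)                                  1
matrix                               48 x 48
shots                                      4
lambda                                  0.01
rho                                     0.05
block width / stride                   6 / 1
ADMM iterations                           15
final data consistency            4.9028e+00
final objective                   1.6044e+02
NRMSE vs phantom: 0.0262
```

The 22 encodings are 20 diffusion directions plus one interspersed b0 volume
per block of ten. The 2.6 % residual against the phantom is dominated by the
navigator phase estimate (the same reconstruction with the true simulated
phases and λ = 0 reaches NRMSE ≈ 1e-6; see the tests).

A command-line driver mirrors the library:

```bash
msdwi simulate --out acq.h5 --protocol p1 --seed 0
msdwi recon    --in acq.h5 --out recon.nii.gz --history history.csv
msdwi eval     --in acq.h5 --recon recon.nii.gz --out metrics.csv
msdwi selftest
```

## Data layout

Acquisitions travel as an HDF5 container: `/kspace` complex (c, q, s, ny, nx),
`/nav_kspace` (optional), `/coil_maps` (c, z, ny, nx), `/masks` uint8
(q, s, ky), `/bvals`, `/bvecs` (b0 rows zero), `/protocol` attributes, and an
optional `/truth` group from the simulator. Reconstructions export as 4-D
NIfTI (x, y, z, q); gradient schemes export as FSL-style `bvals`/`bvecs` text.

See `docs/methods.md` for the model, parameter and design notes.
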