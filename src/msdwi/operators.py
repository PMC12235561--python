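"""Linear forward models for multi-shot, multi-band SENSE encoding.

Two encoding chains are implemented, together with their exact adjoints:

* per-shot model ``E1``:  ``y[c,q,s] = P[q,s] . sum_z Theta[z] . F . S[c,z] . x[q,s,z]``
* shot-combined model ``E2 = E1 . Phi`` where ``Phi`` multiplies the
  shot-combined image ``x~[q,z]`` by a unit-modulus shot-phase map.

Axis conventions (fixed throughout the package)::

    coil maps S       (c, z, ny, nx)
    shot images x     (q, s, z, ny, nx)
    combined DWIs x~  (q, z, ny, nx)
    shot phases phi   (q, s, z, ny, nx)
    k-space y         (c, q, s, ny, nx)   -- collapsed over bands z
    ky masks          (q, s, ny)

``F`` is the centered, orthonormal 2-D DFT (image -> k-space), so that with
full sampling, a single band and a unit coil the whole chain is unitary.
``Theta`` is the CAIPI inter-slice phase modulation along ky, ``P`` zeroes
unacquired ky lines, and the readout axis kx is always fully sampled.
"""

from __future__ import annotations

import warnings

import numpy as np

from .protocol import ProtocolSpec, SamplingPattern, caipi_slice_phase

__all__ = [
    "fft2c",
    "ifft2c",
    "apply_E1",
    "adjoint_E1",
    "apply_phase",
    "adjoint_phase",
    "apply_E2",
    "adjoint_E2",
    "check_unit_modulus",
]


class EncodingError(ValueError):
    """Raised on inconsistent operand shapes."""


def fft2c(img: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2-D FFT over the last two axes (image -> k)."""
    ax = (-2, -1)
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=ax), axes=ax, norm="ortho"), axes=ax
    )


def ifft2c(ksp: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2-D inverse FFT over the last two axes."""
    ax = (-2, -1)
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(ksp, axes=ax), axes=ax, norm="ortho"), axes=ax
    )


def _caipi_factors(protocol: ProtocolSpec, ny: int) -> np.ndarray:
    """exp(i * phase) per (z, ky), broadcastable over kx."""
    if protocol.mb_factor == 1:
        return np.ones((1, ny, 1))
    # nav grids reuse the imaging protocol's mb factor on their own ky length
    ky = np.arange(ny)
    z = np.arange(protocol.mb_factor)[:, None]
    return np.exp(2j * np.pi * z * ky / protocol.mb_factor)[:, :, None]


def _check_e1_shapes(x, maps, masks):
    q, s, z, ny, nx = x.shape
    if maps.shape[1:] != (z, ny, nx):
        raise EncodingError(f"coil maps shape {maps.shape} inconsistent with images {x.shape}")
    if masks.shape != (q, s, ny):
        raise EncodingError(f"mask shape {masks.shape} inconsistent with images {x.shape}")


def _masks_array(pattern) -> np.ndarray:
    return pattern.masks if isinstance(pattern, SamplingPattern) else np.asarray(pattern)


def apply_E1(
    x: np.ndarray,
    maps: np.ndarray,
    pattern: SamplingPattern | np.ndarray,
    protocol: ProtocolSpec,
) -> np.ndarray:
    """Per-shot forward model: shot images -> collapsed multi-coil k-space."""
    x = np.asarray(x)
    maps = np.asarray(maps)
    masks = _masks_array(pattern)
    _check_e1_shapes(x, maps, masks)
    theta = _caipi_factors(protocol, x.shape[-2])
    # (c,1,1,z,ny,nx) * (1,q,s,z,ny,nx)
    k = fft2c(maps[:, None, None] * x[None])
    k = (k * theta).sum(axis=3)
    return k * masks[None, :, :, :, None]


def adjoint_E1(
    y: np.ndarray,
    maps: np.ndarray,
    pattern: SamplingPattern | np.ndarray,
    protocol: ProtocolSpec,
) -> np.ndarray:
    """Exact adjoint of :func:`apply_E1`: k-space -> shot images."""
    y = np.asarray(y)
    maps = np.asarray(maps)
    masks = _masks_array(pattern)
    c, q, s, ny, nx = y.shape
    if maps.shape[0] != c or maps.shape[2:] != (ny, nx):
        raise EncodingError(f"coil maps shape {maps.shape} inconsistent with k-space {y.shape}")
    if masks.shape != (q, s, ny):
        raise EncodingError(f"mask shape {masks.shape} inconsistent with k-space {y.shape}")
    theta = _caipi_factors(protocol, ny)
    k = y * masks[None, :, :, :, None]
    # broadcast over bands with conjugate CAIPI phase: (c,q,s,z,ny,nx)
    img = ifft2c(k[:, :, :, None] * theta.conj())
    return (maps[:, None, None].conj() * img).sum(axis=0)


def check_unit_modulus(phi: np.ndarray, tol: float = 1e-6) -> None:
    dev = np.max(np.abs(np.abs(phi) - 1.0)) if phi.size else 0.0
    if dev > tol:
        warnings.warn(
            f"shot-phase map deviates from unit modulus by {dev:.2e}; proceeding",
            RuntimeWarning,
            stacklevel=3,
        )


def apply_phase(phi: np.ndarray, x_tilde: np.ndarray) -> np.ndarray:
    """Expand combined DWIs to shot images: ``x[q,s,z] = phi[q,s,z] * x~[q,z]``."""
    phi = np.asarray(phi)
    x_tilde = np.asarray(x_tilde)
    if phi.shape[0] != x_tilde.shape[0] or phi.shape[2:] != x_tilde.shape[1:]:
        raise EncodingError(f"phase shape {phi.shape} inconsistent with DWIs {x_tilde.shape}")
    check_unit_modulus(phi)
    return phi * x_tilde[:, None]


def adjoint_phase(phi: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`apply_phase`: conjugate-phase sum over shots."""
    phi = np.asarray(phi)
    x = np.asarray(x)
    if phi.shape != x.shape:
        raise EncodingError(f"phase shape {phi.shape} != shot images {x.shape}")
    return (phi.conj() * x).sum(axis=1)


def apply_E2(
    x_tilde: np.ndarray,
    phi: np.ndarray,
    maps: np.ndarray,
    pattern: SamplingPattern | np.ndarray,
    protocol: ProtocolSpec,
) -> np.ndarray:
    """Shot-combined forward model ``E2 x~ = E1 (Phi x~)``."""
    return apply_E1(apply_phase(phi, x_tilde), maps, pattern, protocol)


def adjoint_E2(
    y: np.ndarray,
    phi: np.ndarray,
    maps: np.ndarray,
    pattern: SamplingPattern | np.ndarray,
    protocol: ProtocolSpec,
) -> np.ndarray:
    """Exact adjoint of :func:`apply_E2`."""
    return adjoint_phase(phi, adjoint_E1(y, maps, pattern, protocol))
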