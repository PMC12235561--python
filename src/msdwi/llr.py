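"""Overlapping locally-low-rank (LLR) transform and its proximal operator.

The LLR transform ``T`` slides a ``b x b`` patch window over every
diffusion-weighted image and flattens each set of co-located patches into a
2-D spatial-diffusion matrix of shape ``(b*b, Q)``: rows index pixels inside
the patch, columns index diffusion encodings.  Penalizing the nuclear norm of
these matrices exploits the fact that locally, DW images across encodings are
well approximated by a few spatial basis functions.

Overlapping patches (stride < block width) suppress the checkerboard
artifacts of non-overlapping blocks.  The plain adjoint ``T^H`` scatter-adds
overlapping contributions; dividing its output elementwise by the overlap
count map ``T^H(T(1))`` yields a left inverse of ``T`` (exact round-trip
identity), which is the form used inside the reconstruction.

Singular values are normalized by the patch width before soft thresholding
and rescaled after, so a given regularization strength acts comparably across
patch-window choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LLRConfig",
    "patch_anchors",
    "llr_transform",
    "llr_adjoint",
    "overlap_scaling",
    "llr_adjoint_scaled",
    "svt_normalized",
]


@dataclass
class LLRConfig:
    """Joint-reconstruction configuration.

    Defaults follow the values used throughout this package's reference
    protocol study: block width 6, full overlap (stride 1), lam = 0.01,
    rho = 0.05, 15 outer ADMM iterations.
    """

    block_width: int = 6
    stride: int = 1
    lam: float = 0.01
    rho: float = 0.05
    n_admm: int = 15
    n_cg: int = 10
    cg_tol: float = 1e-6
    hanning_k: int = 5
    n_batches: int = 1
    nav_lam: float = 1e-4

    def __post_init__(self):
        if not 1 <= self.stride <= self.block_width:
            raise ValueError("require 1 <= stride <= block_width")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")


def patch_anchors(n: int, block: int, stride: int) -> np.ndarray:
    """Anchor positions along one axis: the stride grid plus, if the last
    stride-grid anchor does not reach the edge, a final edge-flush anchor."""
    if block > n:
        raise ValueError(f"block width {block} exceeds axis length {n}")
    anchors = list(range(0, n - block + 1, stride))
    if anchors[-1] != n - block:
        anchors.append(n - block)
    return np.asarray(anchors)


def llr_transform(x_tilde: np.ndarray, cfg: LLRConfig) -> np.ndarray:
    """Apply ``T``: DWIs (q, z, ny, nx) -> patch stack (z, ay, ax, b*b, q)."""
    x_tilde = np.asarray(x_tilde)
    nq, nz, ny, nx = x_tilde.shape
    b = cfg.block_width
    ay = patch_anchors(ny, b, cfg.stride)
    ax = patch_anchors(nx, b, cfg.stride)
    out = np.empty((nz, len(ay), len(ax), b * b, nq), dtype=x_tilde.dtype)
    for i, iy in enumerate(ay):
        for j, ix in enumerate(ax):
            patch = x_tilde[:, :, iy : iy + b, ix : ix + b].reshape(nq, nz, b * b)
            out[:, i, j] = patch.transpose(1, 2, 0)
    return out


def llr_adjoint(
    patches: np.ndarray, cfg: LLRConfig, image_shape: tuple[int, ...]
) -> np.ndarray:
    """Plain adjoint ``T^H``: scatter-add patch columns back to image space.

    ``image_shape`` is the (q, z, ny, nx) shape of the DWI set.  This is the
    exact adjoint of :func:`llr_transform` in the complex inner product;
    overlapping contributions accumulate.
    """
    patches = np.asarray(patches)
    nq, nz, ny, nx = image_shape
    b = cfg.block_width
    ay = patch_anchors(ny, b, cfg.stride)
    ax = patch_anchors(nx, b, cfg.stride)
    if patches.shape != (nz, len(ay), len(ax), b * b, nq):
        raise ValueError(
            f"patch stack shape {patches.shape} inconsistent with config and "
            f"image shape {image_shape}"
        )
    out = np.zeros(image_shape, dtype=patches.dtype)
    for i, iy in enumerate(ay):
        for j, ix in enumerate(ax):
            blk = patches[:, i, j].transpose(2, 0, 1).reshape(nq, nz, b, b)
            out[:, :, iy : iy + b, ix : ix + b] += blk
    return out


def overlap_scaling(cfg: LLRConfig, image_shape: tuple[int, ...]) -> np.ndarray:
    """Overlap-count map ``T^H(T(1))`` used to normalize the adjoint."""
    ones = np.ones(image_shape)
    scale = llr_adjoint(llr_transform(ones, cfg), cfg, image_shape).real
    if np.any(scale <= 0):
        raise ValueError("patch anchors do not cover every pixel")
    return scale


def llr_adjoint_scaled(
    patches: np.ndarray,
    cfg: LLRConfig,
    image_shape: tuple[int, ...],
    scale: np.ndarray | None = None,
) -> np.ndarray:
    """Overlap-normalized adjoint; exact left inverse of :func:`llr_transform`."""
    if scale is None:
        scale = overlap_scaling(cfg, image_shape)
    return llr_adjoint(patches, cfg, image_shape) / scale


def svt_normalized(M: np.ndarray, tau: float, b: int) -> np.ndarray:
    """Width-normalized singular value thresholding of patch matrices.

    For each matrix in the stack ``M`` (last two axes), computes the SVD
    ``M = U diag(s) V^H`` and returns ``U diag(b * soft(s / b, tau)) V^H``
    with ``soft(s, tau) = max(s - tau, 0)``.  Equivalent to the nuclear-norm
    proximal operator with effective threshold ``tau * b``.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if b < 1:
        raise ValueError("b must be >= 1")
    M = np.asarray(M)
    u, s, vh = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s / b - tau, 0.0) * b
    return (u * s[..., None, :]) @ vh
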