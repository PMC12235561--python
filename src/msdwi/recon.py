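"""Three-step joint k-q-slice reconstruction of multi-shot diffusion EPI.

Step I   reconstructs per-shot navigator images (or self-navigator images
         from the central k-space of each segment) by l2-regularized SENSE,
         solved with conjugate gradients.
Step II  smooths the navigator phases with an adaptive Hanning filter in
         k-space, zero-pads them to the imaging grid and keeps only the
         unit-modulus phase — the shot-to-shot phase maps ``Phi``.
Step III jointly reconstructs the shot-combined DW images of all diffusion
         encodings (and simultaneously excited slices) by ADMM on

             argmin_x~  || y - E2 x~ ||_2^2  +  lam * || T(x~) ||_*

         where ``T`` is the overlapping locally-low-rank transform.  The
         x-update is a CG least-squares solve in which the coupling ``rho``
         acts as a Tikhonov term; the auxiliary update is width-normalized
         singular value thresholding with threshold ``lam / rho``.

The module also exposes the pipeline as a statsmodels-style pair:
:class:`JointReconstruction` (model, built from an :class:`~msdwi.dataset.
Acquisition`) whose :meth:`~JointReconstruction.fit` returns a
:class:`ReconstructionResult` carrying estimates, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataset import Acquisition
from .llr import (
    LLRConfig,
    llr_adjoint_scaled,
    llr_transform,
    overlap_scaling,
    svt_normalized,
)
from .operators import (
    adjoint_E1,
    adjoint_E2,
    apply_E1,
    apply_E2,
    fft2c,
    ifft2c,
)
from .protocol import ProtocolSpec

__all__ = [
    "solve_navigator",
    "extract_self_navigator",
    "hanning_smooth",
    "estimate_shot_phase",
    "admm_solve",
    "joint_reconstruct",
    "JointReconstruction",
    "ReconstructionResult",
]


class ConfigurationError(ValueError):
    pass


def _cg(A, b, x0=None, n_iter=10, tol=1e-6):
    """Conjugate gradients for a Hermitian positive (semi)definite operator.

    Returns (x, converged).  ``A`` is a callable on arrays shaped like ``b``.
    """
    x = np.zeros_like(b) if x0 is None else x0.astype(b.dtype, copy=True)
    r = b - A(x)
    p = r.copy()
    rs = np.vdot(r, r).real
    bnorm = np.sqrt(np.vdot(b, b).real)
    if bnorm == 0:
        return np.zeros_like(b), True
    for _ in range(n_iter):
        if np.sqrt(rs) / bnorm < tol:
            return x, True
        Ap = A(p)
        denom = np.vdot(p, Ap).real
        if denom <= 0:
            warnings.warn("CG stagnated (non-positive curvature)", RuntimeWarning)
            return x, False
        alpha = rs / denom
        x = x + alpha * p
        r = r - alpha * Ap
        rs_new = np.vdot(r, r).real
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x, np.sqrt(rs) / bnorm < tol


# ---------------------------------------------------------------------------
# Step I: navigator reconstruction
# ---------------------------------------------------------------------------

def solve_navigator(
    y_nav: np.ndarray,
    maps: np.ndarray,
    pattern,
    protocol: ProtocolSpec,
    lam_l2: float = 1e-4,
    n_cg: int = 300,
    cg_tol: float = 1e-6,
) -> np.ndarray:
    """l2-regularized SENSE reconstruction of per-shot navigator images.

    Solves ``(E1^H E1 + lam I) x = E1^H y`` by conjugate gradients and
    returns complex shot images of shape (q, s, z, ny_nav, nx_nav).  The
    navigator may live on a smaller grid than the imaging echo; ``maps`` must
    match the navigator grid.
    """
    rhs = adjoint_E1(y_nav, maps, pattern, protocol)

    def A(x):
        return adjoint_E1(apply_E1(x, maps, pattern, protocol), maps, pattern, protocol) + lam_l2 * x

    x, converged = _cg(A, rhs, n_iter=n_cg, tol=cg_tol)
    if not converged:
        warnings.warn("navigator CG did not reach tolerance; returning best iterate", RuntimeWarning)
    return x


def extract_self_navigator(
    y: np.ndarray, pattern, protocol: ProtocolSpec
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Central-k-space self-navigator of each segment.

    Restricts each shot's k-space to the central quarter of the image matrix
    (per axis) and returns ``(y_nav, nav_masks, nav_grid)`` on the reduced
    grid.  Grids not divisible by 4 are rounded down to the nearest even
    region size with a warning.
    """
    masks = pattern.masks if hasattr(pattern, "masks") else np.asarray(pattern)
    c, nq, ns, ny, nx = y.shape

    def _region(n):
        m = n // 4
        if n % 4 != 0 or m % 2 != 0:
            m -= m % 2
            warnings.warn(
                f"axis length {n} not divisible by 4; using central region of {m}",
                RuntimeWarning,
            )
        lo = n // 2 - m // 2
        return lo, lo + m, m

    ylo, yhi, my = _region(ny)
    xlo, xhi, mx = _region(nx)
    y_nav = y[:, :, :, ylo:yhi, xlo:xhi].copy()
    nav_masks = masks[:, :, ylo:yhi].copy()
    return y_nav, nav_masks, (my, mx)


# ---------------------------------------------------------------------------
# Step II: phase smoothing and shot-phase estimation
# ---------------------------------------------------------------------------

def hanning_window_1d(n: int, K: int) -> np.ndarray:
    """Separable axis factor of the adaptive Hanning filter.

    Raised cosine centered on DC (index ``n//2``) with half-width
    ``n / (K + 1)`` grid points; unity at DC, zero beyond the half-width.
    Larger ``K`` narrows the passband (stronger smoothing).
    """
    r = np.abs(np.arange(n) - n // 2)
    half = n / (K + 1)
    w = 0.5 * (1.0 + np.cos(np.pi * np.minimum(r / half, 1.0)))
    return w


def hanning_smooth(img: np.ndarray, K: int) -> np.ndarray:
    """Adaptive Hanning smoothing ``F^-1 H_K F`` of a complex image.

    ``K = 0`` is the identity (the raw input); ``K > 0`` multiplies the
    centered k-space by a separable raised-cosine window with unit DC gain.
    Operates on the last two axes.
    """
    if K < 0:
        raise ValueError("K must be a non-negative integer")
    img = np.asarray(img)
    if K == 0:
        return img.copy()
    ny, nx = img.shape[-2:]
    w = hanning_window_1d(ny, K)[:, None] * hanning_window_1d(nx, K)[None, :]
    return ifft2c(fft2c(img) * w)


def estimate_shot_phase(
    nav_images: np.ndarray, K: int, imaging_grid: tuple[int, int]
) -> np.ndarray:
    """Shot-to-shot phase maps from reconstructed navigator images.

    Smooths each (q, s, z) navigator image with :func:`hanning_smooth`,
    zero-pads its k-space to the imaging grid if smaller, and returns the
    unit-modulus phase ``exp(i * arg)``.  Pixels of exactly zero magnitude
    get phase 0 (``arg 0 := 0``), i.e. map value 1.
    """
    nav_images = np.asarray(nav_images)
    ny, nx = imaging_grid
    my, mx = nav_images.shape[-2:]
    if my > ny or mx > nx:
        raise ValueError("navigator grid exceeds imaging grid")
    k = fft2c(hanning_smooth(nav_images, K))
    if (my, mx) != (ny, nx):
        pad = np.zeros(nav_images.shape[:-2] + (ny, nx), dtype=k.dtype)
        ylo = ny // 2 - my // 2
        xlo = nx // 2 - mx // 2
        pad[..., ylo : ylo + my, xlo : xlo + mx] = k
        k = pad
    smoothed = ifft2c(k)
    return np.exp(1j * np.angle(smoothed))


# ---------------------------------------------------------------------------
# Step III: joint ADMM reconstruction
# ---------------------------------------------------------------------------

def _objective(y, x, phi, maps, pattern, protocol, cfg):
    resid = y - apply_E2(x, phi, maps, pattern, protocol)
    dc = np.vdot(resid, resid).real
    s = np.linalg.svd(llr_transform(x, cfg), compute_uv=False)
    nuc = float(np.sum(s))
    return dc, nuc, dc + cfg.lam * nuc


def admm_solve(
    y: np.ndarray,
    phi: np.ndarray,
    maps: np.ndarray,
    pattern,
    protocol: ProtocolSpec,
    cfg: LLRConfig,
    track_objective: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """ADMM for the LLR-regularized shot-combined reconstruction.

    Alternates (i) a CG least-squares x-update of the data term with the
    coupling ``rho`` acting as Tikhonov regularization, (ii) width-normalized
    singular value thresholding of ``T(x) + u`` at threshold ``lam / rho``,
    and (iii) the dual ascent ``u <- u + T(x) - v``.  The x-update is
    warm-started across iterations.

    Data are scaled internally by the peak magnitude of the zero-filled
    adjoint image so the default ``lam``/``rho`` act on an O(1) image scale;
    the output is scaled back.  Returns ``(x_tilde, history)`` with one
    history row per ADMM iteration.
    """
    y = np.asarray(y)
    phi = np.asarray(phi)
    nq = y.shape[1]
    nz, ny, nx = maps.shape[1:]
    shape = (nq, nz, ny, nx)

    x_zf = adjoint_E2(y, phi, maps, pattern, protocol)
    scale = float(np.max(np.abs(x_zf)))
    if scale == 0:
        return np.zeros(shape, dtype=y.dtype), pd.DataFrame()
    yn = y / scale

    T = lambda x: llr_transform(x, cfg)
    ov = overlap_scaling(cfg, shape)
    Tinv = lambda p: llr_adjoint_scaled(p, cfg, shape, scale=ov)

    rhs_data = adjoint_E2(yn, phi, maps, pattern, protocol)

    def A(x):
        return (
            adjoint_E2(apply_E2(x, phi, maps, pattern, protocol), phi, maps, pattern, protocol)
            + 0.5 * cfg.rho * x
        )

    x = x_zf / scale
    v = T(x)
    u = np.zeros_like(v)
    rows = []
    for k in range(cfg.n_admm):
        rhs = rhs_data + 0.5 * cfg.rho * Tinv(v - u)
        x, _ = _cg(A, rhs, x0=x, n_iter=cfg.n_cg, tol=cfg.cg_tol)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite iterate at ADMM iteration {k + 1}")
        Tx = T(x)
        v = svt_normalized(Tx + u, cfg.lam / cfg.rho, cfg.block_width)
        u = u + Tx - v
        if track_objective:
            dc, nuc, obj = _objective(yn, x, phi, maps, pattern, protocol, cfg)
            rows.append(
                {"iteration": k + 1, "data_consistency": dc, "nuclear_norm": nuc, "objective": obj}
            )
    return x * scale, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def _solve_navigator_llr(y_nav, nav_masks, nav_maps, protocol, cfg: LLRConfig):
    """LLR-regularized Step I for heavily undersampled self-navigators.

    All (encoding, shot) navigator images are reconstructed jointly: the shot
    axis is folded into the diffusion axis and the same LLR-ADMM solve used
    in Step III is applied on the navigator grid with unit shot phases.
    """
    nc, nq, ns, my, mx = y_nav.shape
    yf = y_nav.reshape(nc, nq * ns, 1, my, mx)
    mf = np.asarray(nav_masks).reshape(nq * ns, 1, my)
    phif = np.ones((nq * ns, 1, protocol.mb_factor, my, mx), dtype=complex)
    nav_cfg = replace(cfg, n_batches=1, block_width=min(cfg.block_width, my, mx))
    x, _ = admm_solve(yf, phif, nav_maps, mf, protocol, nav_cfg, track_objective=False)
    return x.reshape(nq, ns, protocol.mb_factor, my, mx)


def _estimate_phases(data: Acquisition, cfg: LLRConfig) -> np.ndarray:
    protocol = data.protocol
    grid = (protocol.ny, protocol.nx)
    if data.y_nav is not None:
        nav_grid = data.y_nav.shape[-2:]
        nav_maps = _resample_maps(data.maps, nav_grid)
        nav_imgs = solve_navigator(
            data.y_nav, nav_maps, data.nav_masks, protocol, lam_l2=cfg.nav_lam
        )
    elif protocol.self_navigated:
        # self-navigators carry the full segment undersampling; the plain l2
        # solve degrades there, so Step I reuses the joint LLR regularization
        y_nav, nav_masks, nav_grid = extract_self_navigator(data.y, data.pattern, protocol)
        nav_maps = _resample_maps(data.maps, nav_grid)
        nav_imgs = _solve_navigator_llr(y_nav, nav_masks, nav_maps, protocol, cfg)
    elif protocol.n_shots == 1:
        nq = data.y.shape[1]
        return np.ones((nq, 1, protocol.mb_factor) + grid, dtype=data.y.dtype)
    else:
        raise ConfigurationError(
            "multi-shot dataset has no navigator echoes and is not self-navigating"
        )
    phi = estimate_shot_phase(nav_imgs, cfg.hanning_k, grid)
    # pin the first shot of each encoding as the phase reference
    phi = phi * np.exp(-1j * np.angle(phi[:, :1]))
    return phi


def _resample_maps(maps: np.ndarray, grid: tuple[int, int]) -> np.ndarray:
    """Coil maps on a reduced (navigator) grid via central k-space cropping."""
    ny, nx = maps.shape[-2:]
    my, mx = grid
    if (my, mx) == (ny, nx):
        return maps
    k = fft2c(maps)
    ylo = ny // 2 - my // 2
    xlo = nx // 2 - mx // 2
    small = ifft2c(k[..., ylo : ylo + my, xlo : xlo + mx])
    rss = np.sqrt(np.sum(np.abs(small) ** 2, axis=0, keepdims=True))
    return small / np.maximum(rss, 1e-12 * np.max(rss) if np.max(rss) > 0 else 1.0)


def _batch_slices(nq: int, n_batches: int):
    n_batches = max(1, min(n_batches, nq))
    size = nq // n_batches
    edges = [i * size for i in range(n_batches)] + [nq]  # remainder -> last batch
    return [slice(edges[i], edges[i + 1]) for i in range(n_batches)]


def joint_reconstruct(
    data: Acquisition,
    cfg: LLRConfig | None = None,
    phases: np.ndarray | None = None,
) -> "ReconstructionResult":
    """Run the full three-step joint reconstruction on an acquisition.

    ``phases`` overrides Step I/II with known shot-phase maps (used for
    single-shot data or simulation ground truth).  The diffusion dimension is
    split into ``cfg.n_batches`` contiguous batches reconstructed
    independently and concatenated.
    """
    cfg = cfg or LLRConfig()
    phi = np.asarray(phases) if phases is not None else _estimate_phases(data, cfg)
    masks = data.pattern.masks if hasattr(data.pattern, "masks") else np.asarray(data.pattern)
    nq = data.y.shape[1]
    parts, hists = [], []
    for i, sl in enumerate(_batch_slices(nq, cfg.n_batches)):
        x, hist = admm_solve(
            data.y[:, sl], phi[sl], data.maps, masks[sl], data.protocol, cfg
        )
        parts.append(x)
        if not hist.empty:
            hist.insert(0, "batch", i)
        hists.append(hist)
    x_tilde = np.concatenate(parts, axis=0)
    history = pd.concat(hists, ignore_index=True) if hists else pd.DataFrame()
    return ReconstructionResult(x_tilde=x_tilde, phases=phi, history=history, config=cfg, data=data)


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class JointReconstruction:
    """Joint k-q-slice reconstruction model for a multi-shot DWI acquisition.

    Parameters
    ----------
    data : Acquisition
        Multi-coil k-space, coil maps, sampling masks and protocol (plus
        optional navigator echoes), e.g. from the bundled simulator or an
        HDF5 container.
    config : LLRConfig, optional
        Regularization and solver settings.
    phases : ndarray, optional
        Known shot-phase maps; skips navigator estimation when given.

    Examples
    --------
    >>> model = JointReconstruction(acq, LLRConfig(lam=0.01, rho=0.05))
    >>> res = model.fit()
    >>> res.summary()          # doctest: +SKIP
    """

    def __init__(
        self,
        data: Acquisition,
        config: LLRConfig | None = None,
        phases: np.ndarray | None = None,
    ):
        self.data = data
        self.config = config or LLRConfig()
        self.phases = phases

    @classmethod
    def from_hdf5(cls, path, config: LLRConfig | None = None) -> "JointReconstruction":
        return cls(Acquisition.load(path), config=config)

    def fit(self) -> "ReconstructionResult":
        """Estimate shot phases (unless given) and run the ADMM solve."""
        return joint_reconstruct(self.data, self.config, phases=self.phases)


@dataclass
class ReconstructionResult:
    """Reconstructed shot-combined DW images with diagnostics.

    Attributes
    ----------
    x_tilde : complex ndarray (q, z, ny, nx)
        Shot-combined diffusion-weighted images.
    phases : complex ndarray (q, s, z, ny, nx)
        Shot-phase maps used in the forward model.
    history : pandas.DataFrame
        Per-ADMM-iteration data consistency, nuclear norm and objective.
    """

    x_tilde: np.ndarray
    phases: np.ndarray
    history: pd.DataFrame
    config: LLRConfig
    data: Acquisition | None = None

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.x_tilde)

    def nrmse(self, reference: np.ndarray) -> float:
        from .metrics import nrmse

        return nrmse(self.x_tilde, reference)

    def summary(self) -> str:
        nq, nz, ny, nx = self.x_tilde.shape
        cfg = self.config
        lines = [
            "Joint k-q-slice reconstruction results",
            "=" * 46,
            f"{'diffusion encodings (q)':<32}{nq:>12}",
            f"{'bands (z)':<32}{nz:>12}",
            f"{'matrix':<32}{f'{ny} x {nx}':>12}",
            f"{'shots':<32}{self.phases.shape[1]:>12}",
            f"{'lambda':<32}{cfg.lam:>12g}",
            f"{'rho':<32}{cfg.rho:>12g}",
            f"{'block width / stride':<32}{f'{cfg.block_width} / {cfg.stride}':>12}",
            f"{'ADMM iterations':<32}{cfg.n_admm:>12}",
        ]
        if not self.history.empty:
            last = self.history.iloc[-1]
            lines += [
                f"{'final data consistency':<32}{last['data_consistency']:>12.4e}",
                f"{'final objective':<32}{last['objective']:>12.4e}",
            ]
        return "\n".join(lines)

    def to_nifti(self, path, voxel_size=(1.0, 1.0, 1.0), what: str = "magnitude"):
        from .io import export_nifti

        return export_nifti(self, path, voxel_size=voxel_size, what=what)
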