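"""Synthetic multi-coil, multi-shot, multi-band diffusion acquisitions.

The simulator produces fully specified acquisitions with known ground truth:
an ellipse-based diffusion phantom (per-voxel tensors with distinct isotropic
and anisotropic compartments), a monoexponential tensor signal model, smooth
complex coil sensitivities, smooth random polynomial shot-to-shot phases, and
k-space synthesized through the same per-shot forward model the
reconstruction inverts, with optional i.i.d. circular complex Gaussian noise
on the sampled entries.

Desk-scale analogs of three acquisition styles are provided as protocol
presets: a four-shot fully sampled single-shell acquisition (the
retrospective-undersampling study runs on it), a two-shot accelerated
multi-band three-shell self-navigated acquisition, and a five-shot
navigator-based trace acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataset import Acquisition
from .operators import apply_E1, fft2c, ifft2c
from .protocol import (
    DiffusionScheme,
    ProtocolSpec,
    SamplingPattern,
    make_acquisition_schedule,
    make_diffusion_scheme,
)

__all__ = [
    "PhantomTruth",
    "SimulationConfig",
    "make_phantom",
    "dwi_signal",
    "make_coil_maps",
    "make_shot_phases",
    "simulate_acquisition",
    "retrospective_undersample",
    "tensor_fit",
    "fa_from_tensors",
    "sigma_for_snr",
    "protocol1_analog",
    "protocol2_analog",
    "protocol3_analog",
]


# ---------------------------------------------------------------------------
# Phantom and signal model
# ---------------------------------------------------------------------------

@dataclass
class PhantomTruth:
    """Ground-truth object: proton density, diffusion tensors, support.

    ``s0``: (z, ny, nx) non-negative; ``tensors``: (z, ny, nx, 3, 3)
    symmetric PSD in mm^2/s; ``support``: binary; ``labels``: integer
    compartment map (0 = outside).
    """

    s0: np.ndarray
    tensors: np.ndarray
    support: np.ndarray
    labels: np.ndarray


def _tensor_from_axis(evals, theta):
    """Symmetric 3x3 tensor with in-plane principal axis at angle theta."""
    v1 = np.array([np.cos(theta), np.sin(theta), 0.0])
    v2 = np.array([-np.sin(theta), np.cos(theta), 0.0])
    v3 = np.array([0.0, 0.0, 1.0])
    return (
        evals[0] * np.outer(v1, v1)
        + evals[1] * np.outer(v2, v2)
        + evals[2] * np.outer(v3, v3)
    )


def make_phantom(shape: tuple[int, int, int], seed: int = 0) -> PhantomTruth:
    """Piecewise-smooth ellipse phantom with labelled tensor compartments.

    ``shape`` is (n_bands, ny, nx) with ny, nx >= 16.  Compartment 1 is
    strongly anisotropic (FA ~ 0.85), compartment 2 isotropic (FA = 0),
    compartment 3 moderately anisotropic; the remaining support is isotropic
    background.  Bands differ by a rigid flip of the compartment layout and a
    seed-dependent rotation of the principal axes.
    """
    nz, ny, nx = shape
    if ny < 16 or nx < 16 or nz < 1:
        raise ValueError("phantom requires at least 16 pixels per axis and 1 band")
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(
        np.linspace(-1, 1, ny), np.linspace(-1, 1, nx), indexing="ij"
    )

    def ellipse(cy, cx, ry, rx):
        return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    base_theta = rng.uniform(0, np.pi)
    s0 = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int8)
    tensors = np.zeros(shape + (3, 3))
    comp_tensors = {
        1: (np.array([1.7e-3, 0.2e-3, 0.2e-3]), base_theta),          # FA ~ 0.86
        2: (np.array([0.8e-3, 0.8e-3, 0.8e-3]), 0.0),                 # FA = 0
        3: (np.array([1.2e-3, 0.4e-3, 0.3e-3]), base_theta + np.pi / 3),
        4: (np.array([1.0e-3, 1.0e-3, 1.0e-3]), 0.0),                 # background
    }
    comp_s0 = {1: 1.2, 2: 0.9, 3: 1.1, 4: 1.0}
    for z in range(nz):
        flip = -1.0 if z % 2 else 1.0
        support = ellipse(0.0, 0.0, 0.88, 0.78)
        lab = np.where(support, 4, 0).astype(np.int8)
        lab[ellipse(-0.30 * flip, -0.25, 0.30, 0.20)] = 1
        lab[ellipse(0.30 * flip, -0.20, 0.24, 0.24)] = 2
        lab[ellipse(0.05, 0.38, 0.38, 0.18)] = 3
        lab[~support] = 0
        labels[z] = lab
        # gentle smooth shading keeps the phantom piecewise smooth, not flat
        shade = 1.0 + 0.08 * xx + 0.05 * yy
        for c, val in comp_s0.items():
            s0[z][lab == c] = val
        s0[z] *= shade
        s0[z][lab == 0] = 0.0
        for c, (evals, theta) in comp_tensors.items():
            tensors[z][lab == c] = _tensor_from_axis(evals, theta + 0.1 * z)
    return PhantomTruth(s0=s0, tensors=tensors, support=labels > 0, labels=labels)


def dwi_signal(truth: PhantomTruth, b: float, g) -> np.ndarray:
    """Monoexponential tensor signal ``S = s0 * exp(-b g^T D g)``.

    ``b`` in s/mm^2; ``g`` a unit 3-vector (ignored for b = 0).  Returns a
    complex image per band.
    """
    if b < 0:
        raise ValueError("b-value must be non-negative")
    if b == 0:
        return truth.s0.astype(np.complex128)
    g = np.asarray(g, dtype=float)
    if abs(np.linalg.norm(g) - 1.0) > 1e-8:
        raise ValueError("diffusion direction must be unit norm for b > 0")
    adc = np.einsum("i,zyxij,j->zyx", g, truth.tensors, g)
    return (truth.s0 * np.exp(-b * adc)).astype(np.complex128)


# ---------------------------------------------------------------------------
# Coil maps and shot phases
# ---------------------------------------------------------------------------

def make_coil_maps(n_coils: int, shape: tuple[int, int, int], seed: int = 0) -> np.ndarray:
    """Smooth complex coil sensitivities, (c, z, ny, nx), unit RSS.

    Gaussian magnitude lobes placed around the field of view with low-order
    polynomial phase; a single coil degenerates to the constant unit map.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    nz, ny, nx = shape
    if n_coils == 1:
        return np.ones((1, nz, ny, nx), dtype=np.complex128)
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(np.linspace(-1, 1, ny), np.linspace(-1, 1, nx), indexing="ij")
    maps = np.empty((n_coils, nz, ny, nx), dtype=np.complex128)
    for c in range(n_coils):
        for z in range(nz):
            # each excited slice sees the coil from a different geometry:
            # the lobe center rotates and its width varies with the band
            ang = 2 * np.pi * c / n_coils + 0.7 * z + rng.uniform(-0.1, 0.1)
            radius = 1.15 + 0.1 * np.cos(1.3 * z + c)
            cy, cx = radius * np.sin(ang), radius * np.cos(ang)
            width = 0.75 + 0.15 * ((c + z) % 3) / 2.0
            mag = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * width**2))
            a1, a2, a3 = rng.uniform(-1.0, 1.0, 3)
            phase = a1 * yy + a2 * xx + 0.5 * a3 * yy * xx
            maps[c, z] = mag * np.exp(1j * phase)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0, keepdims=True))
    return maps / rss


@dataclass
class SimulationConfig:
    """Study conditions of one synthetic acquisition.

    ``noise_sigma`` is the standard deviation of the circular complex noise
    added per sampled k-space entry (orthonormal FFT scaling, so it equals
    the image-domain noise level for unit-RSS coils).  ``phase_amplitude``
    (radians) scales smooth random polynomial shot phases of order
    ``phase_order``; shot 0 of each encoding is the zero-phase reference.
    """

    protocol: ProtocolSpec
    n_coils: int = 8
    noise_sigma: float = 0.0
    phase_order: int = 2
    phase_amplitude: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.phase_order < 1:
            raise ValueError("phase_order must be >= 1")


def sigma_for_snr(snr: float, signal_scale: float = 1.0) -> float:
    """k-space noise sigma yielding roughly the requested image-domain SNR."""
    return signal_scale / snr


def make_shot_phases(
    config: SimulationConfig, n_encodings: int | None = None
) -> np.ndarray:
    """Unit-modulus shot-phase maps exp(i * smooth random polynomial).

    Shape (q, s, z, ny, nx).  Per (q, s, z) the phase is a random 2-D
    polynomial of total order ``phase_order`` in normalized coordinates,
    scaled so its coefficient vector has RMS ``phase_amplitude``; shot 0 of
    every encoding carries exactly zero phase (the reference shot).
    """
    p = config.protocol
    if n_encodings is None:
        n_encodings = len(_schedule(p, config.seed))
    nq = n_encodings
    rng = np.random.default_rng(config.seed + 104729)
    ny, nx = p.matrix
    nz, ns = p.mb_factor, p.n_shots
    yy, xx = np.meshgrid(np.linspace(-1, 1, ny), np.linspace(-1, 1, nx), indexing="ij")
    terms = [
        yy**i * xx**j
        for i in range(config.phase_order + 1)
        for j in range(config.phase_order + 1 - i)
    ]
    basis = np.stack(terms)  # (n_terms, ny, nx)
    nt = basis.shape[0]
    phase = np.zeros((nq, ns, nz, ny, nx))
    coeffs = rng.standard_normal((nq, ns, nz, nt))
    coeffs *= config.phase_amplitude / np.sqrt(nt)
    coeffs[:, 0] = 0.0
    phase = np.einsum("qszt,tyx->qszyx", coeffs, basis)
    return np.exp(1j * phase)


# ---------------------------------------------------------------------------
# Acquisition synthesis
# ---------------------------------------------------------------------------

def _schedule(protocol: ProtocolSpec, seed: int) -> DiffusionScheme:
    scheme = make_diffusion_scheme(protocol.shells, seed=seed)
    return make_acquisition_schedule(scheme, protocol.b0_interval)


def _shift_indices(schedule: DiffusionScheme) -> np.ndarray:
    """ky-shift counter per volume: number of preceding DW volumes.

    b0 volumes do not advance the shift; the volume itself reuses the
    current counter value.
    """
    dw = (schedule.bvals > 0).astype(int)
    return np.concatenate([[0], np.cumsum(dw)[:-1]])


def _nav_pattern(protocol: ProtocolSpec, nq: int, my: int) -> np.ndarray:
    """Navigator ky masks (q, s, my): per-shot factor r_inplane, offset s mod R."""
    r = protocol.r_inplane
    masks = np.zeros((nq, protocol.n_shots, my), dtype=np.uint8)
    for s in range(protocol.n_shots):
        masks[:, s, s % r :: r] = 1
    return masks


def simulate_acquisition(config: SimulationConfig) -> Acquisition:
    """Synthesize one multi-band slice group's worth of k-space data.

    Builds the scheduled DW image series from the tensor phantom, applies the
    simulated shot phases, pushes each shot through the per-shot forward
    model with ky-shift-aware masks, and adds complex Gaussian noise to the
    sampled entries.  Navigator echoes (when the protocol is not
    self-navigated) are simulated by central k-space truncation of the same
    phased shot images to the navigator grid, with the navigator's own
    in-plane undersampling.  The returned :class:`Acquisition` carries the
    full ground-truth bundle.
    """
    p = config.protocol
    rng = np.random.default_rng(config.seed)
    schedule = _schedule(p, config.seed)
    nq = len(schedule)
    if nq == 0:
        raise ValueError("protocol schedules zero volumes; specify shells")

    truth = make_phantom((p.mb_factor, p.ny, p.nx), seed=config.seed)
    x_tilde = np.stack(
        [dwi_signal(truth, b, g) for b, g in zip(schedule.bvals, schedule.bvecs)]
    )  # (q, z, ny, nx)
    phi = make_shot_phases(config, n_encodings=nq)
    x = phi * x_tilde[:, None]  # (q, s, z, ny, nx)

    maps = make_coil_maps(config.n_coils, (p.mb_factor, p.ny, p.nx), seed=config.seed)
    pattern = SamplingPattern.from_protocol(p, nq, shift_indices=_shift_indices(schedule))
    y = apply_E1(x, maps, pattern, p)
    if config.noise_sigma > 0:
        noise = (
            rng.standard_normal(y.shape) + 1j * rng.standard_normal(y.shape)
        ) * (config.noise_sigma / np.sqrt(2))
        y = y + noise * pattern.masks[None, :, :, :, None]

    y_nav = nav_masks = None
    if not p.self_navigated:
        my, mx = p.nav_matrix
        ylo, xlo = p.ny // 2 - my // 2, p.nx // 2 - mx // 2
        k = fft2c(x)[..., ylo : ylo + my, xlo : xlo + mx]
        nav_img = ifft2c(k)
        k_maps = fft2c(maps)[..., ylo : ylo + my, xlo : xlo + mx]
        nav_maps = ifft2c(k_maps)
        rss = np.sqrt(np.sum(np.abs(nav_maps) ** 2, axis=0, keepdims=True))
        nav_maps = nav_maps / np.maximum(rss, 1e-12)
        nav_masks = _nav_pattern(p, nq, my)
        y_nav = apply_E1(nav_img, nav_maps, nav_masks, p)
        if config.noise_sigma > 0:
            noise = (
                rng.standard_normal(y_nav.shape) + 1j * rng.standard_normal(y_nav.shape)
            ) * (config.noise_sigma / np.sqrt(2))
            y_nav = y_nav + noise * nav_masks[None, :, :, :, None]

    return Acquisition(
        y=y,
        maps=maps,
        pattern=pattern,
        protocol=p,
        scheme=schedule,
        y_nav=y_nav,
        nav_masks=nav_masks,
        truth={
            "s0": truth.s0,
            "tensors": truth.tensors,
            "support": truth.support.astype(np.uint8),
            "labels": truth.labels,
            "phases": phi,
            "dwis": x_tilde,
        },
    )


def retrospective_undersample(
    data: Acquisition, shots_kept_per_q: int = 1, ky_shift: bool = True
) -> Acquisition:
    """Retrospectively keep a subset of shots per diffusion encoding.

    With ``ky_shift`` enabled the kept shot index cycles with the encoding's
    DW counter, so the retained ky lines realize the shifted complementary
    pattern; without it every encoding retains the same lines.
    """
    ns = data.y.shape[2]
    keep = shots_kept_per_q
    if keep > ns:
        raise ValueError(f"cannot keep {keep} shots from {ns}-shot data")
    if keep == ns:
        return data
    nq = data.n_encodings
    shift = (
        _shift_indices(data.scheme) if data.scheme is not None else np.arange(nq)
    )
    kept = np.array(
        [
            [((shift[q] if ky_shift else 0) + j) % ns for j in range(keep)]
            for q in range(nq)
        ]
    )  # (q, keep)
    qi = np.arange(nq)[:, None]
    y = data.y[:, qi, kept]  # adjacent advanced indices keep (q, keep) in place
    masks = data.pattern.masks[qi, kept]
    truth = dict(data.truth)
    if "phases" in truth:
        truth["phases"] = truth["phases"][qi, kept]
    y_nav = data.y_nav
    nav_masks = data.nav_masks
    if y_nav is not None:
        y_nav = y_nav[:, qi, kept]
        nav_masks = nav_masks[qi, kept]
    protocol = replace(data.protocol, n_shots=keep)
    return Acquisition(
        y=y,
        maps=data.maps,
        pattern=SamplingPattern(masks),
        protocol=protocol,
        scheme=data.scheme,
        y_nav=y_nav,
        nav_masks=nav_masks,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Tensor fitting (log-linear least squares) for recovery checks
# ---------------------------------------------------------------------------

def _design_matrix(scheme: DiffusionScheme) -> np.ndarray:
    g = scheme.bvecs
    b = scheme.bvals
    cols = np.stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ],
        axis=1,
    )
    return np.column_stack([np.ones(len(scheme)), -b[:, None] * cols])


def tensor_fit(
    dwis: np.ndarray, scheme: DiffusionScheme, support: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary log-linear least-squares diffusion tensor fit.

    ``dwis``: magnitude images (q, z, ny, nx); requires at least six distinct
    directions and one b0 volume.  Voxels outside ``support`` or with
    non-positive signal in any volume are skipped (tensor and FA set to 0).
    Returns ``(tensors, fa)`` with shapes (z, ny, nx, 3, 3) and (z, ny, nx).
    """
    dwis = np.asarray(dwis, dtype=float)
    if scheme.n_dwi < 6 or not np.any(scheme.is_b0):
        raise ValueError("tensor fit needs >= 6 diffusion directions and >= 1 b0")
    nq, nz, ny, nx = dwis.shape
    A = _design_matrix(scheme)
    flat = dwis.reshape(nq, -1)
    valid = np.all(flat > 0, axis=0)
    if support is not None:
        valid &= np.asarray(support, dtype=bool).reshape(-1)
    coeffs = np.zeros((7, flat.shape[1]))
    if np.any(valid):
        logs = np.log(flat[:, valid])
        coeffs[:, valid] = np.linalg.lstsq(A, logs, rcond=None)[0]
    d = coeffs[1:]
    tensors = np.zeros((flat.shape[1], 3, 3))
    idx = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
    for k, (i, j) in enumerate(idx):
        tensors[:, i, j] = d[k]
        tensors[:, j, i] = d[k]
    tensors[~valid] = 0.0
    tensors = tensors.reshape(nz, ny, nx, 3, 3)
    fa = fa_from_tensors(tensors)
    return tensors, fa


def fa_from_tensors(tensors: np.ndarray) -> np.ndarray:
    """Fractional anisotropy of a tensor field (..., 3, 3)."""
    evals = np.linalg.eigvalsh(np.asarray(tensors))
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.sum((evals - mean) ** 2, axis=-1)
    den = np.sum(evals**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.nan_to_num(fa)


# ---------------------------------------------------------------------------
# Desk-scale protocol presets
# ---------------------------------------------------------------------------

def protocol1_analog(matrix: tuple[int, int] = (48, 48)) -> ProtocolSpec:
    """Four-shot, fully sampled (union) single-shell navigator-based acquisition."""
    return ProtocolSpec(
        matrix=matrix,
        n_shots=4,
        r_inplane=1,
        mb_factor=1,
        esp_ms=1.0,
        shells=((1000.0, 20),),
        b0_interval=10,
        nav_matrix=(matrix[0] // 3, matrix[1] // 3),
        ky_shift=True,
    )


def protocol2_analog(matrix: tuple[int, int] = (48, 48)) -> ProtocolSpec:
    """Two-shot, R=2, MB=2 three-shell self-navigated acquisition."""
    return ProtocolSpec(
        matrix=matrix,
        n_shots=2,
        r_inplane=2,
        mb_factor=2,
        esp_ms=1.0,
        shells=((1000.0, 6), (2000.0, 6), (3000.0, 8)),
        b0_interval=10,
        nav_matrix="self",
        ky_shift=True,
    )


def protocol3_analog(matrix: tuple[int, int] = (40, 40)) -> ProtocolSpec:
    """Five-shot, R=2 navigator-based trace acquisition."""
    return ProtocolSpec(
        matrix=matrix,
        n_shots=5,
        r_inplane=2,
        mb_factor=1,
        esp_ms=1.0,
        shells=((1000.0, 3),),
        b0_interval=10,
        nav_matrix=(matrix[0] // 2, matrix[1] // 2),
        ky_shift=True,
    )
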