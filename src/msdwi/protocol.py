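"""Acquisition design for ky-shift-encoded interleaved multi-shot EPI.

An interleaved EPI (iEPI) acquisition splits the phase-encode (ky) coverage of
one diffusion-weighted image across ``n_shots`` excitations.  Each shot
("segment") acquires every ``r_inplane * n_shots``-th ky line, so the
undersampling factor of a single segment is ``r_inplane * n_shots`` while the
union of shots realizes the nominal in-plane acceleration ``r_inplane``.

The ky-shift encoding scheme additionally cycles the ky offset of the whole
interleave pattern by one line per diffusion encoding, with cycling period
``r_inplane``.  Neighbouring diffusion encodings then sample complementary ky
lines, which is what makes a joint reconstruction across the diffusion (q)
dimension effective under heavy per-volume undersampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ProtocolSpec",
    "SamplingPattern",
    "DiffusionScheme",
    "build_shot_mask",
    "segment_undersampling_factor",
    "effective_esp",
    "make_diffusion_scheme",
    "make_acquisition_schedule",
    "caipi_slice_phase",
]


class ProtocolError(ValueError):
    """Raised when an acquisition protocol is internally inconsistent."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Geometry and acceleration parameters of one acquisition protocol.

    Parameters
    ----------
    matrix : (ny, nx)
        Image matrix size.
    n_shots : int
        Number of iEPI shots (segments) per diffusion encoding.
    r_inplane : int
        Nominal in-plane (ky) acceleration of the combined shots.
    mb_factor : int
        Number of simultaneously excited slices (multi-band factor).
    esp_ms : float
        Echo spacing of the EPI readout in milliseconds.
    shells : sequence of (b_value, n_directions)
        Diffusion shells; b in s/mm^2.
    b0_interval : int
        One non-diffusion-weighted (b0) volume is interspersed at the start
        of every block of this many diffusion-weighted volumes.
    nav_matrix : (ny_nav, nx_nav) or "self"
        Navigator-echo grid, or ``"self"`` for self-navigation from the
        central k-space of the imaging echo.
    ky_shift : bool
        Enable ky-shift encoding across diffusion encodings.
    """

    matrix: tuple[int, int]
    n_shots: int = 1
    r_inplane: int = 1
    mb_factor: int = 1
    esp_ms: float = 1.0
    shells: tuple[tuple[float, int], ...] = ()
    b0_interval: int = 10
    nav_matrix: tuple[int, int] | str = "self"
    ky_shift: bool = True

    def __post_init__(self):
        object.__setattr__(self, "matrix", tuple(int(v) for v in self.matrix))
        object.__setattr__(
            self, "shells", tuple((float(b), int(n)) for b, n in self.shells)
        )
        if isinstance(self.nav_matrix, str):
            if self.nav_matrix != "self":
                raise ProtocolError(f"nav_matrix must be a grid or 'self', got {self.nav_matrix!r}")
        else:
            object.__setattr__(
                self, "nav_matrix", tuple(int(v) for v in self.nav_matrix)
            )
        self.validate()

    # -- derived geometry ---------------------------------------------------
    @property
    def ny(self) -> int:
        return self.matrix[0]

    @property
    def nx(self) -> int:
        return self.matrix[1]

    @property
    def self_navigated(self) -> bool:
        return self.nav_matrix == "self"

    def validate(self) -> None:
        ny, nx = self.matrix
        if ny <= 0 or nx <= 0:
            raise ProtocolError("matrix dimensions must be positive")
        for name in ("n_shots", "r_inplane", "mb_factor", "b0_interval"):
            if getattr(self, name) < 1:
                raise ProtocolError(f"{name} must be >= 1")
        if self.esp_ms <= 0:
            raise ProtocolError("esp_ms must be positive")
        if ny % (self.r_inplane * self.n_shots) != 0:
            raise ProtocolError(
                f"ny={ny} not divisible by r_inplane*n_shots="
                f"{self.r_inplane * self.n_shots}"
            )
        for b, n in self.shells:
            if b < 0 or n < 0:
                raise ProtocolError("shell b-values and counts must be non-negative")
        if not self.self_navigated:
            if self.nav_matrix[0] > ny or self.nav_matrix[1] > nx:
                raise ProtocolError("navigator grid must not exceed the imaging grid")


def segment_undersampling_factor(protocol: ProtocolSpec) -> int:
    """In-plane undersampling factor of a single shot (segment).

    Equals ``r_inplane * n_shots``; multi-band acceleration is excluded.
    """
    return protocol.r_inplane * protocol.n_shots


def effective_esp(protocol: ProtocolSpec) -> float:
    """Effective echo spacing (ms) of one segment.

    The k-space line advance per unit time of an undersampled segment is
    ``r_inplane * n_shots`` times faster than the nominal echo spacing, so
    geometric distortion scales with ``esp_ms / (r_inplane * n_shots)``.
    """
    if protocol.esp_ms <= 0:
        raise ProtocolError("esp_ms must be positive")
    return protocol.esp_ms / (protocol.r_inplane * protocol.n_shots)


def build_shot_mask(protocol: ProtocolSpec, q: int, s: int) -> np.ndarray:
    """Binary ky sampling vector of shot ``s`` at diffusion encoding ``q``.

    Sampled lines are ``ky = delta(q) + s*r_inplane + j*(r_inplane*n_shots)``
    where ``delta(q) = q mod r_inplane`` under ky-shift encoding and 0
    otherwise.  ``q`` counts diffusion-weighted encodings only; interspersed
    b0 volumes do not advance the shift.
    """
    if q < 0:
        raise IndexError(f"encoding index q={q} out of range")
    if not 0 <= s < protocol.n_shots:
        raise IndexError(f"shot index s={s} out of range for n_shots={protocol.n_shots}")
    ny = protocol.ny
    step = segment_undersampling_factor(protocol)
    delta = q % protocol.r_inplane if protocol.ky_shift else 0
    mask = np.zeros(ny, dtype=np.uint8)
    mask[(delta + s * protocol.r_inplane) % step :: step] = 1
    return mask


@dataclass
class SamplingPattern:
    """Per-(encoding, shot) binary ky masks.

    ``masks`` has shape (q, s, ny); entry 1 marks an acquired ky line.
    """

    masks: np.ndarray

    def __post_init__(self):
        self.masks = np.asarray(self.masks, dtype=np.uint8)
        if self.masks.ndim != 3:
            raise ProtocolError("masks must have shape (q, s, ky)")

    @property
    def n_encodings(self) -> int:
        return self.masks.shape[0]

    @property
    def n_shots(self) -> int:
        return self.masks.shape[1]

    @classmethod
    def from_protocol(
        cls,
        protocol: ProtocolSpec,
        n_encodings: int,
        shift_indices: Sequence[int] | None = None,
    ) -> "SamplingPattern":
        """Build the interleave pattern for ``n_encodings`` volumes.

        ``shift_indices`` gives, per volume, the number of diffusion-weighted
        volumes preceding it (the ky-shift counter); defaults to
        ``0..n_encodings-1``, i.e. an all-DWI train.
        """
        if shift_indices is None:
            shift_indices = range(n_encodings)
        masks = np.stack(
            [
                np.stack(
                    [build_shot_mask(protocol, qi, s) for s in range(protocol.n_shots)]
                )
                for qi in shift_indices
            ]
        )
        return cls(masks)


@dataclass
class DiffusionScheme:
    """Ordered diffusion encodings: (b_value, direction) per volume.

    ``bvals`` has shape (n,), ``bvecs`` shape (n, 3); b0 volumes carry an
    all-zero direction row.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        self.bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if self.bvals.shape[0] != self.bvecs.shape[0]:
            raise ProtocolError("bvals and bvecs length mismatch")
        norms = np.linalg.norm(self.bvecs, axis=1)
        dw = self.bvals > 0
        if np.any(np.abs(norms[dw] - 1.0) > 1e-10):
            raise ProtocolError("diffusion directions must have unit norm")

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def n_dwi(self) -> int:
        return int(np.sum(self.bvals > 0))

    @property
    def is_b0(self) -> np.ndarray:
        return self.bvals == 0

    def to_text(self) -> tuple[str, str]:
        """FSL-style bvals (one row) and bvecs (three rows) text blocks."""
        bvals = " ".join(f"{b:g}" for b in self.bvals)
        bvecs = "\n".join(
            " ".join(f"{v:.8f}" for v in self.bvecs[:, i]) for i in range(3)
        )
        return bvals + "\n", bvecs + "\n"


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Approximately uniform unit vectors via the spherical Fibonacci spiral."""
    if n == 0:
        return np.zeros((0, 3))
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def make_diffusion_scheme(
    shells: Sequence[tuple[float, int]], seed: int = 0
) -> DiffusionScheme:
    """Generate a multi-shell diffusion scheme (no b0 volumes).

    Per shell, directions are a spherical Fibonacci set rotated by a random
    rotation drawn deterministically from ``seed`` — approximately uniform on
    the sphere and exactly reproducible.
    """
    rng = np.random.default_rng(seed)
    bvals, bvecs = [], []
    for b, n in shells:
        if n < 0:
            raise ProtocolError("shell direction count must be >= 0")
        dirs = _fibonacci_sphere(int(n)) @ _random_rotation(rng).T
        bvals.extend([float(b)] * int(n))
        bvecs.append(dirs)
    if bvecs:
        bvecs = np.concatenate(bvecs, axis=0)
    else:
        bvecs = np.zeros((0, 3))
    return DiffusionScheme(np.asarray(bvals), bvecs)


def make_acquisition_schedule(
    scheme: DiffusionScheme, b0_interval: int = 10
) -> DiffusionScheme:
    """Intersperse b0 volumes into a diffusion scheme.

    One b0 volume is inserted at the start of every consecutive block of
    ``b0_interval`` diffusion volumes; a trailing partial block also gets a
    leading b0.  Total length is ``n + ceil(n / b0_interval)``.
    """
    if b0_interval < 1:
        raise ProtocolError("b0_interval must be >= 1")
    n = len(scheme)
    bvals, bvecs = [], []
    for start in range(0, n, b0_interval):
        bvals.append(0.0)
        bvecs.append(np.zeros(3))
        stop = min(start + b0_interval, n)
        bvals.extend(scheme.bvals[start:stop])
        bvecs.extend(scheme.bvecs[start:stop])
    if not bvals:
        return DiffusionScheme(np.zeros(0), np.zeros((0, 3)))
    return DiffusionScheme(np.asarray(bvals), np.stack(bvecs))


def caipi_slice_phase(protocol: ProtocolSpec, z: int) -> np.ndarray:
    """CAIPI phase modulation (radians) of band ``z`` along ky.

    ``phase(z, ky) = 2*pi * z * ky / mb_factor`` applied to the collapsed
    multi-band k-space shifts band ``z`` by ``ny * z / mb_factor`` pixels
    along phase encoding, moving simultaneously excited slices apart in the
    aliased image (controlled aliasing).
    """
    if not 0 <= z < protocol.mb_factor:
        raise IndexError(f"band index z={z} out of range for mb_factor={protocol.mb_factor}")
    ky = np.arange(protocol.ny)
    return 2.0 * np.pi * z * ky / protocol.mb_factor
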