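"""Acquisition container and its HDF5 serialization.

The on-disk layout mirrors the in-memory axis conventions::

    /kspace       complex (c, q, s, ny, nx)   imaging-echo k-space
    /nav_kspace   complex (c, q, s, my, mx)   navigator k-space (optional)
    /coil_maps    complex (c, z, ny, nx)
    /masks        uint8   (q, s, ny)
    /nav_masks    uint8   (q, s, my)          (optional)
    /bvals        float   (q,)
    /bvecs        float   (q, 3)              b0 rows all-zero
    /truth/*      simulation ground truth (optional)
    /protocol     group attributes: matrix, n_shots, r_inplane, mb_factor,
                  esp_ms, b0_interval, ky_shift, nav_matrix; dataset shells

Complex data are stored with h5py's native complex dtype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .protocol import DiffusionScheme, ProtocolSpec, SamplingPattern

__all__ = ["Acquisition"]


@dataclass
class Acquisition:
    """One simulated or measured multi-shot DWI acquisition (one MB group)."""

    y: np.ndarray
    maps: np.ndarray
    pattern: SamplingPattern
    protocol: ProtocolSpec
    scheme: DiffusionScheme | None = None
    y_nav: np.ndarray | None = None
    nav_masks: np.ndarray | None = None
    truth: dict = field(default_factory=dict)

    @property
    def n_encodings(self) -> int:
        return self.y.shape[1]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("kspace", data=np.asarray(self.y, dtype=np.complex64))
            f.create_dataset("coil_maps", data=np.asarray(self.maps, dtype=np.complex64))
            f.create_dataset("masks", data=self.pattern.masks.astype(np.uint8))
            if self.y_nav is not None:
                f.create_dataset("nav_kspace", data=np.asarray(self.y_nav, dtype=np.complex64))
                f.create_dataset("nav_masks", data=np.asarray(self.nav_masks, dtype=np.uint8))
            if self.scheme is not None:
                f.create_dataset("bvals", data=self.scheme.bvals)
                f.create_dataset("bvecs", data=self.scheme.bvecs)
            g = f.create_group("protocol")
            p = self.protocol
            g.attrs["matrix"] = p.matrix
            g.attrs["n_shots"] = p.n_shots
            g.attrs["r_inplane"] = p.r_inplane
            g.attrs["mb_factor"] = p.mb_factor
            g.attrs["esp_ms"] = p.esp_ms
            g.attrs["b0_interval"] = p.b0_interval
            g.attrs["ky_shift"] = bool(p.ky_shift)
            g.attrs["nav_matrix"] = "self" if p.self_navigated else list(p.nav_matrix)
            g.create_dataset("shells", data=np.asarray(p.shells, dtype=float).reshape(-1, 2))
            if self.truth:
                t = f.create_group("truth")
                for key, val in self.truth.items():
                    t.create_dataset(key, data=np.asarray(val))

    @classmethod
    def load(cls, path) -> "Acquisition":
        with h5py.File(path, "r") as f:
            g = f["protocol"]
            nav = g.attrs["nav_matrix"]
            nav = "self" if isinstance(nav, (str, bytes)) and str(nav) in ("self", "b'self'") else tuple(int(v) for v in nav)
            shells = tuple((float(b), int(n)) for b, n in f["protocol/shells"][()])
            protocol = ProtocolSpec(
                matrix=tuple(int(v) for v in g.attrs["matrix"]),
                n_shots=int(g.attrs["n_shots"]),
                r_inplane=int(g.attrs["r_inplane"]),
                mb_factor=int(g.attrs["mb_factor"]),
                esp_ms=float(g.attrs["esp_ms"]),
                shells=shells,
                b0_interval=int(g.attrs["b0_interval"]),
                nav_matrix=nav,
                ky_shift=bool(g.attrs["ky_shift"]),
            )
            scheme = None
            if "bvals" in f:
                scheme = DiffusionScheme(f["bvals"][()], f["bvecs"][()])
            truth = {}
            if "truth" in f:
                truth = {k: f["truth"][k][()] for k in f["truth"]}
            return cls(
                y=f["kspace"][()].astype(np.complex128),
                maps=f["coil_maps"][()].astype(np.complex128),
                pattern=SamplingPattern(f["masks"][()]),
                protocol=protocol,
                scheme=scheme,
                y_nav=f["nav_kspace"][()].astype(np.complex128) if "nav_kspace" in f else None,
                nav_masks=f["nav_masks"][()] if "nav_masks" in f else None,
                truth=truth,
            )
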