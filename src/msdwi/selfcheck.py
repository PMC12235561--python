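"""Built-in property checks: operator adjoints, prox oracle, LLR round trip.

Used by the ``selftest`` CLI subcommand and by the acceptance script; each
check recomputes its quantity from seeded random inputs at run time.
"""

from __future__ import annotations

import numpy as np

from .llr import LLRConfig, llr_adjoint, llr_adjoint_scaled, llr_transform, svt_normalized
from .operators import (
    adjoint_E1,
    adjoint_E2,
    adjoint_phase,
    apply_E1,
    apply_E2,
    apply_phase,
)
from .protocol import ProtocolSpec, SamplingPattern


def _crandn(rng, shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


def small_problem(rng, ny=12, nx=10, nc=3, nq=4, ns=2, mb=2):
    protocol = ProtocolSpec(
        matrix=(ny, nx), n_shots=ns, r_inplane=2, mb_factor=mb, esp_ms=1.0, ky_shift=True
    )
    pattern = SamplingPattern.from_protocol(protocol, nq)
    maps = _crandn(rng, (nc, mb, ny, nx))
    x = _crandn(rng, (nq, ns, mb, ny, nx))
    x_tilde = _crandn(rng, (nq, mb, ny, nx))
    phi = np.exp(1j * rng.standard_normal((nq, ns, mb, ny, nx)))
    y = _crandn(rng, (nc, nq, ns, ny, nx))
    return protocol, pattern, maps, x, x_tilde, phi, y


def adjoint_error_E1(seed=0) -> float:
    """Relative adjoint dot-product mismatch |<E1 x, y> - <x, E1^H y>|."""
    rng = np.random.default_rng(seed)
    protocol, pattern, maps, x, _, _, y = small_problem(rng)
    lhs = np.vdot(y, apply_E1(x, maps, pattern, protocol))
    rhs = np.vdot(adjoint_E1(y, maps, pattern, protocol), x)
    return abs(lhs - rhs) / (np.linalg.norm(x.ravel()) * np.linalg.norm(y.ravel()))


def adjoint_error_E2(seed=0) -> float:
    rng = np.random.default_rng(seed)
    protocol, pattern, maps, _, x_tilde, phi, y = small_problem(rng)
    lhs = np.vdot(y, apply_E2(x_tilde, phi, maps, pattern, protocol))
    rhs = np.vdot(adjoint_E2(y, phi, maps, pattern, protocol), x_tilde)
    return abs(lhs - rhs) / (
        np.linalg.norm(x_tilde.ravel()) * np.linalg.norm(y.ravel())
    )


def adjoint_error_phase(seed=0) -> float:
    rng = np.random.default_rng(seed)
    _, _, _, x, x_tilde, phi, _ = small_problem(rng)
    lhs = np.vdot(x, apply_phase(phi, x_tilde))
    rhs = np.vdot(adjoint_phase(phi, x), x_tilde)
    return abs(lhs - rhs) / (
        np.linalg.norm(x.ravel()) * np.linalg.norm(x_tilde.ravel())
    )


def adjoint_error_llr(seed=0, cfg: LLRConfig | None = None) -> float:
    rng = np.random.default_rng(seed)
    cfg = cfg or LLRConfig(block_width=4, stride=2)
    shape = (3, 2, 12, 10)
    x = _crandn(rng, shape)
    p = llr_transform(rng.standard_normal((3, 2, 12, 10)) + 0j, cfg) * 0
    p += _crandn(rng, p.shape)
    lhs = np.vdot(p, llr_transform(x, cfg))
    rhs = np.vdot(llr_adjoint(p, cfg, shape), x)
    return abs(lhs - rhs) / (np.linalg.norm(x.ravel()) * np.linalg.norm(p.ravel()))


def llr_roundtrip_error(seed=0, block=6, stride=1, shape=(5, 1, 24, 24)) -> float:
    rng = np.random.default_rng(seed)
    cfg = LLRConfig(block_width=block, stride=stride)
    x = _crandn(rng, shape)
    back = llr_adjoint_scaled(llr_transform(x, cfg), cfg, shape)
    return float(np.max(np.abs(back - x)))


def svt_prox_error(seed=0, tau=0.3, b=6, m=36, n=20) -> float:
    """Mismatch against the dense-SVD nuclear-norm prox with threshold tau*b."""
    rng = np.random.default_rng(seed)
    M = _crandn(rng, (m, n))
    ours = svt_normalized(M, tau, b)
    u, s, vh = np.linalg.svd(M, full_matrices=False)
    oracle = (u * np.maximum(s - tau * b, 0.0)) @ vh
    return float(np.max(np.abs(ours - oracle)))


def svt_nonexpansive_margin(seed=0, n_pairs=100, tau=0.2, b=6) -> float:
    """max over pairs of ||prox(M1)-prox(M2)|| - ||M1-M2|| (should be <= 0)."""
    rng = np.random.default_rng(seed)
    worst = -np.inf
    for _ in range(n_pairs):
        m1 = _crandn(rng, (18, 7))
        m2 = _crandn(rng, (18, 7))
        d_out = np.linalg.norm(svt_normalized(m1, tau, b) - svt_normalized(m2, tau, b))
        d_in = np.linalg.norm(m1 - m2)
        worst = max(worst, d_out - d_in)
    return float(worst)


def materialized_adjoint_error(seed=0) -> float:
    """Column-by-column 4x4 operator matrix vs conjugate transpose of E1."""
    rng = np.random.default_rng(seed)
    protocol = ProtocolSpec(matrix=(4, 4), n_shots=2, r_inplane=2, mb_factor=2, ky_shift=True)
    pattern = SamplingPattern.from_protocol(protocol, 2)
    maps = _crandn(rng, (2, 2, 4, 4))
    xshape = (2, 2, 2, 4, 4)
    yshape = (2, 2, 2, 4, 4)
    nX, nY = int(np.prod(xshape)), int(np.prod(yshape))
    A = np.zeros((nY, nX), dtype=complex)
    for i in range(nX):
        e = np.zeros(nX, dtype=complex)
        e[i] = 1.0
        A[:, i] = apply_E1(e.reshape(xshape), maps, pattern, protocol).ravel()
    Ah = np.zeros((nX, nY), dtype=complex)
    for i in range(nY):
        e = np.zeros(nY, dtype=complex)
        e[i] = 1.0
        Ah[:, i] = adjoint_E1(e.reshape(yshape), maps, pattern, protocol).ravel()
    return float(np.max(np.abs(Ah - A.conj().T)))


def run(seed: int = 0):
    """Execute all checks; returns a list of (name, passed, detail)."""
    results = []

    def record(name, value, tol):
        results.append((name, value < tol, f"value={value:.3e} tol={tol:g}"))

    record("adjoint E1", adjoint_error_E1(seed), 1e-6)
    record("adjoint E2", adjoint_error_E2(seed), 1e-6)
    record("adjoint Phi", adjoint_error_phase(seed), 1e-6)
    record("adjoint LLR", adjoint_error_llr(seed), 1e-6)
    record("materialized E1 matrix", materialized_adjoint_error(seed), 1e-10)
    for block, stride in [(3, 1), (6, 1), (6, 3), (6, 6), (9, 3), (9, 9)]:
        record(
            f"LLR round trip b={block} stride={stride}",
            llr_roundtrip_error(seed, block, stride),
            1e-12,
        )
    record("SVT prox oracle", svt_prox_error(seed), 1e-8)
    record("SVT identity at tau=0", svt_prox_error(seed, tau=0.0), 1e-10)
    results.append(
        (
            "SVT non-expansive",
            svt_nonexpansive_margin(seed) <= 1e-10,
            f"margin={svt_nonexpansive_margin(seed):.3e}",
        )
    )
    return results
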