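"""Image fidelity metrics for reconstruction evaluation."""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["ssim", "nrmse"]


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean structural similarity of magnitude image ``a`` against reference ``b``.

    Both images are normalized by the reference maximum, making the metric
    invariant to a common global intensity scale.  Gaussian weighting
    (sigma = 1.5) with the conventional constants K1 = 0.01, K2 = 0.03.
    """
    a = np.abs(np.asarray(a, dtype=float))
    b = np.abs(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    peak = b.max()
    if peak == 0:
        raise ValueError("reference image is identically zero")
    return float(
        structural_similarity(
            a / peak,
            b / peak,
            data_range=1.0,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
        )
    )


def nrmse(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized root-mean-square error ``||a - b|| / ||b||``."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ref = np.linalg.norm(b.ravel())
    if ref == 0:
        raise ValueError("reference has zero norm")
    return float(np.linalg.norm((a - b).ravel()) / ref)
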