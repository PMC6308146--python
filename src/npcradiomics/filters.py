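"""Derived images: Laplacian-of-Gaussian responses and 3-D wavelet sub-bands.

Both operators preserve the grid (shape, spacing, origin), so the ROI mask
applies to every derived image without resampling. The wavelet transform is
a one-level undecimated (stationary) 3-D decomposition with Coiflet-1
filters, implemented as a centered circular separable convolution; per-axis
low/high combinations yield the 8 sub-bands LLL..HHH, first letter = array
axis 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

from .grids import ImageVolume

__all__ = [
    "DerivedImage",
    "LOG_SIGMAS_MM",
    "WAVELET_BANDS",
    "DERIVATIONS",
    "log_response",
    "wavelet_subbands",
]

LOG_SIGMAS_MM = (0.5, 1.5, 2.5)
WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
DERIVATIONS = (
    ("original",)
    + tuple(f"LoG_{s:g}" for s in LOG_SIGMAS_MM)
    + tuple(f"W_{b}" for b in WAVELET_BANDS)
)

_WAVELET = "coif1"


@dataclass
class DerivedImage(ImageVolume):
    derivation: str = "original"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.derivation not in DERIVATIONS:
            raise ValueError(f"unknown derivation tag {self.derivation!r}")


def _log_taps(sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Sampled Gaussian and Gaussian-second-derivative taps.

    The smoothing taps are normalized to unit sum; the second-derivative
    taps share the same normalization and are then recentered to exact zero
    sum, so the operator annihilates constant (and, by symmetry, linear)
    images to machine precision.
    """
    radius = max(1, int(np.ceil(6.0 * sigma)))
    t = np.arange(-radius, radius + 1, dtype=np.float64)
    g_raw = np.exp(-(t**2) / (2.0 * sigma**2))
    norm = g_raw.sum()
    g = g_raw / norm
    g2 = (t**2 / sigma**4 - 1.0 / sigma**2) * g_raw / norm
    g2 -= g2.mean()
    return g, g2


def log_response(vol: ImageVolume, sigma_mm: float) -> DerivedImage:
    """Laplacian of the Gaussian-smoothed image at physical width sigma_mm.

    Separable implementation: for each axis, the sampled second-derivative
    -of-Gaussian filter is applied along that axis and plain Gaussian
    smoothing along the others; the three responses sum to the LoG. sigma
    is converted to voxels via the spacing; boundaries are handled by
    reflection. A sigma below half the voxel size is under-resolved and
    triggers a warning.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    sigma_vox = [sigma_mm / s for s in vol.spacing_mm]
    if min(sigma_vox) < 0.5:
        warnings.warn(
            f"LoG sigma {sigma_mm} mm is under-resolved for spacing {vol.spacing_mm}"
        )
    taps = [_log_taps(s) for s in sigma_vox]
    data = np.asarray(vol.values, dtype=np.float64)
    response = np.zeros_like(data)
    for deriv_axis in range(3):
        part = data
        for axis in range(3):
            g, g2 = taps[axis]
            w = g2 if axis == deriv_axis else g
            part = ndimage.correlate1d(part, w, axis=axis, mode="reflect")
        response += part
    return DerivedImage(
        response, vol.spacing_mm, vol.origin_mm, derivation=f"LoG_{sigma_mm:g}"
    )


def _circular_filter(x: np.ndarray, taps: np.ndarray, axis: int) -> np.ndarray:
    """Centered circular convolution along one axis.

    out[n] = sum_k taps[k] * x[(n - k + c) mod N] with c = len(taps) // 2.
    """
    c = len(taps) // 2
    out = np.zeros_like(x, dtype=np.float64)
    for k, w in enumerate(taps):
        out += w * np.roll(x, k - c, axis=axis)
    return out


def wavelet_subbands(vol: ImageVolume) -> dict[str, DerivedImage]:
    """One-level undecimated 3-D wavelet transform: the 8 LLL..HHH sub-bands.

    Coiflet-1 analysis filters are applied per axis by centered circular
    convolution; L = low-pass, H = high-pass, letters in array-axis order.
    """
    wav = pywt.Wavelet(_WAVELET)
    lo = np.asarray(wav.dec_lo, dtype=np.float64)
    hi = np.asarray(wav.dec_hi, dtype=np.float64)
    if min(vol.shape) < len(lo):
        raise ValueError(
            f"grid dimension {min(vol.shape)} smaller than filter length {len(lo)}"
        )

    data = np.asarray(vol.values, dtype=np.float64)
    partial = {"": data}
    for axis in range(3):
        nxt = {}
        for tag, arr in partial.items():
            nxt[tag + "L"] = _circular_filter(arr, lo, axis)
            nxt[tag + "H"] = _circular_filter(arr, hi, axis)
        partial = nxt

    return {
        band: DerivedImage(
            partial[band], vol.spacing_mm, vol.origin_mm, derivation=f"W_{band}"
        )
        for band in WAVELET_BANDS
    }
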