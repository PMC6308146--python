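"""The default per-case feature manifest and its extraction driver.

One case yields 1117 named features:

* original image: 13 shape + 18 first-order + 74 texture = 105
* each of 11 derived images (3 LoG widths, 8 wavelet sub-bands):
  18 first-order + 74 texture = 92

105 + 11 x 92 = 1117. Keys follow the grammar ``family_Abbrev`` on the
original image (e.g. ``glcm_CT``) and ``<derivation>__family_Abbrev`` on
derived images (e.g. ``W_HLL__gldm_DE``, ``LoG_1.5__F_RMS``). The
abbreviation map is machine-readable (:data:`ABBREVIATIONS`).

Shape features are geometry, not intensity, so they are computed once from
the resampled mask; every derived image is re-normalized and re-quantized
inside the contour before texture computation because LoG and wavelet
responses live on their own intensity scales.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..filters import LOG_SIGMAS_MM, log_response, wavelet_subbands
from ..grids import ImageVolume, RoiMask
from ..preprocess import normalize_and_quantize, resample_isotropic
from .firstorder import FIRSTORDER_KEYS, first_order_features
from .shape import SHAPE_KEYS, shape_features
from .texture import (
    GLCM_KEYS,
    GLDM_KEYS,
    GLRLM_KEYS,
    GLSZM_KEYS,
    NGTDM_KEYS,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = ["FEATURE_MANIFEST", "ABBREVIATIONS", "N_FEATURES", "extract_all"]

_INTENSITY_KEYS = (
    FIRSTORDER_KEYS + GLCM_KEYS + GLRLM_KEYS + GLSZM_KEYS + GLDM_KEYS + NGTDM_KEYS
)

_DERIVED_TAGS = tuple(f"LoG_{s:g}" for s in LOG_SIGMAS_MM) + tuple(
    f"W_{b}" for b in ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
)

FEATURE_MANIFEST: tuple[str, ...] = (
    SHAPE_KEYS
    + _INTENSITY_KEYS
    + tuple(f"{tag}__{key}" for tag in _DERIVED_TAGS for key in _INTENSITY_KEYS)
)
N_FEATURES = len(FEATURE_MANIFEST)

ABBREVIATIONS: dict[str, str] = {
    "shape_Volume": "volume (mm^3, voxel-counted)",
    "shape_SurfaceArea": "surface area (mm^2, marching-cubes mesh)",
    "shape_SVRatio": "surface-to-volume ratio (1/mm)",
    "shape_Sphericity": "sphericity",
    "shape_Max3DDiameter": "maximum 3-D diameter (mm)",
    "shape_Max2DDiameterSlice": "maximum 2-D diameter, plane orthogonal to axis 0 (mm)",
    "shape_Max2DDiameterColumn": "maximum 2-D diameter, plane orthogonal to axis 1 (mm)",
    "shape_Max2DDiameterRow": "maximum 2-D diameter, plane orthogonal to axis 2 (mm)",
    "shape_MajorAxisLength": "major principal axis length (mm)",
    "shape_MinorAxisLength": "minor principal axis length (mm)",
    "shape_LeastAxisLength": "least principal axis length (mm)",
    "shape_Elongation": "elongation",
    "shape_Flatness": "flatness",
    "F_Energy": "first-order energy",
    "F_Entropy": "first-order entropy (64-level histogram, log2)",
    "F_Min": "minimum",
    "F_P10": "10th percentile",
    "F_P90": "90th percentile",
    "F_Max": "maximum",
    "F_Mean": "mean",
    "F_Median": "median",
    "F_IQR": "interquartile range",
    "F_Range": "range",
    "F_MAD": "mean absolute deviation",
    "F_rMAD": "robust mean absolute deviation (10-90 percentile band)",
    "F_RMS": "root mean squared",
    "F_Skew": "skewness",
    "F_Kurt": "kurtosis (non-excess)",
    "F_Variance": "variance (population)",
    "F_Uniformity": "uniformity (64-level histogram)",
    "F_SD": "standard deviation (population)",
    "glcm_AC": "GLCM autocorrelation",
    "glcm_CP": "GLCM cluster prominence",
    "glcm_CS": "GLCM cluster shade",
    "glcm_CT": "GLCM cluster tendency",
    "glcm_Contrast": "GLCM contrast",
    "glcm_Correlation": "GLCM correlation",
    "glcm_DA": "GLCM difference average",
    "glcm_DE": "GLCM difference entropy",
    "glcm_DV": "GLCM difference variance",
    "glcm_JA": "GLCM joint average",
    "glcm_JE": "GLCM joint energy",
    "glcm_JEN": "GLCM joint entropy",
    "glcm_IMC": "GLCM informational measure of correlation 1",
    "glcm_IMC2": "GLCM informational measure of correlation 2",
    "glcm_IDM": "GLCM inverse difference moment",
    "glcm_IDMN": "GLCM inverse difference moment normalized",
    "glcm_ID": "GLCM inverse difference",
    "glcm_IDN": "GLCM inverse difference normalized",
    "glcm_IV": "GLCM inverse variance",
    "glcm_MP": "GLCM maximum probability",
    "glcm_SA": "GLCM sum average",
    "glcm_SEN": "GLCM sum entropy",
    "glcm_SS": "GLCM sum of squares (variance)",
    "glrlm_SRE": "GLRLM short-run emphasis",
    "glrlm_LRE": "GLRLM long-run emphasis",
    "glrlm_GLN": "GLRLM gray-level nonuniformity",
    "glrlm_GLNN": "GLRLM gray-level nonuniformity normalized",
    "glrlm_RLN": "GLRLM run-length nonuniformity",
    "glrlm_RLNN": "GLRLM run-length nonuniformity normalized",
    "glrlm_RP": "GLRLM run percentage",
    "glrlm_GLV": "GLRLM gray-level variance",
    "glrlm_RV": "GLRLM run variance",
    "glrlm_RE": "GLRLM run entropy",
    "glrlm_LGLRE": "GLRLM low gray-level run emphasis",
    "glrlm_HGLRE": "GLRLM high gray-level run emphasis",
    "glrlm_SRLGLE": "GLRLM short-run low gray-level emphasis",
    "glrlm_SRHGLE": "GLRLM short-run high gray-level emphasis",
    "glrlm_LRLGLE": "GLRLM long-run low gray-level emphasis",
    "glrlm_LRHGLE": "GLRLM long-run high gray-level emphasis",
    "glszm_SAE": "GLSZM small-area emphasis",
    "glszm_LAE": "GLSZM large-area emphasis",
    "glszm_GLN": "GLSZM gray-level nonuniformity",
    "glszm_GLNN": "GLSZM gray-level nonuniformity normalized",
    "glszm_SZN": "GLSZM size-zone nonuniformity",
    "glszm_SZNN": "GLSZM size-zone nonuniformity normalized",
    "glszm_ZP": "GLSZM zone percentage",
    "glszm_GLV": "GLSZM gray-level variance",
    "glszm_ZV": "GLSZM zone variance",
    "glszm_ZE": "GLSZM zone entropy",
    "glszm_LGLZE": "GLSZM low gray-level zone emphasis",
    "glszm_HGLZE": "GLSZM high gray-level zone emphasis",
    "glszm_SALGLE": "GLSZM small-area low gray-level emphasis",
    "glszm_SAHGLE": "GLSZM small-area high gray-level emphasis",
    "glszm_LALGLE": "GLSZM large-area low gray-level emphasis",
    "glszm_LAHGLE": "GLSZM large-area high gray-level emphasis",
    "gldm_SDE": "GLDM small-dependence emphasis",
    "gldm_LDE": "GLDM large-dependence emphasis",
    "gldm_GLN": "GLDM gray-level nonuniformity",
    "gldm_DN": "GLDM dependence nonuniformity",
    "gldm_DNN": "GLDM dependence nonuniformity normalized",
    "gldm_GLV": "GLDM gray-level variance",
    "gldm_DV": "GLDM dependence variance",
    "gldm_DE": "GLDM dependence entropy",
    "gldm_LGLE": "GLDM low gray-level emphasis",
    "gldm_HGLE": "GLDM high gray-level emphasis",
    "gldm_SDLGLE": "GLDM small-dependence low gray-level emphasis",
    "gldm_SDHGLE": "GLDM small-dependence high gray-level emphasis",
    "gldm_LDLGLE": "GLDM large-dependence low gray-level emphasis",
    "gldm_LDHGLE": "GLDM large-dependence high gray-level emphasis",
    "ngtdm_Coarseness": "NGTDM coarseness",
    "ngtdm_Contrast": "NGTDM contrast",
    "ngtdm_Busyness": "NGTDM busyness",
    "ngtdm_Complexity": "NGTDM complexity",
    "ngtdm_Strength": "NGTDM strength",
}


def _intensity_block(vol: ImageVolume, mask: RoiMask, n_levels: int) -> dict[str, float]:
    qroi = normalize_and_quantize(vol, mask, n_levels=n_levels)
    out: dict[str, float] = {}
    out.update(first_order_features(qroi))
    out.update(glcm_features(qroi))
    out.update(glrlm_features(qroi))
    out.update(glszm_features(qroi))
    out.update(gldm_features(qroi))
    out.update(ngtdm_features(qroi))
    return out


def extract_all(
    vol: ImageVolume,
    mask: RoiMask,
    target_mm: float = 1.0,
    n_levels: int = 64,
) -> tuple[dict[str, float], dict]:
    """Full 1117-feature vector for one case.

    Returns ``(features, provenance)``; ``provenance`` records the
    preprocessing parameters and flags any non-finite feature (a flagged
    case is returned, never silently dropped).
    """
    rvol, rmask = resample_isotropic(vol, mask, target_mm=target_mm)
    features: dict[str, float] = {}
    features.update(shape_features(rmask))
    features.update(_intensity_block(rvol, rmask, n_levels))

    derived = [log_response(rvol, s) for s in LOG_SIGMAS_MM]
    bands = wavelet_subbands(rvol)
    derived.extend(bands[b] for b in ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"))
    for dimg in derived:
        block = _intensity_block(dimg, rmask, n_levels)
        features.update({f"{dimg.derivation}__{k}": v for k, v in block.items()})

    ordered = {k: features[k] for k in FEATURE_MANIFEST}
    nan_keys = [k for k, v in ordered.items() if not np.isfinite(v)]
    if nan_keys:
        warnings.warn(f"case has {len(nan_keys)} non-finite features (flagged)")
    provenance = {
        "target_mm": target_mm,
        "n_levels": n_levels,
        "pipeline_order": ["resample_isotropic", "normalize_and_quantize"],
        "n_features": len(ordered),
        "nan_features": nan_keys,
    }
    return ordered, provenance
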