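"""First-order (intensity histogram) features.

Entropy and uniformity are computed on the discretized 1..n_levels
histogram (log base 2); every other statistic uses the raw intensities of
the included ROI voxels. Moments are population moments (ddof = 0);
kurtosis is the non-excess Pearson form (Gaussian -> 3). Degenerate
conventions: a constant ROI has variance 0, entropy 0, uniformity 1, and
skewness/kurtosis are reported as 0.
"""

from __future__ import annotations

import numpy as np

from ..preprocess import QuantizedRoi

__all__ = ["FIRSTORDER_KEYS", "first_order_features"]

FIRSTORDER_KEYS = (
    "F_Energy",
    "F_Entropy",
    "F_Min",
    "F_P10",
    "F_P90",
    "F_Max",
    "F_Mean",
    "F_Median",
    "F_IQR",
    "F_Range",
    "F_MAD",
    "F_rMAD",
    "F_RMS",
    "F_Skew",
    "F_Kurt",
    "F_Variance",
    "F_Uniformity",
    "F_SD",
)


def first_order_features(qroi: QuantizedRoi) -> dict[str, float]:
    x = np.asarray(qroi.included_values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("first-order features need at least 2 included voxels")

    hist = qroi.level_histogram().astype(np.float64)
    p = hist[hist > 0] / hist.sum()
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    mean = float(x.mean())
    var = float(x.var())
    sd = float(np.sqrt(var))
    centered = x - mean
    if var > 0:
        skew = float((centered**3).mean() / var**1.5)
        kurt = float((centered**4).mean() / var**2)
    else:
        skew = kurt = 0.0

    p10, p90 = (float(v) for v in np.percentile(x, [10, 90]))
    mid = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(mid - mid.mean()).mean()) if mid.size else 0.0

    values = {
        "F_Energy": float((x**2).sum()),
        "F_Entropy": entropy,
        "F_Min": float(x.min()),
        "F_P10": p10,
        "F_P90": p90,
        "F_Max": float(x.max()),
        "F_Mean": mean,
        "F_Median": float(np.median(x)),
        "F_IQR": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "F_Range": float(x.max() - x.min()),
        "F_MAD": float(np.abs(centered).mean()),
        "F_rMAD": rmad,
        "F_RMS": float(np.sqrt((x**2).mean())),
        "F_Skew": skew,
        "F_Kurt": kurt,
        "F_Variance": var,
        "F_Uniformity": uniformity,
        "F_SD": sd,
    }
    return values
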