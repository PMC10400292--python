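"""First-order (intensity histogram) features.

All moments are population-normalized (divide by n).  Entropy and
uniformity are computed on the fixed-bin-width discretized histogram;
everything else uses the raw intensities.
"""

from __future__ import annotations

import numpy as np

FIRST_ORDER_NAMES = [
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "StandardDeviation",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
]

#: features that are undefined on a single-voxel region
DISPERSION_FEATURES = frozenset(
    {
        "InterquartileRange",
        "Range",
        "MeanAbsoluteDeviation",
        "RobustMeanAbsoluteDeviation",
        "StandardDeviation",
        "Skewness",
        "Kurtosis",
        "Variance",
    }
)


def discretize(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width gray-level discretization.

    ``level(x) = floor((x - min) / bin_width) + 1``; levels start at 1 and
    the mapping is invariant to adding a constant to all values.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty ROI")
    return (np.floor((values - values.min()) / bin_width) + 1).astype(np.int64)


def first_order_features(
    values: np.ndarray, voxel_volume_mm3: float = 1.0, bin_width: float = 25.0
) -> dict[str, float]:
    """The 19 first-order features on a flat array of ROI intensities."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    mean = float(x.mean())
    out: dict[str, float] = {}
    out["Energy"] = float(np.sum(x**2))
    out["TotalEnergy"] = float(voxel_volume_mm3 * out["Energy"])
    out["Minimum"] = float(x.min())
    out["Maximum"] = float(x.max())
    out["Mean"] = mean
    out["Median"] = float(np.median(x))
    out["10Percentile"] = float(np.percentile(x, 10))
    out["90Percentile"] = float(np.percentile(x, 90))
    out["RootMeanSquared"] = float(np.sqrt(np.mean(x**2)))

    levels = discretize(x, bin_width)
    p = np.bincount(levels)[1:].astype(float)
    p = p[p > 0] / n
    out["Entropy"] = float(-np.sum(p * np.log2(p)))
    out["Uniformity"] = float(np.sum(p**2))

    if n == 1:
        for name in DISPERSION_FEATURES:
            out[name] = float("nan")
        return {k: out[k] for k in FIRST_ORDER_NAMES}

    out["InterquartileRange"] = float(np.percentile(x, 75) - np.percentile(x, 25))
    out["Range"] = out["Maximum"] - out["Minimum"]
    out["MeanAbsoluteDeviation"] = float(np.mean(np.abs(x - mean)))
    p10, p90 = out["10Percentile"], out["90Percentile"]
    sel = x[(x >= p10) & (x <= p90)]
    out["RobustMeanAbsoluteDeviation"] = (
        float(np.mean(np.abs(sel - sel.mean()))) if sel.size else 0.0
    )
    var = float(np.mean((x - mean) ** 2))
    out["Variance"] = var
    out["StandardDeviation"] = float(np.sqrt(var))
    if var > 0:
        m3 = float(np.mean((x - mean) ** 3))
        m4 = float(np.mean((x - mean) ** 4))
        out["Skewness"] = m3 / var**1.5
        out["Kurtosis"] = m4 / var**2
    else:
        out["Skewness"] = 0.0
        out["Kurtosis"] = 0.0
    return {k: out[k] for k in FIRST_ORDER_NAMES}
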