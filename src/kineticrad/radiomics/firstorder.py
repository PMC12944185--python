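"""First-order intensity statistics of the in-ROI voxel values.

Entropy and Uniformity operate on the fixed-bin-width discretized levels;
everything else on the raw intensities. Zero-variance ROIs report
Skewness = Kurtosis = 0 rather than NaN.
"""

from __future__ import annotations

import numpy as np

_EPS = np.spacing(1.0)


def firstorder_features(
    values: np.ndarray, levels: np.ndarray, voxel_volume: float
) -> dict[str, float]:
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    m3 = float(((x - mean) ** 3).mean())
    m4 = float(((x - mean) ** 4).mean())
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]

    counts = np.bincount(np.asarray(levels, dtype=np.int64).ravel())[1:]
    p = counts[counts > 0] / n

    energy = float((x**2).sum())
    return {
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Energy": energy,
        "Entropy": float(-(p * np.log2(p + _EPS)).sum()),
        "InterquartileRange": float(p75 - p25),
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Maximum": float(x.max()),
        "Mean": mean,
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "TotalEnergy": voxel_volume * energy,
        "Uniformity": float((p**2).sum()),
        "Variance": m2,
    }
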