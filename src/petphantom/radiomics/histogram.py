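"""First-order (intensity histogram) features.

Moments are computed on the raw intensities inside the MTV; Entropy and
Uniformity operate on the 64-level discretized histogram so they share the
texture features' gray-level resolution.  Population (ddof=0) moments are
used throughout.  Constant regions return the documented sentinels:
Kurtosis = Skewness = 0, Entropy = 0, Uniformity = 1.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .preprocess import DiscretizedVolume, discretize


def histogram_features(
    image, mask, disc: DiscretizedVolume | None = None, n_levels: int = 64
) -> dict[str, float]:
    """The 13 first-order features of the within-mask intensity distribution."""
    values = image.values if hasattr(image, "values") else np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    x = values[mask].astype(np.float64)
    if x.size == 0:
        raise ValueError("empty mask")
    if disc is None:
        disc = discretize(values, mask, n_levels=n_levels)
    lv = disc.levels[disc.mask]
    p = np.bincount(lv, minlength=disc.n_levels + 1)[1:] / lv.size
    pz = p[p > 0]

    var = float(x.var())  # population variance
    constant = var == 0.0
    return {
        "Maximum": float(x.max()),
        "Minimum": float(x.min()),
        "Mean": float(x.mean()),
        "Median": float(np.median(x)),
        "Mean absolute deviation (MAD)": float(np.abs(x - x.mean()).mean()),
        "Root mean square (RMS)": float(np.sqrt(np.mean(x**2))),
        "Energy": float(np.sum(x**2)),
        "Entropy": float(-np.sum(pz * np.log2(pz))),
        "Kurtosis": 0.0 if constant else float(stats.kurtosis(x, fisher=True, bias=True)),
        "Skewness": 0.0 if constant else float(stats.skew(x, bias=True)),
        "Standard deviation": float(np.sqrt(var)),
        "Uniformity": float(np.sum(p**2)),
        "Variance": var,
    }
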