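"""The frozen 58-feature registry and the one-call extraction pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..volume import ActivityVolume
from .histogram import histogram_features
from .morphology import morphological_features
from .preprocess import discretize, resample_isotropic
from .texture import glcm_features, glrlm_features, glszm_features, ngtdm_features
from .texture import _RL_NAMES, _SZ_NAMES

GROUPS = ("IF_M", "IF_HIST", "IF_TX-GLCM", "IF_TX-GLRLM", "IF_TX-GLSZM", "IF_TX-NGTDM")

#: (group, feature name) pairs in canonical order; length 58
FEATURE_REGISTRY: tuple[tuple[str, str], ...] = tuple(
    [("IF_M", n) for n in (
        "MTV", "Surface", "Spherical disproportion", "Sphericity",
        "Surface-volume ratio (SV)")]
    + [("IF_HIST", n) for n in (
        "Maximum", "Minimum", "Mean", "Median", "Mean absolute deviation (MAD)",
        "Root mean square (RMS)", "Energy", "Entropy", "Kurtosis", "Skewness",
        "Standard deviation", "Uniformity", "Variance")]
    + [("IF_TX-GLCM", n) for n in (
        "Energy", "Contrast", "Entropy", "Homogeneity", "Correlation",
        "SumAverage", "Variance", "Dissimilarity", "Autocorrelation")]
    + [("IF_TX-GLRLM", n) for n in _RL_NAMES]
    + [("IF_TX-GLSZM", n) for n in _SZ_NAMES]
    + [("IF_TX-NGTDM", n) for n in (
        "Coarseness", "Contrast", "Busyness", "Complexity", "Strength")]
)

GROUP_SIZES = {g: sum(1 for gg, _ in FEATURE_REGISTRY if gg == g) for g in GROUPS}

#: CSV / report column key for a registry entry
def feature_key(group: str, name: str) -> str:
    return f"{group}:{name}"

FEATURE_KEYS = tuple(feature_key(g, n) for g, n in FEATURE_REGISTRY)


@dataclass
class FeatureVector:
    """58 named scalar features with group labels and degeneracy flags."""

    values: dict[str, float]  # keyed by feature_key, registry order
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        missing = [k for k in FEATURE_KEYS if k not in self.values]
        if missing:
            raise ValueError(f"feature vector incomplete; missing {missing[:3]}...")

    def __len__(self) -> int:
        return len(FEATURE_KEYS)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_KEYS], dtype=float)

    def group(self, group: str) -> dict[str, float]:
        return {n: self.values[feature_key(group, n)]
                for g, n in FEATURE_REGISTRY if g == group}


def extract_all(
    image: ActivityVolume,
    mask: np.ndarray,
    n_levels: int = 64,
    per_direction_average: bool = False,
) -> FeatureVector:
    """Run the full pipeline: resample -> discretize -> all five groups.

    ``per_direction_average`` switches GLCM/GLRLM to averaging features over
    the 13 directions instead of merging matrices (the merged form is the
    default).  Degenerate sub-results (constant region, single voxel) are
    recorded in ``flags``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    img_iso, mask_iso = resample_isotropic(image, mask)
    if not mask_iso.any():  # a tiny mask can vanish under resampling
        mask_iso = mask
        img_iso = image
    disc = discretize(img_iso, mask_iso, n_levels=n_levels)

    flags: dict[str, str] = {}
    if disc.degenerate:
        flags["discretization"] = "constant region: single gray level"
    if int(mask_iso.sum()) < 2:
        flags["mask"] = "single voxel"

    groups = {
        "IF_M": morphological_features(mask_iso, img_iso.spacing),
        "IF_HIST": histogram_features(img_iso, mask_iso, disc=disc),
    }
    if per_direction_average:
        from .texture import DIRECTIONS_13

        def avg(fn):
            per = [fn(disc, directions=(d,)) for d in DIRECTIONS_13]
            return {k: float(np.nanmean([p[k] for p in per])) for k in per[0]}

        groups["IF_TX-GLCM"] = avg(glcm_features)
        groups["IF_TX-GLRLM"] = avg(glrlm_features)
    else:
        groups["IF_TX-GLCM"] = glcm_features(disc)
        groups["IF_TX-GLRLM"] = glrlm_features(disc)
    groups["IF_TX-GLSZM"] = glszm_features(disc)
    groups["IF_TX-NGTDM"] = ngtdm_features(disc)

    values: dict[str, float] = {}
    for grp, name in FEATURE_REGISTRY:
        values[feature_key(grp, name)] = float(groups[grp][name])
    for grp, feats in groups.items():
        if any(isinstance(v, float) and np.isnan(v) for v in feats.values()):
            flags.setdefault(grp, "degenerate: sentinel values present")
    return FeatureVector(values=values, flags=flags)
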