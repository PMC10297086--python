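"""Image-homogeneity features on the full image, peak region and complement.

Ten base statistics quantify the non-homogeneous behaviour of a unit-mean
intensity map:

    MAX, MIN, MEA (mean), MED (median), VAR (population variance),
    MAD0 = mean(|x - MEA|), MAD1 = median(|x - MED|),
    M2AVG = MAX/MEA, ROS1 = (MAX-MIN)/(MEA-MIN), ROS2 = (MAX-MIN)/(MED-MIN).

All ten are computed on the in-breast pixels ("_i" suffix).  The eight
non-ratio bases are additionally computed on the peak region "_p" (the
8-connected component of the super-level set at MAX/sqrt(2) containing the
global argmax) and on its in-breast complement "_c"; the "_r" features are
the elementwise _p/_c ratios.  34 features in total.

Undefined values (zero denominators, empty complement) are returned as NaN
and flagged — never silently imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _cc_label

from .reconstruction import DegenerateImageError, MicrowaveImage

__all__ = [
    "BASE_FEATURES",
    "REGION_FEATURES",
    "FEATURE_IDS",
    "PeakRegion",
    "FeatureVector",
    "base_features",
    "peak_region",
    "feature_vector",
]

BASE_FEATURES = ("MAX", "MIN", "MEA", "MED", "VAR", "MAD0", "MAD1", "M2AVG", "ROS1", "ROS2")
#: bases evaluated on the _p/_c/_r domains (ROS1/ROS2 are full-image only)
REGION_FEATURES = BASE_FEATURES[:8]

FEATURE_IDS: tuple[str, ...] = (
    tuple(f"{b}_i" for b in BASE_FEATURES)
    + tuple(f"{b}_p" for b in REGION_FEATURES)
    + tuple(f"{b}_c" for b in REGION_FEATURES)
    + tuple(f"{b}_r" for b in REGION_FEATURES)
)
assert len(FEATURE_IDS) == 34


@dataclass
class PeakRegion:
    """The "_p" domain: connected super-level region around the image maximum."""

    mask: np.ndarray
    level: float
    seed_pixel: tuple[int, int]


@dataclass
class FeatureVector:
    """Ordered map of the 34 feature values; undefined entries are NaN."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_IDS:
            raise ValueError("feature vector must contain exactly the 34 canonical feature ids in order")

    def __getitem__(self, feature_id: str) -> float:
        return self.values[feature_id]

    def defined(self, feature_id: str) -> bool:
        return math.isfinite(self.values[feature_id])

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


def base_features(values) -> dict[str, float]:
    """The ten base statistics of a non-empty value collection.

    VAR uses the population divisor N (the pixel set is the full
    population); MED is the mean of the middle two for even counts.
    M2AVG/ROS1/ROS2 are NaN when their denominator vanishes.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("base_features requires at least one value")
    mx, mn = float(x.max()), float(x.min())
    mea, med = float(x.mean()), float(np.median(x))
    out = {
        "MAX": mx,
        "MIN": mn,
        "MEA": mea,
        "MED": med,
        "VAR": float(np.var(x)),
        "MAD0": float(np.mean(np.abs(x - mea))),
        "MAD1": float(np.median(np.abs(x - med))),
        "M2AVG": mx / mea if mea != 0 else math.nan,
        "ROS1": (mx - mn) / (mea - mn) if mea != mn else math.nan,
        "ROS2": (mx - mn) / (med - mn) if med != mn else math.nan,
    }
    return out


def peak_region(image: MicrowaveImage) -> PeakRegion:
    """Peak region: 8-connected component at level MAX/sqrt(2) holding the argmax.

    The super-level set {intensity >= MAX/sqrt(2)} is restricted to the
    breast mask; of its 8-connected components, the one containing the
    global masked argmax (row-major tie-break) is the peak region.  A bare
    threshold would merge distant peaks; the connectivity rule keeps the
    region "centred in the image's maximum".
    """
    mask = image.grid.breast_mask
    vals = image.intensity[mask]
    if vals.size == 0 or not np.any(vals > 0):
        raise DegenerateImageError("peak region undefined for an all-zero image")
    masked = np.where(mask, image.intensity, -np.inf)
    seed_flat = int(np.argmax(masked))  # row-major tie-break
    seed = np.unravel_index(seed_flat, image.intensity.shape)
    level = float(masked[seed]) / math.sqrt(2.0)
    super_level = mask & (image.intensity >= level)
    labels = _cc_label(super_level, connectivity=2)
    region = labels == labels[seed]
    return PeakRegion(mask=region, level=level, seed_pixel=(int(seed[0]), int(seed[1])))


def _region_map(values: np.ndarray | None) -> dict[str, float]:
    if values is None or values.size == 0:
        return {b: math.nan for b in REGION_FEATURES}
    full = base_features(values)
    return {b: full[b] for b in REGION_FEATURES}


def feature_vector(image: MicrowaveImage) -> FeatureVector:
    """All 34 homogeneity features of a normalised image.

    The image must be unit-mean normalised (so MEA_i = 1 and MAX_i is the
    normalised maximum).  If the peak region covers the whole breast mask
    the _c and _r features are NaN-flagged but the vector is still returned.
    """
    if not image.normalized:
        raise ValueError("feature_vector requires a unit-mean normalised image")
    region = peak_region(image)
    mask = image.grid.breast_mask
    vals_i = image.intensity[mask]
    vals_p = image.intensity[region.mask]
    comp = mask & ~region.mask
    vals_c = image.intensity[comp] if np.any(comp) else None

    f_i = base_features(vals_i)
    f_p = _region_map(vals_p)
    f_c = _region_map(vals_c)

    values: dict[str, float] = {f"{b}_i": f_i[b] for b in BASE_FEATURES}
    values.update({f"{b}_p": f_p[b] for b in REGION_FEATURES})
    values.update({f"{b}_c": f_c[b] for b in REGION_FEATURES})
    for b in REGION_FEATURES:
        p, c = f_p[b], f_c[b]
        values[f"{b}_r"] = p / c if math.isfinite(p) and math.isfinite(c) and c != 0 else math.nan
    return FeatureVector(values)
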