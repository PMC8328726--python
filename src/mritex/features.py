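"""The twelve named feature operators and the feature-family sets.

First-order statistics (of the raw in-mask intensities y_j, m pixels):

* j_mean      = (1/m) sum y_j
* j_variance  = (1/m) sum (y_j - mean)^2   (population form)
* j_std       = sqrt(j_variance)
* j_skewness  = m3 / m2^(3/2)
* j_kurtosis  = m4 / m2^2 - 3              (excess convention)

Shape descriptors of the binary mask:

* s_area        A = in-mask pixel count
* s_perimeter   L = digital boundary length
* s_circularity = 4 pi A / L^2
* s_elongation  E = n / N, minor/major axes of the best-fit ellipse
* s_form        = L * E / (8 A)

Co-occurrence features of a normalized GLCM L(j, k) with marginal means
phi_y, phi_z and standard deviations lambda_y, lambda_z:

* t_contrast    = sum_jk (j - k)^2 L(j, k)
* t_correlation = (sum_jk j k L(j, k) - phi_y phi_z) / (lambda_y lambda_z)
* t_entropy     = -sum_jk L(j, k) log L(j, k),  0 log 0 := 0  (base 2)

Run-length and size-zone matrices are summarized by the five classical
statistics each (emphasis on short/long runs or small/large zones,
gray-level nonuniformity, length/size nonuniformity, run/zone
percentage); the multi-level GLSZM reports those five averaged over its
quantization depths.

Undefined values (zero variance, zero marginal spread) are reported as
NaN sentinels, never silently zero-filled; downstream classification
drops affected rows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage import measure
from scipy import ndimage

from .errors import EmptyMaskError
from .matrices import (
    DEFAULT_MGLSZM_LEVELS,
    DEFAULT_OFFSETS,
    CooccurrenceMatrix,
    MultiZoneMatrix,
    RunLengthMatrix,
    SizeZoneMatrix,
    glcm,
    glrlm,
    glszm,
    mglszm,
)
from .quantize import QuantizedROI, quantize

__all__ = [
    "Family",
    "FeatureConfig",
    "FamilyFeatureSet",
    "first_order",
    "shape_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "mglszm_features",
    "family_features",
    "UNDEFINED",
]

#: Sentinel for a feature that is mathematically undefined on this input.
UNDEFINED = float("nan")


class Family(str, Enum):
    FIRST_ORDER = "first_order"
    SHAPE = "shape"
    GLCM = "glcm"
    GLRLM = "glrlm"
    GLSZM = "glszm"
    MGLSZM = "mglszm"
    ALL = "all"


def first_order(roi: QuantizedROI) -> Dict[str, float]:
    """Mean, dispersion, skewness and excess kurtosis of the raw intensities."""
    y = roi.raw_values
    m = y.size
    mean = float(y.mean())
    var = float(((y - mean) ** 2).mean())  # population variance
    # roundoff floor: a numerically constant region must hit the sentinel
    if var <= (1e-12 * max(1.0, abs(mean))) ** 2:
        var = 0.0
    out = {"j_mean": mean, "j_variance": var, "j_std": math.sqrt(var)}
    if var > 0:
        m2 = var
        m3 = float(((y - mean) ** 3).mean())
        m4 = float(((y - mean) ** 4).mean())
        out["j_skewness"] = m3 / m2**1.5
        out["j_kurtosis"] = m4 / m2**2 - 3.0
    else:
        out["j_skewness"] = UNDEFINED
        out["j_kurtosis"] = UNDEFINED
    return out


def shape_features(mask: np.ndarray) -> Dict[str, float]:
    """Area, perimeter, circularity, elongation and form factor of a mask.

    Multi-component masks are reduced to the largest connected component
    (with a warning); an empty mask raises.  The perimeter is the
    standard digital boundary-length estimate of the pixelated contour,
    which slightly exceeds the ideal smooth-contour length, so the
    circularity of a rasterized disc lands just below 1.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptyMaskError("shape features need a nonempty mask")
    labeled, n = ndimage.label(mask)
    if n > 1:
        warnings.warn(
            f"mask has {n} connected components; shape features use the largest",
            stacklevel=2,
        )
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, np.arange(1, n + 1))
        mask = labeled == (int(np.argmax(sizes)) + 1)

    props = measure.regionprops(mask.astype(np.uint8))[0]
    area = float(mask.sum())
    perimeter = float(props.perimeter)
    circularity = 4.0 * math.pi * area / perimeter**2 if perimeter > 0 else UNDEFINED
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    elongation = minor / major if major > 0 else UNDEFINED
    form = perimeter * elongation / (8.0 * area) if not math.isnan(elongation) else UNDEFINED
    return {
        "s_area": area,
        "s_perimeter": perimeter,
        "s_circularity": circularity,
        "s_elongation": elongation,
        "s_form": form,
    }


def glcm_features(M: CooccurrenceMatrix, log_base: float = 2.0) -> Dict[str, float]:
    """Contrast, correlation and entropy of a normalized co-occurrence table."""
    P = M.P
    L = M.levels
    j = np.arange(1, L + 1, dtype=np.float64)
    jj, kk = np.meshgrid(j, j, indexing="ij")
    contrast = float(np.sum((jj - kk) ** 2 * P))
    lam = M.std_y * M.std_z
    if lam > 0:
        correlation = float((np.sum(jj * kk * P) - M.mean_y * M.mean_z) / lam)
    else:
        correlation = UNDEFINED
    nz = P[P > 0]
    entropy = float(-np.sum(nz * np.log(nz) / math.log(log_base)))
    return {"t_contrast": contrast, "t_correlation": correlation, "t_entropy": entropy}


def glrlm_features(R: RunLengthMatrix, m: int) -> Dict[str, float]:
    """Five classical run-length summaries, normalized by the run count.

    SRE = sum R(j,r)/r^2 / Nr          (short-run emphasis)
    LRE = sum R(j,r) r^2 / Nr          (long-run emphasis)
    GLN = sum_j (sum_r R)^2 / Nr       (gray-level nonuniformity)
    RLN = sum_r (sum_j R)^2 / Nr       (run-length nonuniformity)
    RP  = Nr / (m * n_directions)      (run percentage)
    """
    counts = R.counts.astype(np.float64)
    nr = counts.sum()
    r = np.arange(1, R.max_run_length + 1, dtype=np.float64)
    return {
        "rl_short_run_emphasis": float(np.sum(counts / r**2) / nr),
        "rl_long_run_emphasis": float(np.sum(counts * r**2) / nr),
        "rl_gray_level_nonuniformity": float(np.sum(counts.sum(axis=1) ** 2) / nr),
        "rl_run_length_nonuniformity": float(np.sum(counts.sum(axis=0) ** 2) / nr),
        "rl_run_percentage": float(nr / (m * len(R.directions))),
    }


def glszm_features(Z: SizeZoneMatrix, m: int, prefix: str = "sz") -> Dict[str, float]:
    """Five classical size-zone summaries, normalized by the zone count."""
    counts = Z.counts.astype(np.float64)
    nz = counts.sum()
    s = np.arange(1, Z.max_zone_size + 1, dtype=np.float64)
    return {
        f"{prefix}_small_zone_emphasis": float(np.sum(counts / s**2) / nz),
        f"{prefix}_large_zone_emphasis": float(np.sum(counts * s**2) / nz),
        f"{prefix}_gray_level_nonuniformity": float(np.sum(counts.sum(axis=1) ** 2) / nz),
        f"{prefix}_zone_size_nonuniformity": float(np.sum(counts.sum(axis=0) ** 2) / nz),
        f"{prefix}_zone_percentage": float(nz / m),
    }


def mglszm_features(MZ: MultiZoneMatrix, m: int) -> Dict[str, float]:
    """Size-zone summaries averaged across the quantization level set."""
    acc: Dict[str, List[float]] = {}
    for L in MZ.level_set:
        feats = glszm_features(MZ.members[L], m, prefix="msz")
        for name, value in feats.items():
            acc.setdefault(name, []).append(value)
    return {name: float(np.mean(vals)) for name, vals in acc.items()}


@dataclass(frozen=True)
class FeatureConfig:
    """Which families to compute and with what construction parameters."""

    levels: int = 16
    families: Tuple[Family, ...] = (
        Family.FIRST_ORDER,
        Family.SHAPE,
        Family.GLCM,
        Family.GLRLM,
        Family.GLSZM,
        Family.MGLSZM,
    )
    offsets: Tuple[Tuple[int, int], ...] = DEFAULT_OFFSETS
    symmetric: bool = True
    connectivity: int = 8
    mglszm_levels: Tuple[int, ...] = DEFAULT_MGLSZM_LEVELS
    log_base: float = 2.0
    #: When False, ALL concatenates only the texture families (GLCM,
    #: GLRLM, GLSZM, MGLSZM), excluding first-order and shape.
    all_includes_nontexture: bool = True


@dataclass(frozen=True)
class FamilyFeatureSet:
    """Named feature values grouped by family, plus their concatenation."""

    families: Dict[Family, Dict[str, float]]
    config: FeatureConfig

    @property
    def all_features(self) -> Dict[str, float]:
        """The ALL vector: concatenation of the enabled families."""
        out: Dict[str, float] = {}
        for fam, feats in self.families.items():
            if not self.config.all_includes_nontexture and fam in (
                Family.FIRST_ORDER,
                Family.SHAPE,
            ):
                continue
            out.update(feats)
        return out

    def vector(self, family: Family) -> Dict[str, float]:
        if family == Family.ALL:
            return self.all_features
        return self.families[family]


def family_features(
    image: np.ndarray, mask: np.ndarray, config: FeatureConfig = FeatureConfig()
) -> FamilyFeatureSet:
    """Compute every enabled feature family for one image/mask pair.

    Deterministic given the config.  A family whose features are all
    undefined is dropped with a warning.
    """
    roi = quantize(image, mask, config.levels)
    computed: Dict[Family, Dict[str, float]] = {}
    for fam in config.families:
        if fam == Family.FIRST_ORDER:
            feats = first_order(roi)
        elif fam == Family.SHAPE:
            feats = shape_features(mask)
        elif fam == Family.GLCM:
            M = glcm(roi, offsets=config.offsets, symmetric=config.symmetric)
            feats = glcm_features(M, log_base=config.log_base)
        elif fam == Family.GLRLM:
            feats = glrlm_features(glrlm(roi, directions=config.offsets), roi.m)
        elif fam == Family.GLSZM:
            feats = glszm_features(glszm(roi, connectivity=config.connectivity), roi.m)
        elif fam == Family.MGLSZM:
            mz = mglszm(image, mask, level_set=config.mglszm_levels, connectivity=config.connectivity)
            feats = mglszm_features(mz, roi.m)
        else:
            continue
        if all(math.isnan(v) for v in feats.values()):
            warnings.warn(f"family {fam.value} is entirely undefined; dropped", stacklevel=2)
            continue
        computed[fam] = feats
    return FamilyFeatureSet(families=computed, config=config)


def cohort_feature_table(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    config: FeatureConfig = FeatureConfig(),
):
    """Feature matrix for a cohort: one DataFrame row per sample.

    Columns are feature names; a ``families`` attribute mapping family ->
    column list is attached via the DataFrame ``attrs``.
    """
    import pandas as pd

    rows = []
    fam_columns: Dict[str, List[str]] = {}
    for image, mask in zip(images, masks):
        fs = family_features(image, mask, config)
        row: Dict[str, float] = {}
        for fam, feats in fs.families.items():
            row.update(feats)
            fam_columns.setdefault(fam.value, list(feats))
        fam_columns.setdefault(Family.ALL.value, list(fs.all_features))
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["families"] = fam_columns
    return df
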