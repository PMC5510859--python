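"""Histogram, size-zone and co-occurrence texture features of an ADC map.

Three tiers of tumor-heterogeneity descriptors are extracted from the ADC
values inside a 3D region of interest:

* **global** — the first four moments of the raw (unquantized) ADC
  histogram: mean, sample SD, skewness and non-excess kurtosis;
* **regional** — intensity variability and size-zone variability from the
  grey-level size-zone matrix (GLSZM) of the 64-level quantized map;
* **local** — seven Haralick features (energy, entropy, correlation,
  contrast, homogeneity, variance, maximum probability) from a
  rotation-invariant grey-level co-occurrence matrix (GLCM) averaged over
  the 13 unique 3D directions at 1-voxel distance.

Quantization is equal-width binning of the per-ROI min-max range into L
levels (default 64, levels 1..L), the dominant radiomics convention for a
stated fixed level count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .adc import AdcMap, RoiMask, tumor_volume

__all__ = [
    "QuantizedRoi",
    "Glcm",
    "Glszm",
    "FeatureVector",
    "global_features",
    "quantize",
    "compute_glcm",
    "compute_glszm",
    "glcm_features",
    "glszm_features",
    "extract_features",
    "GLCM_OFFSETS",
    "FEATURE_NAMES",
]

#: The 13 unique 3D offsets: the 26-neighbourhood modulo sign.
GLCM_OFFSETS: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

#: Canonical feature order: 4 global, 2 regional, 7 local.
FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "sd",
    "skewness",
    "kurtosis",
    "intensity_variability",
    "size_zone_variability",
    "energy",
    "entropy",
    "correlation",
    "contrast",
    "homogeneity",
    "variance",
    "max_probability",
)


@dataclass(frozen=True)
class QuantizedRoi:
    """ROI voxels resampled to integer grey levels 1..L on the 3D grid.

    ``levels`` is 0 outside the ROI (no level) and in 1..L inside.
    """

    levels: np.ndarray
    n_levels: int
    adc_min: float
    adc_max: float

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if lv.ndim != 3:
            raise ValueError("levels grid must be 3D")
        inside = lv[lv > 0]
        if inside.size == 0:
            raise ValueError("quantized ROI is empty")
        if inside.max() > self.n_levels:
            raise ValueError("level exceeds L")
        object.__setattr__(self, "levels", lv.astype(np.int32))

    @property
    def roi_mask(self) -> np.ndarray:
        return self.levels > 0


@dataclass(frozen=True)
class Glcm:
    """Rotation-invariant co-occurrence probability matrix (L x L)."""

    p: np.ndarray
    direction_count: int = 13
    distance: int = 1

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("GLCM must be square")
        if np.any(p < 0):
            raise ValueError("GLCM entries must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("GLCM must sum to 1")
        if not np.allclose(p, p.T, atol=1e-12):
            raise ValueError("GLCM must be symmetric")
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class Glszm:
    """Zone-count matrix: rows grey level 1..L, columns zone size 1..max."""

    M: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.M)
        if M.ndim != 2:
            raise ValueError("GLSZM must be 2D")
        if np.any(M < 0):
            raise ValueError("zone counts must be non-negative")
        object.__setattr__(self, "M", M.astype(np.int64))

    @property
    def n_zones(self) -> int:
        return int(self.M.sum())


@dataclass(frozen=True)
class FeatureVector:
    """The 13 named texture features plus tumor volume for one subject."""

    mean: float
    sd: float
    skewness: float
    kurtosis: float
    intensity_variability: float
    size_zone_variability: float
    energy: float
    entropy: float
    correlation: float
    contrast: float
    homogeneity: float
    variance: float
    max_probability: float
    volume_cm3: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES} | {
            "volume_cm3": self.volume_cm3
        }


def _roi_values(adc: AdcMap, mask: RoiMask) -> np.ndarray:
    if adc.values.shape != mask.mask.shape:
        raise ValueError("ADC map and mask grids differ")
    vals = adc.values[mask.mask]
    return vals[np.isfinite(vals)]


def global_features(adc: AdcMap, mask: RoiMask) -> tuple[float, float, float, float]:
    """Histogram moments of the raw in-ROI ADC values.

    Returns ``(mean, sd, skewness, kurtosis)`` with sample SD (n-1 in the
    denominator), skewness ``m3 / m2^1.5`` and non-excess kurtosis
    ``m4 / m2^2`` from population central moments (Gaussian -> 3).
    Skewness and kurtosis are NaN for a constant ROI.
    """
    x = _roi_values(adc, mask)
    if x.size < 2:
        raise ValueError("need at least 2 defined ROI voxels")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    d = x - mean
    m2 = float(np.mean(d**2))
    if m2 == 0.0:
        return mean, sd, math.nan, math.nan
    skew = float(np.mean(d**3)) / m2**1.5
    kurt = float(np.mean(d**4)) / m2**2
    return mean, sd, skew, kurt


def quantize(adc: AdcMap, mask: RoiMask, n_levels: int = 64) -> QuantizedRoi:
    """Resample in-ROI ADC values to integer levels 1..L by equal-width bins.

    ``level = 1 + floor(L * (x - min) / (max - min))`` with ``x == max``
    clamped to level L; a constant ROI maps everything to level 1.
    Undefined (NaN) ADC voxels are dropped from the ROI.
    """
    if adc.values.shape != mask.mask.shape:
        raise ValueError("ADC map and mask grids differ")
    roi = mask.mask & np.isfinite(adc.values)
    if not roi.any():
        raise ValueError("no defined ROI voxels to quantize")
    x = adc.values[roi]
    lo, hi = float(x.min()), float(x.max())
    levels = np.zeros(adc.values.shape, dtype=np.int32)
    if hi == lo:
        levels[roi] = 1
    else:
        lv = 1 + np.floor(n_levels * (x - lo) / (hi - lo)).astype(np.int32)
        np.clip(lv, 1, n_levels, out=lv)
        levels[roi] = lv
    return QuantizedRoi(levels=levels, n_levels=n_levels, adc_min=lo, adc_max=hi)


def compute_glcm(q: QuantizedRoi) -> Glcm:
    """Symmetric GLCM averaged over the 13 unique directions at distance 1.

    Per direction: count ordered level pairs whose both voxels lie in the
    ROI, add the transpose, normalize to sum 1; directions with no valid
    pair are skipped and the average renormalized over those kept.
    """
    L = q.n_levels
    lv = q.levels
    avg = np.zeros((L, L), dtype=float)
    kept = 0
    for off in GLCM_OFFSETS:
        a, b = _shifted_pairs(lv, off)
        if a.size == 0:
            continue
        counts = np.bincount((a - 1) * L + (b - 1), minlength=L * L).reshape(L, L)
        counts = counts + counts.T
        avg += counts / counts.sum()
        kept += 1
    if kept == 0:
        raise ValueError("no co-occurring ROI voxel pair in any direction")
    return Glcm(p=avg / kept, direction_count=kept, distance=1)


def _shifted_pairs(levels: np.ndarray, off: tuple[int, int, int]):
    """Ordered (a, b) level pairs at offset `off` with both voxels in ROI."""
    sl_a, sl_b = [], []
    for d, n in zip(off, levels.shape):
        if abs(d) >= n:
            return np.empty(0, np.int32), np.empty(0, np.int32)
        if d > 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        elif d < 0:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
        else:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
    a = levels[tuple(sl_a)]
    b = levels[tuple(sl_b)]
    ok = (a > 0) & (b > 0)
    return a[ok], b[ok]


def compute_glszm(q: QuantizedRoi, connectivity: int = 26) -> Glszm:
    """Zone counts of maximal equal-level connected components in the ROI.

    Parameters
    ----------
    connectivity
        6 (faces) or 26 (faces+edges+corners); 26 is the radiomics default.
    """
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    lv = q.levels
    n_vox = int((lv > 0).sum())
    counts: dict[tuple[int, int], int] = {}
    max_size = 1
    for level in np.unique(lv[lv > 0]):
        labeled, n_comp = ndimage.label(lv == level, structure=structure)
        if n_comp == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            s = int(s)
            counts[(int(level), s)] = counts.get((int(level), s), 0) + 1
            max_size = max(max_size, s)
    M = np.zeros((q.n_levels, max_size), dtype=np.int64)
    for (m, n), c in counts.items():
        M[m - 1, n - 1] = c
    z = Glszm(M=M)
    assert int((np.arange(1, max_size + 1) * M).sum()) == n_vox
    return z


def glszm_features(z: Glszm) -> tuple[float, float]:
    """Intensity variability and size-zone variability of a GLSZM.

    ``IV = (1/NZ) * sum_m (sum_n M(m,n))^2`` — large when zones concentrate
    in few grey levels; ``SZV = (1/NZ) * sum_n (sum_m M(m,n))^2`` — large
    when zones concentrate in few sizes (many single-voxel zones).
    """
    nz = z.n_zones
    if nz < 1:
        raise ValueError("GLSZM has no zones")
    row = z.M.sum(axis=1).astype(float)
    col = z.M.sum(axis=0).astype(float)
    return float((row**2).sum() / nz), float((col**2).sum() / nz)


def glcm_features(
    g: Glcm,
) -> tuple[float, float, float, float, float, float, float]:
    """The seven Haralick features of a symmetric GLCM.

    Returns ``(energy, entropy, correlation, contrast, homogeneity,
    variance, max_probability)``.  With marginal ``px(i) = sum_j p(i,j)``,
    ``mu = sum_i i*px(i)`` and ``s2 = sum_i (i-mu)^2 px(i)``:

    * energy         ``sum p^2``
    * entropy        ``-sum p ln p`` (0 ln 0 := 0, natural log)
    * correlation    ``(sum_ij i*j*p - mu^2) / s2``   (NaN if s2 == 0)
    * contrast       ``sum (i-j)^2 p``
    * homogeneity    ``sum p / (1 + |i-j|)``
    * variance       ``sum_ij (i-mu)^2 p``
    * max_probability ``max p``
    """
    p = g.p
    L = p.shape[0]
    i = np.arange(1, L + 1, dtype=float)
    px = p.sum(axis=1)
    mu = float(i @ px)
    s2 = float(((i - mu) ** 2) @ px)

    energy = float((p**2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    ii, jj = np.meshgrid(i, i, indexing="ij")
    if s2 == 0.0:
        correlation = math.nan
    else:
        correlation = (float((ii * jj * p).sum()) - mu * mu) / s2
    contrast = float((((ii - jj) ** 2) * p).sum())
    homogeneity = float((p / (1.0 + np.abs(ii - jj))).sum())
    variance = float((((ii - mu) ** 2) * p).sum())
    max_probability = float(p.max())
    return energy, entropy, correlation, contrast, homogeneity, variance, max_probability


def extract_features(
    adc: AdcMap,
    mask: RoiMask,
    n_levels: int = 64,
    connectivity: int = 26,
) -> FeatureVector:
    """Full per-subject feature vector: 4 global + 2 regional + 7 local + volume.

    Global moments use the raw ADC values; regional and local features use
    the L-level quantized map.
    """
    mean, sd, skew, kurt = global_features(adc, mask)
    q = quantize(adc, mask, n_levels=n_levels)
    iv, szv = glszm_features(compute_glszm(q, connectivity=connectivity))
    en, ent, corr, con, hom, var, mp = glcm_features(compute_glcm(q))
    return FeatureVector(
        mean=mean,
        sd=sd,
        skewness=skew,
        kurtosis=kurt,
        intensity_variability=iv,
        size_zone_variability=szv,
        energy=en,
        entropy=ent,
        correlation=corr,
        contrast=con,
        homogeneity=hom,
        variance=var,
        max_probability=mp,
        volume_cm3=tumor_volume(mask),
    )
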