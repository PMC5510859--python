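"""ADC-map estimation from multi-b-value diffusion-weighted MRI.

The apparent diffusion coefficient (ADC, mm^2/s) is the decay rate of the
DWI signal with diffusion weighting b (s/mm^2) under the mono-exponential
model ``S(b) = S0 * exp(-b * ADC)``.  With three b-values (here 0, 400,
800 s/mm^2) the voxelwise ADC is estimated as minus the slope of the
ordinary least-squares line of ``ln S(b)`` against ``b``.

Conventions
-----------
* The log-domain fit is unweighted and uses every b-value whose signal is
  strictly positive; voxels with fewer than two usable points are flagged
  undefined (NaN) rather than raising.
* Negative fitted slopes would yield a negative diffusivity; the fitted
  ADC is clamped at zero (noise can make signal rise with b).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "DwiSeries",
    "AdcMap",
    "RoiMask",
    "fit_adc",
    "tumor_volume",
    "load_dwi_series",
    "load_mask",
    "save_volume",
]

#: Upper physical bound for diffusivity of free water at body temperature.
ADC_WATER_BOUND = 4.0e-3


@dataclass(frozen=True)
class DwiSeries:
    """Stack of co-registered 3D signal volumes indexed by b-value.

    Parameters
    ----------
    b_values
        Diffusion weightings in s/mm^2; at least two distinct values.
    volumes
        4D array, shape ``(n_b,) + grid_shape``, non-negative signals.
    voxel_spacing_mm
        Physical spacing per axis (mm).
    """

    b_values: tuple[float, ...]
    volumes: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.size < 2 or np.unique(b).size < 2:
            raise ValueError("need at least two distinct b-values")
        vols = np.asarray(self.volumes, dtype=float)
        if vols.ndim != 4 or vols.shape[0] != b.size:
            raise ValueError(
                f"volumes must be (n_b, nx, ny, nz); got {vols.shape} "
                f"for {b.size} b-values"
            )
        if np.any(vols < 0):
            raise ValueError("DWI signals must be non-negative")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        object.__setattr__(self, "b_values", tuple(float(x) for x in b))
        object.__setattr__(self, "volumes", vols)
        object.__setattr__(
            self, "voxel_spacing_mm", tuple(float(s) for s in self.voxel_spacing_mm)
        )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[1:]


@dataclass(frozen=True)
class AdcMap:
    """Voxelwise diffusion-coefficient map in mm^2/s (NaN where undefined)."""

    values: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("ADC map must be 3D")
        defined = v[np.isfinite(v)]
        if defined.size and np.any(defined < 0):
            raise ValueError("defined ADC values must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(
            self, "voxel_spacing_mm", tuple(float(s) for s in self.voxel_spacing_mm)
        )


@dataclass(frozen=True)
class RoiMask:
    """Binary tumor mask on the same grid as the series it belongs to."""

    mask: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 3:
            raise ValueError("ROI mask must be 3D")
        if not m.any():
            raise ValueError("ROI mask contains no voxels")
        object.__setattr__(self, "mask", m)
        object.__setattr__(
            self, "voxel_spacing_mm", tuple(float(s) for s in self.voxel_spacing_mm)
        )

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def fit_adc(series: DwiSeries) -> AdcMap:
    """Fit the voxelwise ADC by log-linear least squares over all b-values.

    Per voxel, ADC = -slope of the OLS line of ``ln S(b)`` versus ``b``,
    restricted to b-values with ``S(b) > 0``.  Voxels with fewer than two
    positive signals are set to NaN; negative slopes clamp to ADC = 0.

    Returns
    -------
    AdcMap
        Same grid and spacing as the input series.
    """
    b = np.asarray(series.b_values, dtype=float)
    signals = series.volumes  # (n_b, nx, ny, nz)
    pos = signals > 0
    n_used = pos.sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(pos, np.log(np.where(pos, signals, 1.0)), 0.0)

    # Weighted (0/1) least-squares slope computed per voxel in closed form:
    # slope = (n*S_by - S_b*S_y) / (n*S_bb - S_b^2) over usable points.
    bcol = b.reshape(-1, 1, 1, 1)
    s_b = np.sum(np.where(pos, bcol, 0.0), axis=0)
    s_bb = np.sum(np.where(pos, bcol**2, 0.0), axis=0)
    s_y = logs.sum(axis=0)
    s_by = np.sum(bcol * logs, axis=0)

    denom = n_used * s_bb - s_b**2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (n_used * s_by - s_b * s_y) / denom

    adc = -slope
    # fewer than 2 usable points, or all usable points share one b: undefined
    undefined = (n_used < 2) | (denom <= 0)
    adc = np.where(undefined, np.nan, adc)
    adc = np.where(np.isfinite(adc) & (adc < 0), 0.0, adc)
    return AdcMap(values=adc.astype(float), voxel_spacing_mm=series.voxel_spacing_mm)


def tumor_volume(mask: RoiMask) -> float:
    """Tumor volume in cm^3: voxel count times unit voxel volume."""
    voxel_mm3 = float(np.prod(mask.voxel_spacing_mm))
    return mask.n_voxels * voxel_mm3 / 1000.0


# ---------------------------------------------------------------------------
# NIfTI I/O


def _spacing_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(
    data: np.ndarray, spacing: tuple[float, float, float], path: str | Path
) -> None:
    """Write a 3D volume as NIfTI with a diagonal spacing affine."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _spacing_affine(spacing))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def _load(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def load_dwi_series(paths: dict[float, str | Path]) -> DwiSeries:
    """Load one NIfTI volume per b-value into a :class:`DwiSeries`."""
    b_values = sorted(paths)
    vols, spacing = [], None
    for b in b_values:
        data, sp = _load(paths[b])
        if spacing is None:
            spacing = sp
        elif not np.allclose(sp, spacing, rtol=1e-4):
            raise ValueError(f"voxel spacing mismatch at b={b}: {sp} vs {spacing}")
        vols.append(data)
    return DwiSeries(
        b_values=tuple(b_values), volumes=np.stack(vols), voxel_spacing_mm=spacing
    )


def load_mask(path: str | Path) -> RoiMask:
    data, spacing = _load(path)
    return RoiMask(mask=data > 0.5, voxel_spacing_mm=spacing)


def load_adc(path: str | Path) -> AdcMap:
    data, spacing = _load(path)
    return AdcMap(values=data, voxel_spacing_mm=spacing)
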