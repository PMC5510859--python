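"""Synthetic DWI phantoms of myxoid-containing soft-tissue tumors.

Generates ellipsoidal tumor phantoms with a known voxelwise ADC field and
Rician-noised DWI signal volumes at b = 0/400/800 s/mm^2, plus cohort-level
covariates, so that the full ADC -> texture -> statistics pipeline can be
exercised without patient data.

Tumor classes
-------------
benign-like
    Concentric two-compartment ADC: a low-diffusivity core (fibrous
    center) inside ``core_fraction`` of the ellipsoid radius, surrounded by
    a high-diffusivity myxoid rim, mimicking the histology of neurogenic
    tumors.  The spatial jitter is short-range (grainy), so the ADC map is
    spatially heterogeneous.
malignant-like
    A single uniform ADC compartment (abundant, uniform myxoid matrix)
    with long-range smooth jitter: a spatially homogeneous ADC map.

Signal model
------------
Per b-value, the noise-free magnitude is ``S0 * exp(-b * ADC)``; the
observed magnitude is Rician, ``sqrt((A + n1)^2 + n2^2)`` with
``n1, n2 ~ N(0, S0/SNR)`` drawn independently per b-value volume.  At
``snr = inf`` the noise-free magnitude is returned exactly.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .adc import ADC_WATER_BOUND, AdcMap, DwiSeries, RoiMask, save_volume

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "SubjectRecord",
    "benign_template",
    "malignant_template",
    "default_cohort_spec",
    "make_phantom",
    "make_cohort",
    "write_cohort",
]

#: ADC assigned outside the tumor (muscle-like background), mm^2/s.
BACKGROUND_ADC = 1.5e-3

#: b-values of the emulated acquisition, s/mm^2.
DEFAULT_B_VALUES = (0.0, 400.0, 800.0)

#: Acquisition geometry emulated by default: 350 mm FOV / 256 matrix,
#: 5 mm sections.
DEFAULT_SPACING = (1.37, 1.37, 5.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to synthesize one tumor phantom.

    Parameters
    ----------
    grid_shape
        Voxel counts per axis.
    voxel_spacing_mm
        Physical spacing per axis, mm.
    tumor_class
        ``"benign-like"`` (core/rim) or ``"malignant-like"`` (uniform).
    tumor_semiaxes_mm
        Ellipsoid semi-axes, mm; the ellipsoid is centred in the grid.
    core_fraction
        Fraction of the ellipsoid radius occupied by the low-ADC core
        (benign-like only), in [0, 1].
    adc_core, adc_rim, adc_uniform
        Compartment diffusivities, mm^2/s; must lie in (0, 4e-3).
    adc_jitter_sd
        SD of the spatial ADC fluctuation field, mm^2/s.
    jitter_correlation_mm
        Gaussian correlation length of the jitter field; 0 means white
        (voxelwise independent) jitter.
    s0_signal
        Baseline (b = 0) noise-free magnitude.
    snr
        Ratio of ``s0_signal`` to the Gaussian noise SD of each quadrature
        channel; ``math.inf`` disables noise.
    seed
        RNG seed; identical spec + seed gives identical output.
    """

    grid_shape: tuple[int, int, int]
    voxel_spacing_mm: tuple[float, float, float] = DEFAULT_SPACING
    tumor_class: str = "malignant-like"
    tumor_semiaxes_mm: tuple[float, float, float] = (20.0, 16.0, 14.0)
    core_fraction: float = 0.0
    adc_core: float = 1.2e-3
    adc_rim: float = 2.6e-3
    adc_uniform: float = 1.914e-3
    adc_jitter_sd: float = 0.0
    jitter_correlation_mm: float = 0.0
    s0_signal: float = 1000.0
    snr: float = math.inf
    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_class not in ("benign-like", "malignant-like"):
            raise ValueError(f"unknown tumor_class {self.tumor_class!r}")
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be strictly positive")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if any(a <= 0 for a in self.tumor_semiaxes_mm):
            raise ValueError("semi-axes must be positive")
        for name in ("adc_core", "adc_rim", "adc_uniform"):
            v = getattr(self, name)
            if not 0.0 < v < ADC_WATER_BOUND:
                raise ValueError(
                    f"{name}={v} outside the physical range (0, {ADC_WATER_BOUND})"
                )
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ValueError("core_fraction must lie in [0, 1]")
        if self.adc_jitter_sd < 0:
            raise ValueError("adc_jitter_sd must be >= 0")
        if not self.snr > 0:
            raise ValueError("snr must be positive")


@dataclass(frozen=True)
class ClassTemplate:
    """Per-class phantom parameters; geometry and seed are set per subject."""

    tumor_class: str
    core_fraction: float = 0.0
    adc_core: float = 1.2e-3
    adc_rim: float = 2.6e-3
    adc_uniform: float = 1.914e-3
    adc_jitter_sd: float = 0.3e-3
    jitter_correlation_mm: float = 0.0
    s0_signal: float = 1000.0
    snr: float = 100.0


def benign_template() -> ClassTemplate:
    """Heterogeneous phantom: fibrous-center core, myxoid rim, grainy jitter."""
    return ClassTemplate(
        tumor_class="benign-like",
        core_fraction=0.7,
        adc_core=1.2e-3,
        adc_rim=2.6e-3,
        adc_jitter_sd=0.3e-3,
        jitter_correlation_mm=0.0,
    )


def malignant_template() -> ClassTemplate:
    """Homogeneous phantom: uniform myxoid ADC with long-range smooth jitter."""
    return ClassTemplate(
        tumor_class="malignant-like",
        adc_uniform=1.914e-3,
        adc_jitter_sd=0.3e-3,
        jitter_correlation_mm=8.0,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level sampling parameters for the two tumor groups.

    Ages are normal truncated at 18 years; sex is Bernoulli on the female
    fraction; tumor volumes (cm^3) are log-normal, moment-matched to the
    requested mean/SD (their SDs approach or exceed the means, which a
    normal law on positive support cannot produce).  Volumes are converted
    to ellipsoid semi-axes with fixed axis ratios.
    """

    n_benign: int = 23
    n_malignant: int = 17
    age_mean_benign: float = 53.0
    age_sd_benign: float = 12.7
    age_mean_malignant: float = 60.8
    age_sd_malignant: float = 13.4
    sex_female_frac_benign: float = 12 / 23
    sex_female_frac_malignant: float = 6 / 17
    volume_mean_benign: float = 15.630
    volume_sd_benign: float = 14.803
    volume_mean_malignant: float = 139.355
    volume_sd_malignant: float = 179.174
    benign: ClassTemplate = field(default_factory=benign_template)
    malignant: ClassTemplate = field(default_factory=malignant_template)
    axis_ratios: tuple[float, float, float] = (1.0, 0.8, 0.7)
    voxel_spacing_mm: tuple[float, float, float] = DEFAULT_SPACING
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_benign < 1 or self.n_malignant < 1:
            raise ValueError("group counts must be >= 1")
        for name in (
            "volume_mean_benign",
            "volume_sd_benign",
            "volume_mean_malignant",
            "volume_sd_malignant",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not all(0 <= f <= 1 for f in
                   (self.sex_female_frac_benign, self.sex_female_frac_malignant)):
            raise ValueError("female fractions must lie in [0, 1]")


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The 40-subject study cohort: 23 benign-like, 17 malignant-like."""
    return CohortSpec(seed=seed)


@dataclass(frozen=True)
class SubjectRecord:
    """One simulated subject with imaging and covariates."""

    subject_id: str
    group: str  # "benign" | "malignant"
    age: float
    sex: str  # "F" | "M"
    series: DwiSeries
    mask: RoiMask
    true_adc: AdcMap
    seed: int


# ---------------------------------------------------------------------------
# Single-phantom synthesis


def _ellipsoid_radius(spec: PhantomSpec) -> np.ndarray:
    """Normalized ellipsoidal radius (<= 1 inside the tumor) per voxel."""
    shape = spec.grid_shape
    center = [(n - 1) / 2.0 for n in shape]
    r2 = np.zeros(shape, dtype=float)
    for ax, (n, c, sp, a) in enumerate(
        zip(shape, center, spec.voxel_spacing_mm, spec.tumor_semiaxes_mm)
    ):
        coord = (np.arange(n) - c) * sp / a
        r2 = r2 + (coord.reshape([-1 if i == ax else 1 for i in range(3)])) ** 2
    return np.sqrt(r2)


def _check_fits(spec: PhantomSpec) -> None:
    axes = "xyz"
    for ax in range(3):
        half_extent = spec.grid_shape[ax] * spec.voxel_spacing_mm[ax] / 2.0
        if spec.tumor_semiaxes_mm[ax] >= half_extent:
            raise ValueError(
                f"ellipsoid semi-axis {spec.tumor_semiaxes_mm[ax]:g} mm exceeds "
                f"half the grid extent ({half_extent:g} mm) along axis "
                f"{axes[ax]!r}"
            )


def _jitter_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.adc_jitter_sd == 0.0:
        return np.zeros(spec.grid_shape)
    white = rng.standard_normal(spec.grid_shape)
    if spec.jitter_correlation_mm > 0.0:
        sigma_vox = [spec.jitter_correlation_mm / s for s in spec.voxel_spacing_mm]
        fld = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    else:
        fld = white
    sd = fld.std()
    if sd == 0.0:  # degenerate 1-voxel grid
        return np.zeros(spec.grid_shape)
    return fld * (spec.adc_jitter_sd / sd)


def make_phantom(spec: PhantomSpec) -> tuple[DwiSeries, RoiMask, AdcMap]:
    """Synthesize one phantom: DWI series, tumor mask and true ADC field.

    The true ADC is the compartment field plus the spatial jitter, clipped
    to the physical range [0, 4e-3] mm^2/s; signals are Rician samples of
    the mono-exponential decay per b-value.
    """
    _check_fits(spec)
    rng = np.random.default_rng(spec.seed)
    radius = _ellipsoid_radius(spec)
    inside = radius <= 1.0
    if not inside.any():
        raise ValueError("ellipsoid contains no voxel at this resolution")

    adc = np.full(spec.grid_shape, BACKGROUND_ADC, dtype=float)
    if spec.tumor_class == "benign-like":
        adc[inside] = spec.adc_rim
        adc[inside & (radius <= spec.core_fraction)] = spec.adc_core
    else:
        adc[inside] = spec.adc_uniform
    adc = adc + _jitter_field(spec, rng)
    np.clip(adc, 0.0, ADC_WATER_BOUND, out=adc)

    noise_sd = 0.0 if math.isinf(spec.snr) else spec.s0_signal / spec.snr
    vols = []
    for b in spec.b_values:
        clean = spec.s0_signal * np.exp(-b * adc)
        if noise_sd == 0.0:
            vols.append(clean)
        else:
            n1 = rng.normal(0.0, noise_sd, size=spec.grid_shape)
            n2 = rng.normal(0.0, noise_sd, size=spec.grid_shape)
            vols.append(np.sqrt((clean + n1) ** 2 + n2**2))
    series = DwiSeries(
        b_values=spec.b_values,
        volumes=np.stack(vols),
        voxel_spacing_mm=spec.voxel_spacing_mm,
    )
    mask = RoiMask(mask=inside, voxel_spacing_mm=spec.voxel_spacing_mm)
    true_adc = AdcMap(values=adc, voxel_spacing_mm=spec.voxel_spacing_mm)
    return series, mask, true_adc


def rician_sample(
    magnitude: np.ndarray | float, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Rician-distributed magnitudes around a noise-free magnitude."""
    a = np.asarray(magnitude, dtype=float)
    if noise_sd == 0.0:
        return a.copy()
    n1 = rng.normal(0.0, noise_sd, size=a.shape)
    n2 = rng.normal(0.0, noise_sd, size=a.shape)
    return np.sqrt((a + n1) ** 2 + n2**2)


# ---------------------------------------------------------------------------
# Cohort synthesis


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given arithmetic mean and SD."""
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def volume_to_semiaxes(
    volume_cm3: float, axis_ratios: tuple[float, float, float]
) -> tuple[float, float, float]:
    """Ellipsoid semi-axes (mm) of given volume with fixed axis ratios."""
    r1, r2, r3 = axis_ratios
    v_mm3 = volume_cm3 * 1000.0
    a = (3.0 * v_mm3 / (4.0 * math.pi * r1 * r2 * r3)) ** (1.0 / 3.0)
    return (a * r1, a * r2, a * r3)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= lower:
            return float(x)
    return lower  # pathological spec; keep deterministic


def _grid_for(semiaxes: tuple[float, float, float],
              spacing: tuple[float, float, float]) -> tuple[int, int, int]:
    return tuple(int(math.ceil(2.0 * a / s)) + 4 for a, s in zip(semiaxes, spacing))


def make_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a full synthetic cohort; deterministic under the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    groups = [
        (
            "benign",
            spec.n_benign,
            spec.age_mean_benign,
            spec.age_sd_benign,
            spec.sex_female_frac_benign,
            spec.volume_mean_benign,
            spec.volume_sd_benign,
            spec.benign,
        ),
        (
            "malignant",
            spec.n_malignant,
            spec.age_mean_malignant,
            spec.age_sd_malignant,
            spec.sex_female_frac_malignant,
            spec.volume_mean_malignant,
            spec.volume_sd_malignant,
            spec.malignant,
        ),
    ]
    subjects: list[SubjectRecord] = []
    idx = 0
    for (group, n, age_mu, age_sd, female_frac, vol_mean, vol_sd, tmpl) in groups:
        mu, sigma = lognormal_params(vol_mean, vol_sd)
        for _ in range(n):
            idx += 1
            subject_id = f"sub-{idx:03d}"
            age = _truncated_normal(rng, age_mu, age_sd, lower=18.0)
            sex = "F" if rng.random() < female_frac else "M"
            volume = float(rng.lognormal(mu, sigma))
            semiaxes = volume_to_semiaxes(volume, spec.axis_ratios)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            pspec = PhantomSpec(
                grid_shape=_grid_for(semiaxes, spec.voxel_spacing_mm),
                voxel_spacing_mm=spec.voxel_spacing_mm,
                tumor_class=tmpl.tumor_class,
                tumor_semiaxes_mm=semiaxes,
                core_fraction=tmpl.core_fraction,
                adc_core=tmpl.adc_core,
                adc_rim=tmpl.adc_rim,
                adc_uniform=tmpl.adc_uniform,
                adc_jitter_sd=tmpl.adc_jitter_sd,
                jitter_correlation_mm=tmpl.jitter_correlation_mm,
                s0_signal=tmpl.s0_signal,
                snr=tmpl.snr,
                seed=sub_seed,
            )
            series, mask, true_adc = make_phantom(pspec)
            subjects.append(
                SubjectRecord(
                    subject_id=subject_id,
                    group=group,
                    age=age,
                    sex=sex,
                    series=series,
                    mask=mask,
                    true_adc=true_adc,
                    seed=sub_seed,
                )
            )
    return subjects


def write_cohort(subjects: list[SubjectRecord], out_dir: str | Path) -> Path:
    """Write NIfTI volumes per subject plus the cohort covariate CSV.

    Files per subject: ``<id>_b0.nii.gz``, ``<id>_b400.nii.gz``,
    ``<id>_b800.nii.gz``, ``<id>_mask.nii.gz``.  Returns the covariate CSV
    path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cov_path = out / "covariates.csv"
    with open(cov_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "group", "age", "sex", "seed"])
        for sub in subjects:
            spacing = sub.series.voxel_spacing_mm
            for b, vol in zip(sub.series.b_values, sub.series.volumes):
                save_volume(vol, spacing, out / f"{sub.subject_id}_b{int(b)}.nii.gz")
            save_volume(
                sub.mask.mask.astype(np.uint8),
                spacing,
                out / f"{sub.subject_id}_mask.nii.gz",
            )
            writer.writerow(
                [sub.subject_id, sub.group, f"{sub.age:.2f}", sub.sex, sub.seed]
            )
    return cov_path
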