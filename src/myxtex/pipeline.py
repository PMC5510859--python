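"""End-to-end orchestration: cohort in, feature table and statistics out.

The pipeline mirrors the study flow: for every subject, fit the ADC map
from the three-b-value DWI series, compute the four global histogram
moments on the raw ADC values, quantize to 64 levels and compute the
GLSZM and GLCM features, then assemble the cohort table and run the
statistical layer (group comparison, ROC on the covariate-adjusted
significant features, pairwise AUC comparison).

Failures on a single subject are reported in the manifest and skipped;
a cohort run does not die on one degenerate case.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adc import AdcMap, DwiSeries, RoiMask, fit_adc, load_dwi_series, load_mask
from .cohortstats import group_comparison_table, pairwise_auc_table, roc_table
from .phantom import CohortSpec, SubjectRecord, default_cohort_spec, make_cohort
from .texture import (
    FEATURE_NAMES,
    compute_glcm,
    compute_glszm,
    extract_features,
    quantize,
)

__all__ = [
    "RunConfig",
    "RunManifest",
    "subject_features",
    "cohort_feature_table",
    "run_pipeline",
    "render_case_report",
    "ingest_cohort",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    ``mode`` is ``"simulate"`` (synthesize the default 40-subject cohort,
    or the one given by ``cohort_spec``) or ``"ingest"`` (read NIfTI
    volumes and a covariate CSV from ``input_dir``).
    """

    out_dir: str
    mode: str = "simulate"
    input_dir: str | None = None
    cohort_spec: CohortSpec | None = None
    n_levels: int = 64
    connectivity: int = 26
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        if self.mode == "ingest" and not self.input_dir:
            raise ValueError("ingest mode requires input_dir")


@dataclass
class RunManifest:
    """Provenance record of one run: config echo, hashes, timings, failures."""

    config: dict
    version: str
    subjects: dict[str, dict] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    timestamp: str = ""

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _hash_arrays(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def subject_features(
    series: DwiSeries,
    mask: RoiMask,
    n_levels: int = 64,
    connectivity: int = 26,
) -> dict[str, float]:
    """ADC fit + full feature vector for one subject, as a plain dict."""
    adc = fit_adc(series)
    fv = extract_features(adc, mask, n_levels=n_levels, connectivity=connectivity)
    return fv.as_dict()


def cohort_feature_table(
    subjects: list[SubjectRecord],
    n_levels: int = 64,
    connectivity: int = 26,
    manifest: RunManifest | None = None,
) -> pd.DataFrame:
    """Subjects x (covariates + 14 features) table; per-subject failures skipped."""
    rows = []
    for sub in subjects:
        try:
            feats = subject_features(
                sub.series, sub.mask, n_levels=n_levels, connectivity=connectivity
            )
        except Exception as exc:  # noqa: BLE001 - isolation is the contract
            if manifest is not None:
                manifest.failures[sub.subject_id] = f"{type(exc).__name__}: {exc}"
            continue
        row = {
            "subject_id": sub.subject_id,
            "group": sub.group,
            "age": sub.age,
            "sex": sub.sex,
        }
        row.update(feats)
        rows.append(row)
        if manifest is not None:
            manifest.subjects[sub.subject_id] = {
                "input_hash": _hash_arrays(sub.series.volumes, sub.mask.mask),
                "group": sub.group,
            }
    return pd.DataFrame(rows)


def ingest_cohort(input_dir: str | Path) -> list[SubjectRecord]:
    """Load a written cohort (NIfTI volumes + covariates.csv) back into memory."""
    d = Path(input_dir)
    cov = pd.read_csv(d / "covariates.csv")
    subjects = []
    for _, row in cov.iterrows():
        sid = row["subject_id"]
        series = load_dwi_series(
            {b: d / f"{sid}_b{int(b)}.nii.gz" for b in (0, 400, 800)}
        )
        mask = load_mask(d / f"{sid}_mask.nii.gz")
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=row["group"],
                age=float(row["age"]),
                sex=row["sex"],
                series=series,
                mask=mask,
                true_adc=AdcMap(
                    values=np.full(mask.mask.shape, np.nan),
                    voxel_spacing_mm=mask.voxel_spacing_mm,
                ),
                seed=int(row.get("seed", -1)),
            )
        )
    return subjects


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full flow and write all tables under ``config.out_dir``.

    Outputs: ``features.csv`` (subjects x features), ``group_comparison.csv``
    (means, KS, t-test, ANCOVA), ``roc.csv`` and ``pairwise_auc.csv`` for
    the covariate-adjusted significant features, and ``manifest.json``.
    Statistics are skipped with a warning in the manifest when a group has
    fewer than two processed subjects.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    t0 = time.perf_counter()
    if config.mode == "simulate":
        spec = config.cohort_spec or default_cohort_spec(seed=config.seed)
        subjects = make_cohort(spec)
    else:
        subjects = ingest_cohort(config.input_dir)
    manifest.stage_seconds["cohort"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    table = cohort_feature_table(
        subjects,
        n_levels=config.n_levels,
        connectivity=config.connectivity,
        manifest=manifest,
    )
    manifest.stage_seconds["features"] = time.perf_counter() - t0
    table.to_csv(out / "features.csv", index=False)

    counts = table["group"].value_counts() if len(table) else pd.Series(dtype=int)
    if counts.get("benign", 0) < 2 or counts.get("malignant", 0) < 2:
        manifest.failures["__stats__"] = (
            "fewer than 2 subjects per group after feature extraction; "
            "statistics skipped"
        )
    else:
        t0 = time.perf_counter()
        features = list(FEATURE_NAMES)
        comparison = group_comparison_table(table, features)
        comparison.to_csv(out / "group_comparison.csv", index=False)
        significant = comparison.loc[
            comparison["adjusted_p"] < config.alpha, "feature"
        ].tolist()
        roc_features = significant if significant else features
        roc_table(table, roc_features).to_csv(out / "roc.csv", index=False)
        if len(roc_features) >= 2:
            pairwise_auc_table(table, roc_features).to_csv(
                out / "pairwise_auc.csv", index=False
            )
        manifest.stage_seconds["stats"] = time.perf_counter() - t0

    manifest.to_json(out / "manifest.json")
    return manifest


def render_case_report(
    adc: AdcMap,
    mask: RoiMask,
    out_dir: str | Path,
    n_levels: int = 64,
    connectivity: int = 26,
    n_hist_bins: int = 64,
) -> dict[str, Path]:
    """Write the five per-case diagnostic artifacts as CSV files.

    Mirrors the per-case panels: the ADC map slice through the ROI
    centroid (B), the discrete 64-level map slice (C), the in-ROI ADC
    histogram (D), the GLSZM (E) and the averaged GLCM (F).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    zs = np.where(mask.mask.any(axis=(0, 1)))[0]
    z_mid = int(zs[len(zs) // 2])

    q = quantize(adc, mask, n_levels=n_levels)
    paths: dict[str, Path] = {}

    paths["adc_slice"] = out / "panel_b_adc_slice.csv"
    np.savetxt(paths["adc_slice"], adc.values[:, :, z_mid], delimiter=",", fmt="%.6e")

    paths["discrete_slice"] = out / "panel_c_discrete_slice.csv"
    np.savetxt(
        paths["discrete_slice"], q.levels[:, :, z_mid], delimiter=",", fmt="%d"
    )

    vals = adc.values[mask.mask & np.isfinite(adc.values)]
    counts, edges = np.histogram(vals, bins=n_hist_bins)
    paths["histogram"] = out / "panel_d_histogram.csv"
    pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    ).to_csv(paths["histogram"], index=False)

    z = compute_glszm(q, connectivity=connectivity)
    paths["glszm"] = out / "panel_e_glszm.csv"
    np.savetxt(paths["glszm"], z.M, delimiter=",", fmt="%d")

    g = compute_glcm(q)
    paths["glcm"] = out / "panel_f_glcm.csv"
    np.savetxt(paths["glcm"], g.p, delimiter=",", fmt="%.10e")
    return paths
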