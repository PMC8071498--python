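"""End-to-end orchestration: segment -> tint -> measure -> calibrate ->
invert -> aggregate -> classify.

These functions are the library behind the command-line interface.  They
work on pandas DataFrames keyed by the manifest columns (donor_id, sex,
finger, image_path) so the same code path serves synthetic fixtures and
real scanned images.

Per-image failures (unreadable file, no detectable window) are isolated:
the offending row is flagged in an ``error`` column and processing
continues.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import calibration as cal
from . import cohort as coh
from .color import ColorMetrics, measure
from .image_io import (
    WindowNotFoundError,
    read_image,
    rectangle_mask,
    segment_detection_window,
)
from .synthetic import DEFAULT_STANDARD_CONCENTRATIONS, ForwardModel, generate_standard_series, noise_free

__all__ = [
    "SegmentationConfig",
    "measure_window",
    "calibrate_from_images",
    "default_calibration",
    "quantify_manifest",
    "classify_donors",
    "config_fingerprint",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """How to isolate the detection window in an image.

    ``roi`` is an optional explicit rectangle (x, y, width, height) used
    as a fallback when color thresholding finds no window — or instead of
    thresholding when ``force_roi`` is set.
    """

    hue_range: tuple[float, float] = (300.0, 60.0)
    min_saturation: float = 5.0
    min_area_fraction: float = 0.01
    roi: tuple[int, int, int, int] | None = None
    force_roi: bool = False


def measure_window(
    image: np.ndarray, seg: SegmentationConfig = SegmentationConfig(), tint: bool = True
) -> ColorMetrics:
    """Segment the detection window of one image and measure it."""
    if seg.force_roi and seg.roi is not None:
        mask = rectangle_mask(image.shape[:2], *seg.roi)
    else:
        try:
            mask = segment_detection_window(
                image, seg.hue_range, seg.min_saturation, seg.min_area_fraction
            )
        except WindowNotFoundError:
            if seg.roi is None:
                raise
            mask = rectangle_mask(image.shape[:2], *seg.roi)
    return measure(image, mask, tint=tint)


def calibrate_from_images(
    standards: Sequence[tuple[float, np.ndarray]],
    seg: SegmentationConfig = SegmentationConfig(),
) -> cal.CalibrationModel:
    """Fit the standard curve from (concentration µM, image) pairs."""
    metrics = [measure_window(img, seg) for _, img in standards]
    series = cal.series_from_measurements([c for c, _ in standards], metrics)
    return cal.fit_calibration(series)


def default_calibration(
    model: ForwardModel = ForwardModel(),
    concentrations: Sequence[float] = DEFAULT_STANDARD_CONCENTRATIONS,
    seg: SegmentationConfig = SegmentationConfig(),
    seed: int | None = None,
) -> cal.CalibrationModel:
    """Calibration fitted to a noise-free synthetic standard series.

    Useful as the reference curve when quantifying synthetic cohorts: the
    standards are rendered by the same forward model but without pixel
    noise, mirroring a carefully scanned standard series.
    """
    standards = generate_standard_series(noise_free(model), concentrations, seed)
    return calibrate_from_images(standards, seg)


def quantify_manifest(
    manifest: str | Path | pd.DataFrame,
    model: cal.CalibrationModel,
    seg: SegmentationConfig = SegmentationConfig(),
) -> pd.DataFrame:
    """Quantify every image listed in a manifest.

    The manifest is a CSV (or DataFrame) with at least ``image_path``;
    ``donor_id``, ``sex`` and ``finger`` columns are carried through when
    present.  Relative image paths are resolved against the manifest's
    directory.  Output adds ``pixel_count``, ``saturation`` (%),
    ``concentration`` (µM), ``in_range`` and ``error`` columns; failed rows
    carry the error message and NaN measurements.
    """
    if isinstance(manifest, (str, Path)):
        base = Path(manifest).parent
        df = pd.read_csv(manifest, comment="#")
    else:
        base = Path(".")
        df = manifest.copy()
    if "image_path" not in df.columns:
        raise ValueError("manifest must have an image_path column")

    records = []
    for _, row in df.iterrows():
        out = dict(row)
        out.update(
            pixel_count=np.nan,
            saturation=np.nan,
            concentration=np.nan,
            in_range=False,
            error="",
        )
        path = Path(row["image_path"])
        if not path.is_absolute():
            path = base / path
        try:
            metrics = measure_window(read_image(path), seg)
            estimate = cal.invert(model, metrics.mean_saturation)
            out.update(
                pixel_count=metrics.pixel_count,
                saturation=round(metrics.mean_saturation, 1),
                concentration=round(estimate.value, 1),
                in_range=estimate.in_range,
            )
        except (OSError, ValueError, WindowNotFoundError) as exc:
            out["error"] = f"{type(exc).__name__}: {exc}"
        records.append(out)
    return pd.DataFrame.from_records(records)


def classify_donors(
    concentrations: pd.DataFrame,
    admitted_fingers: frozenset[str] | set[str] = coh.ADMITTED_FINGERS,
    ref: coh.LiteratureReference = coh.LiteratureReference(),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Aggregate per-print concentrations to donor calls and a cohort report.

    Parameters
    ----------
    concentrations : DataFrame
        Columns ``donor_id``, ``finger``, ``concentration``; optional
        ``sex`` (ground truth) and ``error``.  Rows with errors or missing
        concentrations are ignored.

    Returns
    -------
    (donors, report)
        ``donors``: one row per donor with n_prints, donor_mean,
        presumptive, actual, match (donors with no admitted print are
        listed as skipped).  ``report``: dict with per-sex print-sample
        summaries, literature comparisons, the male-vs-female Welch test
        and blind-study accuracy when ground truth is present.
    """
    df = concentrations.copy()
    if "error" in df.columns:
        df = df[(df["error"].isna()) | (df["error"] == "")]
    df = df.dropna(subset=["concentration"])

    donor_rows = []
    records: list[coh.DonorRecord] = []
    admitted_by_sex: dict[str, list[float]] = {"female": [], "male": []}
    for donor_id, group in df.groupby("donor_id", sort=True):
        prints = [
            coh.PrintSample(
                donor_id=str(donor_id),
                finger=str(r["finger"]),
                concentration=float(r["concentration"]),
            )
            for _, r in group.iterrows()
        ]
        actual = None
        if "sex" in group.columns and group["sex"].notna().any():
            actual = str(group["sex"].dropna().iloc[0])
        row = {
            "donor_id": donor_id,
            "n_prints": len(prints),
            "donor_mean": np.nan,
            "presumptive": "skipped",
            "actual": actual if actual is not None else "",
            "match": "",
        }
        try:
            donor_mean = coh.aggregate_donor(prints, admitted_fingers)
        except ValueError:
            donor_rows.append(row)
            continue
        presumptive = coh.classify_sex(donor_mean, ref)
        row.update(donor_mean=round(donor_mean, 1), presumptive=presumptive)
        if actual is not None:
            row["match"] = "yes" if presumptive == actual else "no"
            records.append(
                coh.DonorRecord(
                    donor_id=str(donor_id),
                    prints=prints,
                    donor_mean=donor_mean,
                    presumptive_sex=presumptive,
                    actual_sex=actual,
                )
            )
        if actual in admitted_by_sex:
            admitted_by_sex[actual].extend(
                p.concentration for p in prints if p.finger in admitted_fingers
            )
        donor_rows.append(row)

    report: dict = {"groups": {}, "comparisons": {}}
    ref_by_sex = {
        "female": (ref.mu_female, ref.sem_female),
        "male": (ref.mu_male, ref.sem_male),
    }
    for sex, values in admitted_by_sex.items():
        if len(values) < 2:
            continue
        summary = coh.cohort_summary(values)
        report["groups"][sex] = {
            "n": summary.n,
            "mean": round(summary.mean, 1),
            "sem": round(summary.sem, 1),
            "ci95": [round(summary.ci95_low, 1), round(summary.ci95_high, 1)],
        }
        mu_ref, sem_ref = ref_by_sex[sex]
        comp = coh.compare_summary_to_reference(
            summary.mean, summary.sem, mu_ref, sem_ref, alpha
        )
        report["comparisons"][f"{sex}_vs_literature"] = {
            "statistic": round(comp.statistic, 3),
            "p_value": round(comp.p_value, 3),
            "significant": comp.significant,
        }
    if len(admitted_by_sex["female"]) >= 2 and len(admitted_by_sex["male"]) >= 2:
        welch = coh.compare_print_samples(
            admitted_by_sex["female"], admitted_by_sex["male"], alpha
        )
        report["comparisons"]["female_vs_male"] = {
            "statistic": round(welch.statistic, 3),
            "p_value": float(welch.p_value),
            "significant": welch.significant,
        }
    if records:
        matches, total, accuracy = coh.score_blind_study(records)
        report["blind_study"] = {
            "matches": matches,
            "total": total,
            "accuracy_percent": accuracy,
        }
    return pd.DataFrame.from_records(donor_rows), report


def config_fingerprint(config: dict) -> str:
    """Short stable hash of a configuration mapping, for output provenance."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
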