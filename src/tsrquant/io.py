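"""Readers/writers for images and tabular artifacts, and run configuration.

Sample sheets map image files to (patient, core) identifiers; follow-up
tables carry per-patient time to biochemical recurrence. All tabular
artifacts are UTF-8, comma-separated CSV with a header row and '.' as
the decimal separator. TSR values are written rounded to 4 decimals;
in-memory values stay at double precision.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .masking import MaskingParams
from .stain import StainVectors, build_stain_matrix
from .stats import SurvivalRecord
from .tsr import (
    CoreResult,
    Cutoff,
    NoInformativeCoresError,
    aggregate_patient,
    categorize,
    quantify_core,
)

__all__ = [
    "SampleSheetRow",
    "RunConfig",
    "SampleSheetError",
    "read_sample_sheet",
    "read_image",
    "read_followup",
    "load_config",
    "run_quantify",
    "cores_to_frame",
    "aggregate_frame",
]

log = logging.getLogger("tsrquant")

CORE_COLUMNS = [
    "core_id",
    "patient_id",
    "tumor_area_px",
    "stroma_area_px",
    "tsr",
    "four_sides_pass",
    "epcam_negative",
    "empty_stroma",
    "informative",
]
PATIENT_COLUMNS = ["patient_id", "n_informative_cores", "tsr_min", "tsr_max", "category"]


class SampleSheetError(ValueError):
    pass


@dataclass(frozen=True)
class SampleSheetRow:
    patient_id: str
    core_id: str
    image_path: Path
    include: bool = True


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (stain basis, masking, cut-off)."""

    stains: StainVectors = field(default_factory=build_stain_matrix)
    background_intensity: float = 255.0
    masking: MaskingParams = field(default_factory=MaskingParams)
    cutoff: Cutoff = field(default_factory=Cutoff)


_KNOWN_KEYS = {
    "stains": {"hematoxylin", "dab", "background_intensity"},
    "masking": {"median_radius", "border_fraction", "min_tumor_fraction", "overlap_mode"},
    "cutoff": {"value", "statistic"},
}


def load_config(path: str | Path | None) -> RunConfig:
    """Load a TOML config; unknown sections or keys are rejected."""
    if path is None:
        return RunConfig()
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown_sections = set(raw) - set(_KNOWN_KEYS)
    if unknown_sections:
        raise ValueError(f"unknown config sections: {sorted(unknown_sections)}")
    for section, keys in _KNOWN_KEYS.items():
        extra = set(raw.get(section, {})) - keys
        if extra:
            raise ValueError(f"unknown keys in [{section}]: {sorted(extra)}")
    stain_cfg = raw.get("stains", {})
    stains = build_stain_matrix(
        stain_cfg.get("hematoxylin", (0.650, 0.704, 0.286)),
        stain_cfg.get("dab", (0.269, 0.568, 0.778)),
    )
    masking = MaskingParams(**raw.get("masking", {}))
    cutoff = Cutoff(**raw.get("cutoff", {}))
    return RunConfig(
        stains=stains,
        background_intensity=float(stain_cfg.get("background_intensity", 255.0)),
        masking=masking,
        cutoff=cutoff,
    )


def read_sample_sheet(path: str | Path) -> list[SampleSheetRow]:
    """Read and validate a sample sheet CSV.

    Requires columns patient_id, core_id, image_path; optional boolean
    include (default true). Duplicate (patient, core) keys and missing
    image files are reported with their row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = {"patient_id", "core_id", "image_path"}
    missing = required - set(df.columns)
    if missing:
        raise SampleSheetError(f"sample sheet missing columns: {sorted(missing)}")
    if df.empty:
        raise SampleSheetError("sample sheet has no rows")

    rows: list[SampleSheetRow] = []
    seen: dict[tuple[str, str], int] = {}
    problems: list[str] = []
    base = path.parent
    for i, rec in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        key = (rec.patient_id, rec.core_id)
        if key in seen:
            problems.append(
                f"duplicate (patient_id, core_id) {key} at rows {seen[key]} and {i}"
            )
        else:
            seen[key] = i
        image_path = Path(rec.image_path)
        if not image_path.is_absolute():
            image_path = base / image_path
        if not image_path.exists():
            problems.append(f"row {i}: image file not found: {image_path}")
        include = True
        if "include" in df.columns:
            val = getattr(rec, "include")
            include = str(val).strip().lower() in ("1", "true", "yes", "")
        rows.append(
            SampleSheetRow(
                patient_id=str(rec.patient_id),
                core_id=str(rec.core_id),
                image_path=image_path,
                include=include,
            )
        )
    if problems:
        raise SampleSheetError("; ".join(problems))
    return rows


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB TIFF/PNG; an alpha channel is dropped."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit input, got {arr.dtype}")
    return arr


def read_followup(path: str | Path) -> list[SurvivalRecord]:
    """Read a follow-up CSV (patient_id, time_months, event 0/1).

    Rows with a missing time are kept with time=None and excluded from
    survival analyses downstream.
    """
    df = pd.read_csv(path)
    required = {"patient_id", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"follow-up table missing columns: {sorted(missing)}")
    records = []
    for rec in df.itertuples(index=False):
        time = None if pd.isna(rec.time_months) else float(rec.time_months)
        records.append(
            SurvivalRecord(
                patient_id=str(rec.patient_id), time=time, event=bool(int(rec.event))
            )
        )
    return records


def cores_to_frame(cores: Sequence[CoreResult]) -> pd.DataFrame:
    rows = []
    for c in cores:
        rows.append(
            {
                "core_id": c.core_id,
                "patient_id": c.patient_id,
                "tumor_area_px": c.tumor_area,
                "stroma_area_px": c.stroma_area,
                "tsr": round(c.tsr, 4) if c.tsr is not None else np.nan,
                "four_sides_pass": c.qc.four_sides_pass,
                "epcam_negative": c.qc.epcam_negative,
                "empty_stroma": c.qc.empty_stroma,
                "informative": c.informative,
            }
        )
    return pd.DataFrame(rows, columns=CORE_COLUMNS)


def aggregate_frame(cores: Sequence[CoreResult], cutoff: Cutoff) -> pd.DataFrame:
    """Patient-level min/max TSR and category from per-core results.

    Patients without an informative core are omitted (their exclusion is
    counted in the run summary, not silently dropped from it).
    """
    by_patient: dict[str, list[CoreResult]] = {}
    for c in cores:
        by_patient.setdefault(c.patient_id, []).append(c)
    rows = []
    for pid in sorted(by_patient):
        try:
            pr = aggregate_patient(by_patient[pid])
        except NoInformativeCoresError:
            continue
        rows.append(
            {
                "patient_id": pr.patient_id,
                "n_informative_cores": pr.n_informative_cores,
                "tsr_min": round(pr.tsr_min, 4),
                "tsr_max": round(pr.tsr_max, 4),
                "category": categorize(pr, cutoff),
            }
        )
    return pd.DataFrame(rows, columns=PATIENT_COLUMNS)


def run_quantify(
    config: RunConfig, sheet: Sequence[SampleSheetRow], out_dir: str | Path
) -> dict:
    """Quantify every included core and write the run artifacts.

    Writes cores.csv, patients.csv and summary.json under ``out_dir``.
    Unreadable images are logged and counted as failed; the run
    continues. The summary reports core counts per exclusion reason,
    mirroring an enrollment flow.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cores: list[CoreResult] = []
    n_failed = n_skipped = 0
    for row in sheet:
        if not row.include:
            n_skipped += 1
            continue
        try:
            image = read_image(row.image_path)
        except Exception as exc:  # corrupt/unreadable file: keep going
            log.error("failed to read %s: %s", row.image_path, exc)
            n_failed += 1
            continue
        cores.append(
            quantify_core(
                image,
                params=config.masking,
                stains=config.stains,
                core_id=row.core_id,
                patient_id=row.patient_id,
                background_intensity=config.background_intensity,
            )
        )
    core_df = cores_to_frame(cores)
    patient_df = aggregate_frame(cores, config.cutoff)
    core_df.to_csv(out_dir / "cores.csv", index=False)
    patient_df.to_csv(out_dir / "patients.csv", index=False)

    summary = {
        "n_rows": len(sheet),
        "n_skipped_not_included": n_skipped,
        "n_failed_technical": n_failed,
        "n_quantified": len(cores),
        "n_informative": int(core_df["informative"].sum()) if len(core_df) else 0,
        "n_excluded_four_sides": int((~core_df["four_sides_pass"]).sum()) if len(core_df) else 0,
        "n_flagged_epcam_negative": int(core_df["epcam_negative"].sum()) if len(core_df) else 0,
        "n_excluded_empty_stroma": int(core_df["empty_stroma"].sum()) if len(core_df) else 0,
        "n_patients": int(patient_df.shape[0]),
        "category_counts": patient_df["category"].value_counts().to_dict()
        if len(patient_df)
        else {},
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
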