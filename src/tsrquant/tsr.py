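"""Per-core TSR computation, patient-level aggregation and dichotomization.

The tumor-to-stroma ratio of a tissue core is the pixel area of the
tumor mask divided by the pixel area of the (tumor-excluded) stroma
mask. Patients typically contribute two tissue-microarray cores; the
minimal and maximal TSR over their informative cores are recorded, and
the patient is dichotomized on the chosen statistic (max by default)
at a cut-off of 1: low if the statistic is strictly below the cut-off,
high otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from . import masking, stain
from .masking import MaskingParams, QCFlags
from .stain import StainVectors

__all__ = [
    "CoreResult",
    "PatientResult",
    "Cutoff",
    "NoInformativeCoresError",
    "compute_tsr",
    "quantify_core",
    "aggregate_patient",
    "categorize",
]

LOW, HIGH = "low", "high"


class NoInformativeCoresError(ValueError):
    """A patient has no informative core and must be excluded explicitly."""


@dataclass(frozen=True)
class CoreResult:
    """Quantification output for one tissue core."""

    core_id: str
    patient_id: str
    tumor_area: int
    stroma_area: int
    tsr: Optional[float]
    qc: QCFlags

    @property
    def informative(self) -> bool:
        return self.qc.informative and self.tsr is not None


@dataclass(frozen=True)
class PatientResult:
    patient_id: str
    n_informative_cores: int
    tsr_min: float
    tsr_max: float


@dataclass(frozen=True)
class Cutoff:
    """Dichotomization rule: patient statistic vs. cut-off value.

    The boundary belongs to the high class (statistic >= value -> high).
    """

    value: float = 1.0
    statistic: str = "max"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("cutoff value must be > 0")
        if self.statistic not in ("max", "min", "mean", "median"):
            raise ValueError("statistic must be max, min, mean or median")


def compute_tsr(tumor: np.ndarray, stroma: np.ndarray) -> Optional[float]:
    """Tumor area / stroma area over disjoint binary masks.

    Returns None when the stroma mask is empty (undefined ratio; the
    caller marks the core non-informative).
    """
    tumor = np.asarray(tumor, dtype=bool)
    stroma = np.asarray(stroma, dtype=bool)
    if tumor.shape != stroma.shape:
        raise ValueError("masks must have the same shape")
    if np.any(tumor & stroma):
        raise ValueError("tumor and stroma masks must be disjoint")
    stroma_area = masking.mask_area(stroma)
    if stroma_area == 0:
        return None
    return masking.mask_area(tumor) / stroma_area


def quantify_core(
    image: np.ndarray,
    params: MaskingParams | None = None,
    stains: StainVectors | None = None,
    core_id: str = "",
    patient_id: str = "",
    background_intensity: float = 255.0,
) -> CoreResult:
    """Run the full single-core pipeline on an 8-bit RGB image.

    Steps: optical-density conversion, H-DAB color deconvolution,
    8-bit channel rendering, median filtering, moments threshold on the
    DAB channel (tumor), Otsu threshold on the hematoxylin channel
    (stroma), tumor-overlap exclusion, QC flags, ratio. Deterministic
    for fixed inputs.
    """
    params = params or MaskingParams()
    stains = stains or stain.build_stain_matrix()

    od = stain.rgb_to_od(image, background_intensity)
    conc = stain.deconvolve(od, stains)
    dab_channel = masking.median_filter(
        stain.to_channel_image(conc.dab), params.median_radius
    )
    hema_channel = masking.median_filter(
        stain.to_channel_image(conc.hematoxylin), params.median_radius
    )

    # cap the automatic thresholds at the stain-positivity floor so a
    # stain-free channel (degenerate near-white histogram) yields an
    # empty mask instead of labeling the whole field
    cap = params.max_threshold
    tumor = masking.apply_threshold(
        dab_channel,
        min(masking.moments_threshold(masking.histogram256(dab_channel)), cap),
    )
    stroma_raw = masking.apply_threshold(
        hema_channel,
        min(masking.otsu_threshold(masking.histogram256(hema_channel)), cap),
    )
    stroma = masking.exclude_overlap(stroma_raw, tumor, params.overlap_mode)

    qc = QCFlags(
        four_sides_pass=masking.four_sides_qc(tumor, params.border_fraction),
        epcam_negative=masking.epcam_negativity_flag(tumor, params.min_tumor_fraction),
        empty_stroma=masking.mask_area(stroma) == 0,
    )
    tsr = compute_tsr(tumor, stroma) if qc.informative else None
    return CoreResult(
        core_id=core_id,
        patient_id=patient_id,
        tumor_area=masking.mask_area(tumor),
        stroma_area=masking.mask_area(stroma),
        tsr=tsr,
        qc=qc,
    )


def aggregate_patient(cores: Sequence[CoreResult]) -> PatientResult:
    """Min/max TSR over a patient's informative cores.

    With a single informative core min equals max; with none the
    patient is excluded via :class:`NoInformativeCoresError`.
    """
    if not cores:
        raise NoInformativeCoresError("no cores supplied")
    patient_ids = {c.patient_id for c in cores}
    if len(patient_ids) > 1:
        raise ValueError(f"cores span multiple patients: {sorted(patient_ids)}")
    values = [c.tsr for c in cores if c.informative]
    if not values:
        raise NoInformativeCoresError(
            f"patient {cores[0].patient_id!r} has no informative core"
        )
    return PatientResult(
        patient_id=cores[0].patient_id,
        n_informative_cores=len(values),
        tsr_min=min(values),
        tsr_max=max(values),
    )


def _patient_statistic(patient: PatientResult, statistic: str) -> float:
    if statistic == "max":
        return patient.tsr_max
    if statistic == "min":
        return patient.tsr_min
    if statistic == "mean":
        return 0.5 * (patient.tsr_min + patient.tsr_max)
    if statistic == "median":
        return 0.5 * (patient.tsr_min + patient.tsr_max)
    raise ValueError(f"unknown statistic {statistic!r}")


def categorize(patient: PatientResult, cutoff: Cutoff = Cutoff()) -> str:
    """Dichotomize a patient: 'low' if statistic < cutoff, else 'high'."""
    return LOW if _patient_statistic(patient, cutoff.statistic) < cutoff.value else HIGH
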