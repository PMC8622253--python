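"""Synthetic H-DAB histology with known ground truth.

No public scans exist for the cohorts this pipeline targets, so
validation uses rendered stand-ins: elliptical "glands" of DAB-brown
tumor tissue, each with a blank central lumen, placed on a
hematoxylin-blue stroma background. Gland size is adjusted so the
realized tumor/stroma pixel ratio matches a requested target, then the
label field is pushed through the same Beer-Lambert forward model the
deconvolution inverts (class-wise stain concentrations, additive
Gaussian noise in OD space, 8-bit quantization). The blank lumina are
deliberate: gland architecture creates unstained holes that a naive
area measure would misclassify, and the pipeline must not count them
as stroma.

A separate cohort simulator draws per-core TSR values from a
log-normal distribution, dichotomizes patients on their maximal core,
and draws exponential recurrence times whose hazards differ between
the low- and high-TSR groups by a specified hazard ratio, for power
and calibration studies of the survival statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .stain import StainVectors, build_stain_matrix
from .stats import SurvivalRecord
from .tsr import Cutoff, categorize, PatientResult

__all__ = [
    "STROMA",
    "TUMOR",
    "LUMEN",
    "TissueLayout",
    "RenderParams",
    "SimulatedCohort",
    "make_layout",
    "render_ihc",
    "simulate_cohort",
]

STROMA, TUMOR, LUMEN = 0, 1, 2

RATIO_TOLERANCE = 0.05  # realized/target relative mismatch allowed
MIN_RATIO, MAX_RATIO = 0.02, 50.0

# Lognormal TSR defaults reproduce a cohort with median 1.06 and
# mean 2.89 (median = exp(mu); mean = exp(mu + sigma^2/2)).
DEFAULT_TSR_MU = math.log(1.06)
DEFAULT_TSR_SIGMA = math.sqrt(2.0 * math.log(2.89 / 1.06))


@dataclass(frozen=True)
class TissueLayout:
    """Pixel label field over {stroma, tumor, lumen} with known ratio."""

    labels: np.ndarray
    target_ratio: float
    seed: int

    @property
    def realized_ratio(self) -> float:
        tumor = int(np.count_nonzero(self.labels == TUMOR))
        stroma = int(np.count_nonzero(self.labels == STROMA))
        return tumor / stroma


@dataclass(frozen=True)
class RenderParams:
    """Class-wise stain amounts (OD units) and OD-space noise.

    Tumor carries the DAB chromogen plus a light hematoxylin
    counterstain; stroma carries hematoxylin only; lumina are blank.
    """

    dab_od_amplitude: float = 1.0
    hema_od_amplitude: float = 0.7
    hema_background_in_tumor: float = 0.2
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dab_od_amplitude, self.hema_od_amplitude,
               self.hema_background_in_tumor) < 0:
            raise ValueError("stain amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SimulatedCohort:
    """Ground-truth cohort: per-core TSRs, categories, follow-up."""

    patients: list  # of (patient_id, tuple of core TSRs, category)
    survival: list  # of SurvivalRecord
    hazard_ratio_high_vs_low: float
    seed: int


def _gland_geometry(rng: np.random.Generator, height: int, width: int,
                    gland_count: int) -> list[tuple[float, float, float, float, float]]:
    """Gland centers, axis-anisotropies and orientations.

    The first four glands sit on the midpoints of the four borders so
    tumor tissue reaches every edge band regardless of gland size.
    """
    jitter_h = 0.2 * height
    jitter_w = 0.2 * width
    centers = [
        (0.0, width / 2 + rng.uniform(-jitter_w, jitter_w)),          # north
        (float(height - 1), width / 2 + rng.uniform(-jitter_w, jitter_w)),  # south
        (height / 2 + rng.uniform(-jitter_h, jitter_h), 0.0),          # west
        (height / 2 + rng.uniform(-jitter_h, jitter_h), float(width - 1)),  # east
    ]
    for _ in range(max(gland_count - 4, 0)):
        centers.append((rng.uniform(0, height - 1), rng.uniform(0, width - 1)))
    glands = []
    for cy, cx in centers:
        aniso = rng.uniform(0.7, 1.4)       # axis ratio
        theta = rng.uniform(0, math.pi)     # orientation
        glands.append((cy, cx, aniso, 1.0 / aniso, theta))
    return glands


def _rasterize(glands, scale: float, height: int, width: int,
               lumen_fraction: float) -> np.ndarray:
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    labels = np.full((height, width), STROMA, dtype=np.uint8)
    lumen_scale = math.sqrt(lumen_fraction)
    for cy, cx, ay, ax, theta in glands:
        dy, dx = yy - cy, xx - cx
        u = dy * math.cos(theta) + dx * math.sin(theta)
        v = -dy * math.sin(theta) + dx * math.cos(theta)
        ra, rb = scale * ay, scale * ax
        q = (u / ra) ** 2 + (v / rb) ** 2
        labels[q <= 1.0] = TUMOR
        if lumen_fraction > 0:
            labels[q <= lumen_scale**2] = LUMEN
    return labels


def make_layout(
    height: int,
    width: int,
    target_ratio: float,
    gland_count: int = 12,
    lumen_fraction: float = 0.25,
    seed: int = 0,
) -> TissueLayout:
    """Place elliptical glands so tumor/stroma matches ``target_ratio``.

    Gland size is found by bisection on a common scale factor until the
    realized pixel ratio is within 5% of the target; deterministic for
    a fixed seed.
    """
    if height < 64 or width < 64:
        raise ValueError("canvas must be at least 64x64")
    if not MIN_RATIO <= target_ratio <= MAX_RATIO:
        raise ValueError(
            f"target_ratio must be in [{MIN_RATIO}, {MAX_RATIO}]"
        )
    if gland_count < 4:
        raise ValueError("need at least 4 glands (one per border)")
    if not 0 <= lumen_fraction < 1:
        raise ValueError("lumen_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    glands = _gland_geometry(rng, height, width, gland_count)

    def ratio_at(scale: float) -> tuple[float, np.ndarray]:
        labels = _rasterize(glands, scale, height, width, lumen_fraction)
        tumor = np.count_nonzero(labels == TUMOR)
        stroma = np.count_nonzero(labels == STROMA)
        if stroma == 0:
            return math.inf, labels
        return tumor / stroma, labels

    lo, hi = 1.0, float(max(height, width))
    best_labels, best_err = None, math.inf
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        ratio, labels = ratio_at(mid)
        err = abs(ratio - target_ratio) / target_ratio
        if err < best_err:
            best_labels, best_err = labels, err
        if err <= RATIO_TOLERANCE * 0.5:
            break
        if ratio < target_ratio:
            lo = mid
        else:
            hi = mid
    if best_err > RATIO_TOLERANCE:
        raise ValueError(
            f"could not realize ratio {target_ratio} on a "
            f"{height}x{width} canvas (best error {best_err:.1%})"
        )
    return TissueLayout(labels=best_labels, target_ratio=target_ratio, seed=seed)


def render_ihc(
    layout: TissueLayout,
    params: RenderParams = RenderParams(),
    stains: Optional[StainVectors] = None,
) -> np.ndarray:
    """Forward Beer-Lambert render of a layout to an 8-bit RGB image.

    Per pixel, OD = c_hema * v_hema + c_dab * v_dab with class-wise
    concentrations, plus Gaussian noise of sd ``noise_sd`` in each OD
    channel; RGB = round(255 * 10**(-OD)) clamped to [0, 255].
    """
    stains = stains or build_stain_matrix()
    labels = layout.labels
    c_hema = np.zeros(labels.shape)
    c_dab = np.zeros(labels.shape)
    c_hema[labels == STROMA] = params.hema_od_amplitude
    c_hema[labels == TUMOR] = params.hema_background_in_tumor
    c_dab[labels == TUMOR] = params.dab_od_amplitude
    od = (
        c_hema[..., None] * stains.hematoxylin
        + c_dab[..., None] * stains.dab
    )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        od = od + rng.normal(0.0, params.noise_sd, size=od.shape)
    od = np.maximum(od, 0.0)
    rgb = np.clip(np.rint(255.0 * np.power(10.0, -od)), 0, 255)
    return rgb.astype(np.uint8)


def simulate_cohort(
    n_patients: int,
    cores_per_patient: int = 2,
    tsr_mu: float = DEFAULT_TSR_MU,
    tsr_sigma: float = DEFAULT_TSR_SIGMA,
    cutoff: Cutoff = Cutoff(),
    hazard_ratio: float = 2.75,
    baseline_event_rate: float = 0.09,
    followup_horizon: float = 120.0,
    seed: int = 0,
) -> SimulatedCohort:
    """Simulate a dichotomized cohort with TSR-dependent hazards.

    Per-core TSRs are log-normal(mu, sigma); each patient's category
    comes from the cut-off statistic over their cores. Event times are
    exponential: the low-TSR group's hazard is set so a fraction
    ``baseline_event_rate`` of that group recurs before the follow-up
    horizon, and the high-TSR hazard is ``hazard_ratio`` times larger.
    Times past the horizon are censored there. Deterministic per seed.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    if not 0 < baseline_event_rate < 1:
        raise ValueError("baseline_event_rate must be in (0, 1)")
    rng = np.random.default_rng(seed)
    lam_low = -math.log1p(-baseline_event_rate) / followup_horizon
    lam_high = hazard_ratio * lam_low

    patients, survival = [], []
    for i in range(n_patients):
        pid = f"P{i:04d}"
        tsrs = tuple(np.exp(rng.normal(tsr_mu, tsr_sigma, size=cores_per_patient)))
        pr = PatientResult(
            patient_id=pid,
            n_informative_cores=cores_per_patient,
            tsr_min=min(tsrs),
            tsr_max=max(tsrs),
        )
        category = categorize(pr, cutoff)
        lam = lam_high if category == "high" else lam_low
        t = rng.exponential(1.0 / lam)
        event = t <= followup_horizon
        record = SurvivalRecord(
            patient_id=pid,
            time=float(min(t, followup_horizon)),
            event=bool(event),
        )
        patients.append((pid, tsrs, category))
        survival.append(record)
    return SimulatedCohort(
        patients=patients,
        survival=survival,
        hazard_ratio_high_vs_low=hazard_ratio,
        seed=seed,
    )
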