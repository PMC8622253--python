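"""Binary tumor/stroma mask extraction and per-core quality control.

The tumor compartment is the DAB-positive area (EpCAM membrane stain)
and the stroma compartment is the hematoxylin-positive, DAB-negative
area. Each 8-bit per-stain pseudo-transmittance channel is median
filtered, then binarized with an automatic 256-bin histogram threshold:
Tsai's moment-preserving method for the DAB channel and Otsu's
between-class-variance method for the hematoxylin channel. Stain-positive
pixels are dark, so a mask is "value <= threshold". Stroma pixels that
overlap the tumor mask are excluded before the ratio is taken.

Quality control mirrors informativeness rules used in visual TSR
scoring: a core is informative only if tumor tissue reaches all four
sides of the field of view (north, south, east, west edge bands), the
tumor mask is not so small that the core is effectively
EpCAM-negative, and the stroma mask is non-empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "MaskingParams",
    "QCFlags",
    "histogram256",
    "median_filter",
    "otsu_threshold",
    "moments_threshold",
    "apply_threshold",
    "exclude_overlap",
    "four_sides_qc",
    "epcam_negativity_flag",
]


@dataclass(frozen=True)
class MaskingParams:
    """Tunable segmentation/QC parameters.

    median_radius : disc radius (px) of the pre-threshold median filter.
    border_fraction : width of each edge band as a fraction of the
        corresponding image dimension, used by the four-sides criterion.
    min_tumor_fraction : tumor-area fraction below which a core is
        flagged EpCAM-negative and routed to manual scoring.
    overlap_mode : 'pixel' subtracts tumor pixels from stroma;
        'component' removes every 8-connected stroma component that
        touches the tumor mask.
    min_stain_od : stain-positivity floor (OD). Automatic thresholds on
        a channel with no genuine stain degenerate to a near-white
        split, so the effective threshold is capped at the
        pseudo-transmittance of this OD; pixels lighter than that are
        never counted as stained.
    """

    median_radius: int = 2
    border_fraction: float = 0.05
    min_tumor_fraction: float = 0.01
    overlap_mode: str = "pixel"
    min_stain_od: float = 0.1

    def __post_init__(self) -> None:
        if self.median_radius < 0:
            raise ValueError("median_radius must be >= 0")
        if not 0 < self.border_fraction <= 0.5:
            raise ValueError("border_fraction must be in (0, 0.5]")
        if not 0 <= self.min_tumor_fraction < 1:
            raise ValueError("min_tumor_fraction must be in [0, 1)")
        if self.overlap_mode not in ("pixel", "component"):
            raise ValueError("overlap_mode must be 'pixel' or 'component'")
        if self.min_stain_od < 0:
            raise ValueError("min_stain_od must be >= 0")

    @property
    def max_threshold(self) -> int:
        """Largest admissible threshold given the stain-positivity floor."""
        return int(np.rint(255.0 * 10.0 ** (-self.min_stain_od)))


@dataclass(frozen=True)
class QCFlags:
    four_sides_pass: bool
    epcam_negative: bool
    empty_stroma: bool

    @property
    def informative(self) -> bool:
        return self.four_sides_pass and not self.epcam_negative and not self.empty_stroma


def histogram256(channel: np.ndarray) -> np.ndarray:
    """256-bin integer histogram of an 8-bit channel image."""
    channel = np.asarray(channel)
    if channel.dtype != np.uint8:
        raise ValueError("channel must be uint8")
    return np.bincount(channel.ravel(), minlength=256).astype(np.int64)


def median_filter(channel: np.ndarray, radius: int) -> np.ndarray:
    """Median filter with a disc footprint; reflective boundaries.

    Radius 0 is the identity.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    channel = np.asarray(channel)
    if radius == 0:
        return channel.copy()
    footprint = morphology.disk(radius)
    return ndimage.median_filter(channel, footprint=footprint, mode="reflect")


def _check_hist(hist: np.ndarray) -> np.ndarray:
    hist = np.asarray(hist, dtype=float)
    if hist.shape != (256,) or np.any(hist < 0):
        raise ValueError("histogram must be 256 non-negative counts")
    if hist.sum() <= 0:
        raise ValueError("histogram is empty")
    return hist


def otsu_threshold(hist: np.ndarray) -> int:
    """Otsu's threshold on a 256-bin histogram.

    Returns the t maximizing the between-class variance of the split
    {<= t, > t}; ties are broken by the smallest t. If all mass sits in
    a single bin the threshold is that bin index.
    """
    hist = _check_hist(hist)
    nonzero = np.flatnonzero(hist)
    if nonzero.size == 1:
        return int(nonzero[0])
    total = hist.sum()
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist) / total            # weight of class {<= t}
    mu_cum = np.cumsum(hist * levels) / total
    mu_total = mu_cum[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_total - mu_cum) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.nan_to_num(between, nan=-1.0)
    return int(np.argmax(between))  # argmax returns the first (smallest) maximizer


def moments_threshold(hist: np.ndarray) -> int:
    """Tsai's moment-preserving threshold on a 256-bin histogram.

    Finds the two representative gray levels z0 < z1 and the dark-class
    fraction p0 such that a binary image with fraction p0 at z0 and
    1 - p0 at z1 preserves the first three gray-level moments of the
    histogram, then returns the smallest gray level at which the
    cumulative histogram fraction reaches p0.
    """
    hist = _check_hist(hist)
    nonzero = np.flatnonzero(hist)
    if nonzero.size == 1:
        return int(nonzero[0])
    total = hist.sum()
    p = hist / total
    levels = np.arange(256, dtype=float)
    m1 = float(np.sum(levels * p))
    m2 = float(np.sum(levels**2 * p))
    m3 = float(np.sum(levels**3 * p))
    # Solve for z0, z1 as roots of z^2 + c1 z + c0 = 0 with coefficients
    # chosen so the binary distribution matches m1, m2, m3 (m0 = 1).
    cd = m2 - m1 * m1
    if cd <= 0:  # numerically degenerate (near-single-level histogram)
        return int(nonzero[0])
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        disc = 0.0
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        return int(nonzero[0])
    p0 = (z1 - m1) / (z1 - z0)  # fraction of the darker class
    p0 = min(max(p0, 0.0), 1.0)
    cum = np.cumsum(p)
    # smallest gray level whose cumulative fraction reaches p0; the
    # tolerance absorbs round-off when p0 ties a cumulative step exactly
    # (e.g. two-spike histograms), where the tie belongs to the lower level
    idx = np.searchsorted(cum, p0 - 1e-7)
    return int(min(idx, 255))


def apply_threshold(channel: np.ndarray, t: int) -> np.ndarray:
    """Binarize a pseudo-transmittance channel: stain-positive = dark.

    Returns a boolean mask, true where value <= t.
    """
    if not 0 <= t <= 255:
        raise ValueError("threshold must be in [0, 255]")
    channel = np.asarray(channel)
    return channel <= t


def mask_area(mask: np.ndarray) -> int:
    """Number of true pixels in a binary mask."""
    return int(np.count_nonzero(mask))


def exclude_overlap(
    stroma: np.ndarray, tumor: np.ndarray, mode: str = "pixel"
) -> np.ndarray:
    """Remove tumor-overlapping parts of the stroma mask.

    'pixel' keeps stroma pixels outside the tumor mask; 'component'
    drops every 8-connected stroma component that shares at least one
    pixel with the tumor. Both outputs are disjoint from the tumor mask.
    """
    stroma = np.asarray(stroma, dtype=bool)
    tumor = np.asarray(tumor, dtype=bool)
    if stroma.shape != tumor.shape:
        raise ValueError("stroma and tumor masks must have the same shape")
    if mode == "pixel":
        return stroma & ~tumor
    if mode == "component":
        labels = measure.label(stroma, connectivity=2)
        touching = np.unique(labels[tumor & stroma])
        touching = touching[touching > 0]
        keep = stroma.copy()
        if touching.size:
            keep[np.isin(labels, touching)] = False
        return keep
    raise ValueError("mode must be 'pixel' or 'component'")


def _band_width(n: int, border_fraction: float) -> int:
    return int(np.ceil(border_fraction * n))


def four_sides_qc(tumor: np.ndarray, border_fraction: float = 0.05) -> bool:
    """True iff tumor pixels reach all four edge bands of the field.

    The bands are the top/bottom ``ceil(border_fraction * H)`` rows and
    the left/right ``ceil(border_fraction * W)`` columns.
    """
    if not 0 < border_fraction <= 0.5:
        raise ValueError("border_fraction must be in (0, 0.5]")
    tumor = np.asarray(tumor, dtype=bool)
    h, w = tumor.shape
    bh = _band_width(h, border_fraction)
    bw = _band_width(w, border_fraction)
    return bool(
        tumor[:bh, :].any()
        and tumor[h - bh :, :].any()
        and tumor[:, :bw].any()
        and tumor[:, w - bw :].any()
    )


def epcam_negativity_flag(tumor: np.ndarray, min_tumor_fraction: float = 0.01) -> bool:
    """Flag a core as EpCAM-negative when the tumor mask is too small.

    True iff tumor area / image area < min_tumor_fraction (strict).
    Flagged cores go to manual scoring instead of the automatic ratio.
    """
    if not 0 <= min_tumor_fraction < 1:
        raise ValueError("min_tumor_fraction must be in [0, 1)")
    tumor = np.asarray(tumor, dtype=bool)
    return mask_area(tumor) / tumor.size < min_tumor_fraction
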