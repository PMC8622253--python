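"""Color deconvolution of H-DAB brightfield images.

Brightfield immunohistochemistry obeys the Beer-Lambert law: each stain
absorbs light proportionally to its local amount, and absorbances
(optical densities) add. An RGB pixel is therefore a mixture

    OD(pixel) = c_hema * v_hema + c_dab * v_dab + c_res * v_res

where the ``v`` are unit absorption vectors characteristic of
hematoxylin (blue counterstain), DAB (brown chromogen) and a residual
complement, and the ``c`` are per-pixel stain amounts. Inverting this
3x3 linear system per pixel (Ruifrok-Johnston color deconvolution)
yields one concentration map per stain. Downstream thresholding
operates on 8-bit pseudo-transmittance renderings of those maps
(0 = maximal stain, 255 = unstained), the convention of classical
deconvolution plugins and of 256-bin histogram threshold methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainVectors",
    "ODImage",
    "ConcentrationMaps",
    "HEMATOXYLIN_HDAB",
    "DAB_HDAB",
    "rgb_to_od",
    "build_stain_matrix",
    "deconvolve",
    "to_channel_image",
]

#: Default H-DAB absorption vectors (unit-normalized below in
#: :func:`build_stain_matrix`); the widely used H-DAB preset.
HEMATOXYLIN_HDAB = (0.650, 0.704, 0.286)
DAB_HDAB = (0.269, 0.568, 0.778)

#: Intensity floor preventing log(0) when converting to optical density.
INTENSITY_FLOOR = 1.0


class StainBasisError(ValueError):
    """Raised when the requested stain vectors do not span a valid basis."""


@dataclass(frozen=True)
class StainVectors:
    """Unit-normalized stain absorption basis, rows (hematoxylin, DAB, residual).

    Attributes
    ----------
    matrix : (3, 3) ndarray
        Row-stochastic in direction only: each row has Euclidean norm 1.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise StainBasisError("stain matrix must be 3x3")
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise StainBasisError("each stain vector must be unit-normalized")
        if not np.isfinite(np.linalg.cond(m)) or np.linalg.cond(m) > 1e12:
            raise StainBasisError("stain matrix is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.matrix[0]

    @property
    def dab(self) -> np.ndarray:
        return self.matrix[1]

    @property
    def residual(self) -> np.ndarray:
        return self.matrix[2]


@dataclass(frozen=True)
class ODImage:
    """Optical-density image (H, W, 3), base-10, all values >= 0."""

    values: np.ndarray
    background_intensity: float = 255.0


@dataclass(frozen=True)
class ConcentrationMaps:
    """Per-stain amount fields; small negatives can occur from noise."""

    hematoxylin: np.ndarray
    dab: np.ndarray
    residual: np.ndarray

    def __iter__(self):
        return iter((self.hematoxylin, self.dab, self.residual))


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(
            f"expected an H x W x 3 RGB image, got shape {image.shape}"
        )
    if image.dtype != np.uint8:
        raise ValueError(f"expected 8-bit (uint8) input, got dtype {image.dtype}")
    return image


def rgb_to_od(image: np.ndarray, background_intensity: float = 255.0) -> ODImage:
    """Convert an 8-bit RGB image to optical density.

    OD = -log10(max(I, 1) / I0) per channel; the floor of 1 bounds the
    OD of a fully dark pixel at log10(I0) instead of infinity.

    Parameters
    ----------
    image : (H, W, 3) uint8 ndarray
    background_intensity : float
        Incident (white) intensity I0, in (0, 255]. Default 255.
    """
    image = _validate_rgb(image)
    if not 0 < background_intensity <= 255:
        raise ValueError("background_intensity must be in (0, 255]")
    intensity = np.maximum(image.astype(float), INTENSITY_FLOOR)
    od = -np.log10(intensity / background_intensity)
    # the floor can still leave tiny negatives if I0 < 255; clip to contract
    od = np.maximum(od, 0.0)
    return ODImage(values=od, background_intensity=background_intensity)


def build_stain_matrix(
    hema_vector=HEMATOXYLIN_HDAB, dab_vector=DAB_HDAB
) -> StainVectors:
    """Complete a two-stain H-DAB basis with a residual third vector.

    The residual row is the unit cross product of the (normalized)
    hematoxylin and DAB vectors, so the matrix is always invertible for
    non-collinear inputs.
    """
    h = np.asarray(hema_vector, dtype=float)
    d = np.asarray(dab_vector, dtype=float)
    if h.shape != (3,) or d.shape != (3,):
        raise StainBasisError("stain vectors must be 3-vectors")
    hn, dn = np.linalg.norm(h), np.linalg.norm(d)
    if hn == 0 or dn == 0:
        raise StainBasisError("stain vectors must be non-zero")
    h, d = h / hn, d / dn
    r = np.cross(h, d)
    rn = np.linalg.norm(r)
    if rn < 1e-12:
        raise StainBasisError("hematoxylin and DAB vectors are collinear")
    return StainVectors(matrix=np.vstack([h, d, r / rn]))


def deconvolve(od: ODImage, stains: StainVectors) -> ConcentrationMaps:
    """Unmix an OD image into per-stain concentration maps.

    Solves OD = c @ M per pixel (M the stain matrix, rows = stains)
    by exact linear inversion. Reconstruction ``c @ M`` reproduces the
    input OD to machine precision.
    """
    values = np.asarray(od.values, dtype=float)
    if values.ndim != 3 or values.shape[2] != 3:
        raise ValueError("OD image must be H x W x 3")
    if not np.all(np.isfinite(values)):
        raise ValueError("OD image must be finite")
    inv = np.linalg.inv(stains.matrix)
    conc = values @ inv  # (H, W, 3): od_vec @ M^-1 solves c @ M = od
    return ConcentrationMaps(
        hematoxylin=conc[..., 0], dab=conc[..., 1], residual=conc[..., 2]
    )


def to_channel_image(concentration: np.ndarray) -> np.ndarray:
    """Render a concentration field as an 8-bit pseudo-transmittance image.

    value = round(255 * 10**(-c)) clamped to [0, 255]: zero stain maps
    to white (255), heavy stain to black (0). Monotonically
    non-increasing in concentration.
    """
    c = np.asarray(concentration, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("concentration field must be finite")
    with np.errstate(over="ignore"):
        trans = 255.0 * np.power(10.0, -c)
    return np.clip(np.rint(trans), 0, 255).astype(np.uint8)
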