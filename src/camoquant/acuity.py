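"""Receiver spatial acuity: Gaussian blur and rescale of catch images.

A receiver with acuity *A* cycles per degree has a minimum resolvable
angle (MRA) of 1/A degrees.  Viewed from distance *d*, one MRA spans

    mra_mm = 2 · d · tan(mra_deg / 2)

on the object plane, or ``mra_mm · scale_px_per_mm`` pixels in the
image.  Acuity control removes spatial information finer than the MRA
by blurring every channel with a Gaussian whose full width at half
maximum equals one MRA in pixels (σ = FWHM / 2.3548, boundary mode
reflect), then rescales the image so one MRA spans a fixed number of
pixels (5 by default), putting images taken at different distances on a
common receiver-resolution footing.  The whole image is processed;
masks are rescaled with nearest-neighbour so labels stay integers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from .errors import DomainError, UsageError
from .spectra import CatchImage, validate_mask

#: FWHM = 2·sqrt(2·ln 2)·σ for a Gaussian
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class ViewingGeometry:
    """Receiver acuity (cycles/degree), viewing distance (mm) and the
    target resolution of the rescaled image (pixels per MRA)."""

    acuity_cpd: float
    distance_mm: float
    px_per_mra: float = 5.0

    def __post_init__(self) -> None:
        if self.acuity_cpd <= 0 or self.distance_mm <= 0 or self.px_per_mra <= 0:
            raise DomainError("acuity, distance and px_per_mra must all be positive")


@dataclass(frozen=True)
class MRAGeometry:
    mra_deg: float
    mra_mm: float
    mra_px: float


def mra_geometry(g: ViewingGeometry, scale_px_per_mm: float) -> MRAGeometry:
    """Minimum resolvable angle in degrees, millimetres on the object
    plane, and image pixels."""
    if scale_px_per_mm <= 0:
        raise DomainError("scale_px_per_mm must be positive")
    mra_deg = 1.0 / g.acuity_cpd
    mra_mm = 2.0 * g.distance_mm * np.tan(np.deg2rad(mra_deg / 2.0))
    return MRAGeometry(mra_deg, float(mra_mm), float(mra_mm * scale_px_per_mm))


def apply_acuity(
    img: CatchImage,
    g: ViewingGeometry,
    mask: np.ndarray | None = None,
    rescale: bool = True,
):
    """Blur every channel to the receiver's MRA and rescale.

    Returns the acuity-controlled :class:`CatchImage` (its
    ``scale_px_per_mm`` updated for the rescale), or a
    ``(CatchImage, mask)`` pair when a label mask is supplied.  If the
    image is already at or below receiver resolution (MRA < 2 px) a
    minimal blur is applied with a warning.
    """
    shape = img.shape
    if min(shape) < 1 or any(s == 0 for s in shape):
        raise UsageError("empty image")
    geo = mra_geometry(g, img.scale_px_per_mm)
    mra_px = geo.mra_px
    if mra_px < 2.0:
        warnings.warn(
            f"MRA of {mra_px:.2f} px is below image resolution; applying minimal blur",
            stacklevel=2,
        )
        mra_px = 2.0
    sigma = mra_px / FWHM_PER_SIGMA

    blurred = img.map(lambda ch: gaussian_filter(ch, sigma, mode="reflect"))
    if not rescale:
        return blurred if mask is None else (blurred, np.asarray(mask))

    factor = g.px_per_mra / mra_px
    out_shape = (max(1, round(shape[0] * factor)), max(1, round(shape[1] * factor)))
    out = CatchImage(
        {
            name: resize(
                ch, out_shape, order=1, mode="edge",
                anti_aliasing=False, preserve_range=True,
            )
            for name, ch in blurred.channels.items()
        },
        scale_px_per_mm=img.scale_px_per_mm * factor,
        receptor_set=img.receptor_set,
    )
    if mask is None:
        return out
    mask = validate_mask(mask, shape, require=())
    mask_out = resize(
        mask.astype(float), out_shape, order=0, mode="edge",
        anti_aliasing=False, preserve_range=True,
    ).astype(int)
    # nearest-neighbour rescale may drop tiny ROIs; revalidate leniently
    lost = set(np.unique(mask)) - set(np.unique(mask_out))
    if lost:
        warnings.warn(f"mask labels {sorted(lost)} lost during rescale", stacklevel=2)
    return out, mask_out
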