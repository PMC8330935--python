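"""Signal compensation and projection-artifact exclusion masks.

The angiographic slab is attenuated wherever the overlying RPE/BM complex
scatters light; the structural slab carries the same attenuation pattern.
Compensation divides the angio image by a smoothed, max-normalized, floored
version of the structural image, which brightens attenuated regions without
amplifying noise in near-zero areas.  Shadows of superficial-plexus vessels
are handled separately, by exclusion: a dilated vessel mask flags pixels
that never enter any count.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .core import BinaryMask, EnFaceImage, Masked

DEFAULT_SIGMA_UM = 5.0
DEFAULT_FLOOR = 0.05


def compensate_signal(
    angio: EnFaceImage,
    structural: EnFaceImage,
    smoothing_sigma_um: float = DEFAULT_SIGMA_UM,
    floor: float = DEFAULT_FLOOR,
) -> EnFaceImage:
    """Divide the angio slab by its smoothed structural counterpart.

    The structural image is Gaussian-smoothed (sigma given in um, converted
    through the pixel pitch), rescaled to (0, 1] by its maximum and clamped
    below at ``floor``; the angio image is divided by the result and
    re-clipped to [0, 1].  Under a flat structural field the operation is
    the identity.
    """
    if angio.pixels.shape != structural.pixels.shape:
        raise ValueError("angio and structural images must share a shape")
    if abs(angio.pitch_um - structural.pitch_um) > 1e-9:
        raise ValueError("angio and structural images must share a pitch")
    if structural.kind != "structural":
        raise ValueError("second argument must be a structural image")
    if not 0.0 < floor < 1.0:
        raise ValueError("floor must lie strictly inside (0, 1)")

    sigma_px = smoothing_sigma_um / angio.pitch_um
    smooth = ndimage.gaussian_filter(structural.pixels, sigma=sigma_px, mode="reflect")
    peak = smooth.max()
    if peak <= 0:
        # fully dark structural slab: nothing to compensate against
        field = np.ones_like(smooth)
    else:
        field = np.clip(smooth / peak, floor, None)
    out = np.clip(angio.pixels / field, 0.0, 1.0)
    return angio.with_pixels(out, kind="angio")


def build_vessel_mask(vessel_raster: BinaryMask, dilation_um: float, pitch_um: float) -> BinaryMask:
    """Dilate a superficial-plexus vessel raster into an exclusion mask.

    Dilation uses a digital disk of radius ``round(dilation_um / pitch_um)``
    pixels (a pixel belongs to the disk iff its center distance is <= the
    radius).
    """
    if dilation_um < 0:
        raise ValueError("dilation must be non-negative")
    radius_px = int(round(dilation_um / pitch_um))
    pixels = vessel_raster.pixels
    if radius_px > 0:
        pixels = ndimage.binary_dilation(pixels, structure=disk(radius_px))
    return BinaryMask(pixels=pixels, semantics="vessel-exclusion")


def apply_exclusion(data: np.ndarray, exclusion: BinaryMask) -> Masked:
    """Attach a validity channel: pixels under the exclusion mask are invalid."""
    data = np.asarray(data)
    if data.shape != exclusion.pixels.shape:
        raise ValueError("exclusion mask does not match the data shape")
    return Masked(data=data, valid=~exclusion.pixels)
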