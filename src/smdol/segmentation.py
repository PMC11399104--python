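"""Cell-footprint segmentation from the reference channel.

The mask serves two purposes: restrict the analysis to signal inside
cells so that background localizations outside cells never enter the
colocalization statistics, and provide the cell area used for density
normalisation.  The pipeline is background subtraction, a difference-of-
Gaussians band-pass, an automatic (Otsu) global threshold, morphological
closing, hole filling and removal of small components.  The band-pass is
tuned to the diffuse cellular fluorescence (out-of-focus and membrane-
proximal signal) rather than to individual molecules, so the footprint
is recovered even when only a handful of probes are present.  Degree of
colocalization and density are ratios over the same mask, so modest
over- or under-segmentation does not bias them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label

from .io import Image2D, LocalizationSet, SegmentationSettings

__all__ = ["CellMask", "NoCellFoundWarning", "segment_reference", "mask_filter"]


class NoCellFoundWarning(UserWarning):
    pass


@dataclass
class CellMask:
    """Binary cell footprint aligned to an :class:`Image2D`."""

    mask: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * (self.pixel_size_nm / 1000.0) ** 2

    @property
    def n_components(self) -> int:
        return int(label(self.mask, connectivity=2).max())

    @property
    def found(self) -> bool:
        """False flags "no cell found"; downstream stages must skip the image."""
        return bool(self.mask.any())


def _closing_edt(mask: np.ndarray, radius: float) -> np.ndarray:
    """Morphological closing with a disk via distance transforms (O(N),
    independent of radius)."""
    if radius <= 0 or not mask.any():
        return mask
    dilated = ndimage.distance_transform_edt(~mask) <= radius
    eroded = ndimage.distance_transform_edt(dilated) > radius - 0.5
    return eroded | mask  # closing is extensive


def segment_reference(
    image: Image2D,
    low_sigma_px: float = 4.0,
    high_sigma_px: float = 64.0,
    min_object_area_um2: float = 20.0,
    close_radius_px: float = 8.0,
    min_separation_sd: float = 4.0,
) -> CellMask:
    """Segment the cell footprint from a reference-channel image.

    Steps: subtract a large-scale background estimate (Gaussian at
    3x ``high_sigma_px``), band-pass with a difference of Gaussians
    (``low_sigma_px``/``high_sigma_px``) whose pass-band spans the
    cell-body scale, Otsu threshold, closing with a ``close_radius_px``
    disk, hole filling, and removal of connected components smaller than
    ``min_object_area_um2``.  The threshold is accepted only when the
    foreground separates from the background by at least
    ``min_separation_sd`` robust noise SDs — on an image with no cell,
    Otsu would otherwise split pure noise.  An empty result is flagged
    (warning + ``found == False``) rather than raised, so batch runs can
    skip the image.
    """
    if not low_sigma_px < high_sigma_px:
        raise ValueError("low_sigma_px must be < high_sigma_px")
    img = image.pixels
    background = gaussian(img, sigma=3.0 * high_sigma_px, preserve_range=True)
    flattened = img - background
    band = gaussian(flattened, sigma=low_sigma_px, preserve_range=True) - gaussian(
        flattened, sigma=high_sigma_px, preserve_range=True
    )

    if np.ptp(band) <= 0:
        warnings.warn("no cell found (flat image)", NoCellFoundWarning)
        return CellMask(np.zeros(img.shape, dtype=bool), image.pixel_size_nm)

    binary = band > threshold_otsu(band)
    if binary.any() and not binary.all():
        noise_sd = 1.4826 * np.median(np.abs(band[~binary] - np.median(band[~binary])))
        separation = np.median(band[binary]) - np.median(band[~binary])
        if noise_sd > 0 and separation < min_separation_sd * noise_sd:
            warnings.warn("no cell found (no foreground contrast)", NoCellFoundWarning)
            return CellMask(np.zeros(img.shape, dtype=bool), image.pixel_size_nm)
    closed = _closing_edt(binary, close_radius_px)
    filled = ndimage.binary_fill_holes(closed)

    px_area_um2 = (image.pixel_size_nm / 1000.0) ** 2
    min_px = int(np.ceil(min_object_area_um2 / px_area_um2))
    labels = label(filled, connectivity=2)
    keep = np.zeros_like(filled)
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        if comp.sum() >= min_px:
            keep |= comp

    if not keep.any():
        warnings.warn("no cell found after cleanup", NoCellFoundWarning)
    return CellMask(keep, image.pixel_size_nm)


def segment_with_settings(image: Image2D, settings: SegmentationSettings) -> CellMask:
    return segment_reference(
        image,
        low_sigma_px=settings.low_sigma_px,
        high_sigma_px=settings.high_sigma_px,
        min_object_area_um2=settings.min_object_area_um2,
        close_radius_px=settings.close_radius_px,
        min_separation_sd=settings.min_separation_sd,
    )


def mask_filter(localizations: LocalizationSet, cell_mask: CellMask) -> LocalizationSet:
    """Keep localizations whose position falls on a true mask pixel.

    Pixel membership is by floor(nm / pixel size); a point exactly on the
    mask boundary therefore counts as inside its pixel.
    """
    if len(localizations) == 0:
        return localizations
    px = cell_mask.pixel_size_nm
    rows, cols = cell_mask.mask.shape
    c = np.floor(localizations.x_nm / px).astype(int)
    r = np.floor(localizations.y_nm / px).astype(int)
    inside = (r >= 0) & (r < rows) & (c >= 0) & (c < cols)
    keep = np.zeros(len(localizations), dtype=bool)
    keep[inside] = cell_mask.mask[r[inside], c[inside]]
    return localizations.select(keep)
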