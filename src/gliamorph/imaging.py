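"""Preprocessing of single-cell images into paired filled/outline binary masks.

The measurement stages all operate on a :class:`BinaryCellImage`: a filled
silhouette of one cell together with its one-pixel outer boundary.  The
digital-topology conventions are fixed here once: rasters are row-major
(row, col) with origin at the top-left, foreground is 8-connected,
background is 4-connected, and the outline is the set of foreground pixels
4-adjacent to background (pixels on the image border count as adjacent to
background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk as _disk_footprint

__all__ = [
    "BinaryCellImage",
    "binarize",
    "isolate_cell",
    "fill_and_outline",
    "outline_of",
]

#: physical pixel side, in micrometres, of the acquisition setup emulated here
DEFAULT_PIXEL_SIZE_UM = 0.115

_S8 = np.ones((3, 3), bool)  # 8-connectivity structuring element
_S4 = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


class ImagePipelineError(ValueError):
    """Raised when an image cannot be turned into a valid cell mask."""


def outline_of(filled: np.ndarray) -> np.ndarray:
    """Outer boundary: foreground pixels 4-adjacent to background.

    The image border is treated as background, so a shape touching the
    frame still has a closed outline.
    """
    filled = np.asarray(filled, bool)
    eroded = ndimage.binary_erosion(filled, structure=_S4, border_value=0)
    return filled & ~eroded


@dataclass(frozen=True)
class BinaryCellImage:
    """Filled silhouette of a single cell plus its outline.

    Invariants checked at construction: the filled mask is nonempty, forms
    exactly one 8-connected component with no interior holes, and the
    outline equals its outer boundary.
    """

    filled_mask: np.ndarray
    outline_mask: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        filled = np.asarray(self.filled_mask, bool)
        outline = np.asarray(self.outline_mask, bool)
        object.__setattr__(self, "filled_mask", filled)
        object.__setattr__(self, "outline_mask", outline)
        if self.pixel_size_um <= 0:
            raise ImagePipelineError("pixel_size_um must be positive")
        if filled.ndim != 2 or filled.shape != outline.shape:
            raise ImagePipelineError("masks must be 2-D and share a shape")
        if not filled.any():
            raise ImagePipelineError("filled mask is empty")
        _, n = ndimage.label(filled, structure=_S8)
        if n != 1:
            raise ImagePipelineError(f"filled mask has {n} components, expected 1")
        if ndimage.binary_fill_holes(filled).sum() != filled.sum():
            raise ImagePipelineError("filled mask has interior holes")
        if not np.array_equal(outline, outline_of(filled)):
            raise ImagePipelineError("outline mask is not the boundary of the filled mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.filled_mask.shape


def binarize(
    gray: np.ndarray,
    threshold: float,
    smoothing_radius: float = 0.0,
    foreground: str = "dark",
) -> np.ndarray:
    """Threshold a single-channel image into a binary raster.

    The same, previously established threshold is meant to be reused across
    a whole cohort so that cells remain comparable.  ``foreground`` selects
    the polarity: ``"dark"`` (DAB-stained cells on a light background, the
    default) keeps pixels ``<= threshold``; ``"light"`` keeps ``>=``.
    An optional Gaussian smoothing (sigma in pixels) suppresses
    high-frequency background noise before thresholding.
    """
    gray = np.asarray(gray, float)
    if gray.ndim != 2:
        raise ImagePipelineError("binarize expects a single-channel 2-D image")
    if smoothing_radius > 0:
        gray = ndimage.gaussian_filter(gray, sigma=smoothing_radius)
    if foreground == "dark":
        mask = gray <= threshold
    elif foreground == "light":
        mask = gray >= threshold
    else:
        raise ImagePipelineError(f"unknown polarity {foreground!r}")
    if not mask.any():
        raise ImagePipelineError("no cell at threshold")
    return mask


def isolate_cell(
    binary: np.ndarray,
    marker: tuple[int, int],
    closing_radius: int = 1,
    marker_tolerance_px: int = 5,
) -> np.ndarray:
    """Keep only the connected component of the cell at ``marker``.

    Morphological closing with a disk of ``closing_radius`` first bridges
    small gaps between the soma and branches that thresholding may have
    disconnected; this is the deterministic surrogate for manual editing of
    the binarized image.  ``marker`` is (row, col); if it falls on
    background, the nearest foreground pixel within ``marker_tolerance_px``
    is used instead.
    """
    binary = np.asarray(binary, bool)
    if closing_radius > 0:
        binary = ndimage.binary_closing(
            binary, structure=_disk_footprint(closing_radius), border_value=0
        )
    labels, n = ndimage.label(binary, structure=_S8)
    if n == 0:
        raise ImagePipelineError("no foreground after closing")
    r, c = marker
    r = int(round(r))
    c = int(round(c))
    if not (0 <= r < binary.shape[0] and 0 <= c < binary.shape[1]):
        raise ImagePipelineError(f"marker {marker} outside image {binary.shape}")
    if labels[r, c] == 0:
        fg = np.argwhere(binary)
        d2 = ((fg - [r, c]) ** 2).sum(axis=1)
        i = int(np.argmin(d2))
        if d2[i] > marker_tolerance_px**2:
            raise ImagePipelineError(
                f"marker {marker} is {np.sqrt(d2[i]):.1f} px from foreground "
                f"(tolerance {marker_tolerance_px})"
            )
        r, c = fg[i]
    return labels == labels[r, c]


def fill_and_outline(
    component: np.ndarray, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
) -> BinaryCellImage:
    """Fill interior holes of a single-component mask and derive its outline."""
    component = np.asarray(component, bool)
    _, n = ndimage.label(component, structure=_S8)
    if n != 1:
        raise ImagePipelineError(f"expected a single component, found {n}")
    filled = ndimage.binary_fill_holes(component)
    return BinaryCellImage(filled, outline_of(filled), pixel_size_um)
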