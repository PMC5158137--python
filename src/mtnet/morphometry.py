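"""Microtubule-network morphometry from 2-D superresolution images.

The pipeline mirrors the standard filament-morphometry recipe: enhance the
filament signal with a white top-hat, binarize at a fixed manual threshold
(the same threshold for every image of a run), thin the binary network to a
one-pixel-wide skeleton, and detect branch points (skeleton pixels with three
or more skeleton neighbours) as a proxy for microtubule crossings.  Two
densities summarize a cell:

* MT density       = skeleton length / imaged cell area   (px^-1)
* crossing density = branch-point count / skeleton length (px^-1)

Coordinates are row-major 0-based pixel indices throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology

__all__ = [
    "FilamentImage",
    "CellMask",
    "MorphometryResult",
    "CellAreaConfig",
    "EmptyFieldError",
    "detect_cell_area",
    "enhance_tophat",
    "binarize",
    "skeletonize",
    "prune_spurs",
    "detect_branchpoints",
    "skeleton_length",
    "measure",
]


class EmptyFieldError(ValueError):
    """No foreground signal found in the field."""


@dataclass(frozen=True)
class FilamentImage:
    """A 2-D grayscale image of a filament network.

    pixels : non-negative finite intensity array (float).
    pixel_size : nm per pixel.
    identifier : label used in reports.
    """

    pixels: np.ndarray
    pixel_size: float = 20.0
    identifier: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", arr)
        if arr.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("pixel intensities must be finite")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class CellMask:
    """Binary mask of the imaged cell area (a single connected component)."""

    mask: np.ndarray

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class MorphometryResult:
    skeleton: np.ndarray
    skeleton_length: float  # px
    branchpoint_count: int
    mt_density: float  # px^-1, skeleton_length / cell area
    crossing_density: float  # px^-1, branchpoints / skeleton_length; nan if undefined
    crossing_density_defined: bool


@dataclass(frozen=True)
class CellAreaConfig:
    """Parameters of the automated cell-area selection.

    Coarse Gaussian smoothing (sigma in px) -> Otsu threshold -> fill holes ->
    keep the largest connected component.
    """

    smooth_sigma: float = 10.0


def detect_cell_area(img: FilamentImage, config: CellAreaConfig | None = None) -> CellMask:
    """Select the imaged cell area as the largest smoothed foreground region."""
    cfg = config or CellAreaConfig()
    pix = img.pixels
    if pix.size == 0:
        raise EmptyFieldError("empty field: image has no pixels")
    smooth = ndi.gaussian_filter(pix, sigma=cfg.smooth_sigma)
    lo, hi = float(smooth.min()), float(smooth.max())
    if hi == lo:
        if hi > 0:  # saturated/flat bright field: the whole frame is cell
            return CellMask(np.ones_like(pix, dtype=bool))
        raise EmptyFieldError("empty field: no foreground found")
    fg = smooth > filters.threshold_otsu(smooth)
    fg = ndi.binary_fill_holes(fg)
    labels, n = ndi.label(fg)
    if n == 0:
        raise EmptyFieldError("empty field: no foreground found")
    sizes = ndi.sum_labels(fg, labels, index=np.arange(1, n + 1))
    mask = labels == (int(np.argmax(sizes)) + 1)
    return CellMask(mask)


def enhance_tophat(img: FilamentImage, radius_px: int = 5) -> FilamentImage:
    """White top-hat (image minus its morphological opening) with a disk element.

    Removes background structures larger than the disk while preserving thin
    bright filaments; the radius must exceed the filament width and stay below
    the inter-filament spacing.  Output is everywhere >= 0 and <= input.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    enhanced = morphology.white_tophat(img.pixels, footprint=morphology.disk(radius_px))
    return FilamentImage(enhanced, img.pixel_size, img.identifier)


def binarize(img: FilamentImage, threshold: float) -> np.ndarray:
    """Fixed-threshold binarization: pixel is foreground iff intensity > threshold.

    The same manually chosen threshold is applied to every image in a run.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return img.pixels > threshold


def _neighbours_connected_without(skel: np.ndarray, r: int, c: int) -> bool:
    """True if the 8-neighbours of (r, c) form one 8-connected component when
    (r, c) itself is removed (connectivity judged inside the 3x3 window)."""
    h, w = skel.shape
    rs = slice(max(r - 1, 0), min(r + 2, h))
    cs = slice(max(c - 1, 0), min(c + 2, w))
    win = skel[rs, cs].copy()
    win[r - rs.start, c - cs.start] = False
    _, n_comp = ndi.label(win, structure=np.ones((3, 3), dtype=int))
    return n_comp == 1


def _remove_staircase_pixels(skel: np.ndarray) -> np.ndarray:
    """Drop 8-redundant pixels: a non-endpoint pixel whose neighbours remain
    8-connected without it fills a staircase corner (or a thick junction
    corner) and can be removed without changing topology.  Thinning leaves
    such pixels on anti-aliased band edges, where they masquerade as 3-way
    junctions.  Removal is sequential: each removal re-checks its
    neighbourhood, so a chain of corners cannot be cut through."""
    skel = skel.copy()
    changed = True
    while changed:
        changed = False
        neighbours = ndi.convolve(skel.astype(np.uint8), _NEIGHBOUR_KERNEL, mode="constant")
        for r, c in np.argwhere(skel & (neighbours >= 2)):
            if _neighbours_connected_without(skel, r, c):
                skel[r, c] = False
                changed = True
    return skel


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to a 1-px-wide, topology-preserving skeleton.

    Zhang-Suen thinning followed by staircase-corner cleanup, so that the
    result is minimal: no pixel can be removed without breaking connectivity.
    """
    mask = np.asarray(mask, dtype=bool)
    return _remove_staircase_pixels(morphology.skeletonize(mask))


def prune_spurs(skeleton: np.ndarray, min_length: int = 10, iterations: int = 2) -> np.ndarray:
    """Remove short dangling twigs (spurs) from a skeleton.

    A spur is a skeleton segment shorter than ``min_length`` pixels that hangs
    off exactly one junction cluster; such twigs are artifacts of boundary
    noise on the binarized filament bands and would otherwise count as branch
    points.  Segments linking two junctions (bridges) and isolated short
    filaments are never removed, so true structure is preserved.
    """
    skel = np.asarray(skeleton, dtype=bool).copy()
    eight = np.ones((3, 3), dtype=int)
    for _ in range(iterations):
        neighbours = ndi.convolve(skel.astype(np.uint8), _NEIGHBOUR_KERNEL, mode="constant")
        branch = skel & (neighbours >= 3)
        if not branch.any():
            break
        clusters, _ = ndi.label(branch, structure=eight)
        segments, n_seg = ndi.label(skel & ~branch, structure=eight)
        removed_any = False
        for s in range(1, n_seg + 1):
            seg = segments == s
            if seg.sum() >= min_length:
                continue
            grown = ndi.binary_dilation(seg, structure=eight.astype(bool))
            touched = np.unique(clusters[grown & branch])
            if touched.size == 1:  # dangles off a single junction: a spur
                skel[seg] = False
                removed_any = True
        if not removed_any:
            break
        skel = _remove_staircase_pixels(skel)
    return skel


_NEIGHBOUR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def detect_branchpoints(skeleton: np.ndarray) -> tuple[int, np.ndarray]:
    """Count branch points of a 1-px skeleton.

    A branch pixel has >= 3 skeleton neighbours in 8-connectivity.  Thinning can
    emit small clusters of such pixels at a single junction, so 8-connected
    clusters of branch pixels are merged and counted once.  Returns the count
    and the branch-pixel mask.
    """
    skel = np.asarray(skeleton, dtype=bool)
    neighbours = ndi.convolve(skel.astype(np.uint8), _NEIGHBOUR_KERNEL, mode="constant")
    branch = skel & (neighbours >= 3)
    _, count = ndi.label(branch, structure=np.ones((3, 3), dtype=int))
    return int(count), branch


def skeleton_length(skeleton: np.ndarray, diagonal_weighting: bool = False) -> float:
    """Skeleton length in pixels.

    Default: the pixel count (the convention of the density definitions here).
    With ``diagonal_weighting``, length is measured along 8-connected edges,
    axial steps counting 1 and diagonal steps sqrt(2); isolated pixels count 1.
    """
    skel = np.asarray(skeleton, dtype=bool)
    if not diagonal_weighting:
        return float(skel.sum())
    axial = np.count_nonzero(skel[1:, :] & skel[:-1, :]) + np.count_nonzero(
        skel[:, 1:] & skel[:, :-1]
    )
    diag = np.count_nonzero(skel[1:, 1:] & skel[:-1, :-1]) + np.count_nonzero(
        skel[1:, :-1] & skel[:-1, 1:]
    )
    neighbours = ndi.convolve(skel.astype(np.uint8), _NEIGHBOUR_KERNEL, mode="constant")
    isolated = int(np.count_nonzero(skel & (neighbours == 0)))
    return float(axial + np.sqrt(2.0) * diag + isolated)


def measure(
    mask: CellMask,
    skeleton: np.ndarray,
    branchpoint_count: int,
    diagonal_weighting: bool = False,
) -> MorphometryResult:
    """Combine skeleton and branch-point measurements into the per-cell result."""
    if mask.area <= 0:
        raise ValueError("cell mask area must be positive")
    length = skeleton_length(skeleton, diagonal_weighting)
    mt_density = length / mask.area
    if length > 0:
        crossing_density = branchpoint_count / length
        defined = True
    else:
        crossing_density = float("nan")
        defined = False
    return MorphometryResult(
        skeleton=np.asarray(skeleton, dtype=bool),
        skeleton_length=length,
        branchpoint_count=int(branchpoint_count),
        mt_density=float(mt_density),
        crossing_density=float(crossing_density),
        crossing_density_defined=defined,
    )
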