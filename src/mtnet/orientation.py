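"""Axial orientation of the microtubule signal and its local dispersion.

Per-pixel orientation is found with a rotating morphological filter: the image
(by default the binarized MT mask) is opened with a digitized line element of
fixed length at each angle of a coarse axial grid (0..170 deg in 10-deg steps;
microtubules carry no polarity information, so angles live in [0, 180)), and
the angle of maximal response wins, ties going to the smallest angle.

Local order is then quantified by the mean resultant length of the doubled
angles inside a sliding circular window:

    S = | mean over MT pixels in window of exp(2 i theta) |      in [0, 1]

Doubling maps axial data onto the full circle so that theta and theta+180 are
identified; S is 1 when all filaments in the window are parallel and falls
toward 0 as orientations disperse.  (Conventionally the *circular variance* of
the doubled angles is 1 - S; this module reports S, the is-parallel score.)
The per-cell statistic is the arithmetic mean of S over all MT pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import draw

__all__ = [
    "OrientationConfig",
    "OrientationField",
    "AlignmentMap",
    "line_element",
    "orientation_map",
    "alignment_map",
    "cell_alignment",
]


@dataclass(frozen=True)
class OrientationConfig:
    """Parameters of the rotating-filter orientation analysis.

    element_length : odd length (px) of the linear structuring element.
    angle_step : spacing (deg) of the axial angle grid {0, step, ..., <180}.
    window_diameter : odd diameter (px) of the circular dispersion window.
    """

    element_length: int = 11
    angle_step: float = 10.0
    window_diameter: int = 51

    def __post_init__(self) -> None:
        if self.element_length < 3 or self.element_length % 2 == 0:
            raise ValueError("element_length must be odd and >= 3")
        if not 0 < self.angle_step <= 90 or 180.0 % self.angle_step:
            raise ValueError("angle_step must divide 180")
        if self.window_diameter < 1 or self.window_diameter % 2 == 0:
            raise ValueError("window_diameter must be odd")

    @property
    def angle_set(self) -> np.ndarray:
        """Axial angle grid in degrees, [0, 180), ascending."""
        return np.arange(0.0, 180.0, self.angle_step)


@dataclass(frozen=True)
class OrientationField:
    """Per-pixel best axial angle (deg, in [0,180)), its filter response, and
    the validity (MT-pixel) mask."""

    angle: np.ndarray
    response: np.ndarray
    valid: np.ndarray


@dataclass(frozen=True)
class AlignmentMap:
    """Per-pixel angle-doubled resultant length S in [0,1]; invalid where the
    window contains no MT pixel."""

    S: np.ndarray
    valid: np.ndarray


def line_element(length: int, angle_deg: float) -> np.ndarray:
    """Digitized (Bresenham) line of ``length`` px at axial angle ``angle_deg``,
    centered in an odd square footprint.

    Angle convention: 0 deg is horizontal (along columns), angles increase
    counter-clockwise on screen (row index decreasing), matching the usual
    image-rotation convention.
    """
    half = (length - 1) / 2.0
    theta = np.deg2rad(angle_deg)
    dr, dc = -np.sin(theta), np.cos(theta)
    c0 = (length - 1) // 2
    r0_px = c0 + int(round(half * dr))
    c0_px = c0 + int(round(half * dc))
    r1_px = c0 - int(round(half * dr))
    c1_px = c0 - int(round(half * dc))
    fp = np.zeros((length, length), dtype=bool)
    rr, cc = draw.line(r0_px, c0_px, r1_px, c1_px)
    fp[rr, cc] = True
    return fp


def orientation_map(
    data: np.ndarray, cfg: OrientationConfig | None = None, mt_mask: np.ndarray | None = None
) -> OrientationField:
    """Rotating-filter orientation: per pixel, the angle of maximal opening response.

    ``data`` may be a binary MT mask (default route: binary opening =
    erosion then dilation with the line element) or a grayscale image
    (grayscale opening).  Ties at equal maximal response resolve to the
    smallest angle.  ``mt_mask`` restricts the validity mask; for binary input
    it defaults to the input itself.
    """
    cfg = cfg or OrientationConfig()
    data = np.asarray(data)
    if min(data.shape) < cfg.element_length:
        raise ValueError("image smaller than the structuring element")
    binary = data.dtype == bool
    angles = cfg.angle_set
    responses = np.empty((angles.size,) + data.shape, dtype=float)
    for i, ang in enumerate(angles):
        fp = line_element(cfg.element_length, ang)
        if binary:
            opened = ndi.binary_opening(data, structure=fp)
            responses[i] = opened.astype(float)
        else:
            responses[i] = ndi.grey_opening(data.astype(float), footprint=fp)
    best = np.argmax(responses, axis=0)  # first max -> smallest angle on ties
    angle = angles[best]
    response = np.take_along_axis(responses, best[None], axis=0)[0]
    if mt_mask is None:
        if not binary:
            raise ValueError("mt_mask is required for grayscale input")
        valid = data.copy()
    else:
        valid = np.asarray(mt_mask, dtype=bool)
    return OrientationField(angle=angle, response=response, valid=valid)


def _disk_kernel(diameter: int) -> np.ndarray:
    r = (diameter - 1) // 2
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx <= r * r).astype(float)


def alignment_map(field: OrientationField, cfg: OrientationConfig | None = None) -> AlignmentMap:
    """Angle-doubled resultant length of MT orientations in a sliding circular window.

    For each pixel, over the MT pixels inside the disk of the configured
    diameter (truncated at image borders), S = |mean exp(2 i theta)|.  Pixels
    whose window holds no MT pixel are marked invalid.
    """
    cfg = cfg or OrientationConfig()
    kernel = _disk_kernel(cfg.window_diameter)
    theta2 = np.deg2rad(2.0 * field.angle)
    w = field.valid.astype(float)
    sum_c = ndi.convolve(np.cos(theta2) * w, kernel, mode="constant")
    sum_s = ndi.convolve(np.sin(theta2) * w, kernel, mode="constant")
    n = ndi.convolve(w, kernel, mode="constant")
    valid = n > 0.5
    S = np.zeros_like(n)
    np.divide(np.hypot(sum_c, sum_s), n, out=S, where=valid)
    np.clip(S, 0.0, 1.0, out=S)
    return AlignmentMap(S=S, valid=valid)


def cell_alignment(amap: AlignmentMap, mt_mask: np.ndarray) -> float:
    """Per-cell order statistic: mean of S over the MT pixels.

    Close to 1 means the microtubules are locally parallel over most of the
    cell (on the length scale of the window); smaller values indicate locally
    crossing/disordered networks.
    """
    sel = np.asarray(mt_mask, dtype=bool) & amap.valid
    if not sel.any():
        raise ValueError("no MT pixels to average over")
    return float(amap.S[sel].mean())
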