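"""Ground-truthed synthetic inputs: filament-network images and AFM approach curves.

The network generator draws straight filaments (infinite lines clipped to the
frame; the real microtubules are long and only gently curved, and straight
segments give exact crossing counts and angles), records the exact ground
truth — per-filament axial angle, centerline pixels, pairwise crossing count,
axial resultant length — *before* rendering, then renders by dilating the
centerlines to the filament width, Gaussian blurring, and adding background
plus Gaussian noise.  Re-rendering with a different noise realisation never
changes the ground truth.

The curve generator forward-models the Sneddon sphere contact: beyond the
contact point the cantilever deflection d solves the self-consistency
``k d = F(delta)`` with ``delta = (z - z0) - d`` (the piezo travel is shared
between indentation and cantilever bending), by bracketed root finding.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage as ndi, optimize
from skimage import draw, morphology

from .afm import ForceCurve, sneddon_force
from .morphometry import FilamentImage

__all__ = [
    "NetworkSpec",
    "NetworkGroundTruth",
    "CurveSpec",
    "generate_filament_image",
    "generate_force_curve",
    "axial_resultant_length",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Recipe for one synthetic filament-network image.

    orientation_mode:
      * ``single_angle``       — every filament at ``mean_angle``
      * ``uniform_axial``      — angles uniform on [0, 180)
      * ``wrapped_dispersion`` — von Mises on the doubled angle with
        concentration ``dispersion`` (0 = uniform), mean ``2*mean_angle``,
        halved back to the axial range; matches the angle-doubling analysis
        convention.

    placement:
      * ``random`` — anchors uniform over the frame
      * ``spaced`` — anchors offset evenly along each filament's normal, so
        same-angle filaments stay non-overlapping (parallel test networks).

    Intensity units are arbitrary (16-bit scale on disk): the rendered
    centerlines peak near ``foreground_level`` above ``background_level``,
    with additive Gaussian noise of SD ``noise_sd``.
    """

    image_size: tuple[int, int] = (512, 512)
    n_filaments: int = 60
    orientation_mode: str = "uniform_axial"
    placement: str = "random"
    mean_angle: float = 0.0
    dispersion: float = 0.0
    filament_width: int = 3
    blur_sigma: float = 2.0
    background_level: float = 100.0
    foreground_level: float = 600.0
    noise_sd: float = 20.0
    pixel_size: float = 20.0
    seed: int = 0
    noise_seed: int | None = None  # defaults to seed; geometry never depends on it

    def validate(self) -> None:
        h, w = self.image_size
        if h < 64 or w < 64:
            raise ValueError("image_size must be at least 64x64")
        if self.n_filaments < 0:
            raise ValueError("n_filaments must be non-negative")
        if self.orientation_mode not in ("single_angle", "uniform_axial", "wrapped_dispersion"):
            raise ValueError(f"orientation_mode unknown: {self.orientation_mode!r}")
        if self.placement not in ("random", "spaced"):
            raise ValueError(f"placement unknown: {self.placement!r}")
        if not 0.0 <= self.mean_angle < 180.0:
            raise ValueError("mean_angle must lie in [0, 180)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.filament_width < 1:
            raise ValueError("filament_width must be >= 1")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class NetworkGroundTruth:
    """Exact, render-independent truth of a synthetic network."""

    angles: np.ndarray  # per-filament axial angle, deg in [0, 180)
    segments: np.ndarray  # (n, 2, 2) clipped endpoints as (row, col) floats
    centerline: np.ndarray  # boolean mask of Bresenham centerline pixels
    centerline_length: int  # number of distinct centerline pixels
    crossing_count: int  # pairwise centerline intersections inside the frame
    resultant_length: float  # |mean exp(2 i theta)| of the angle population


def axial_resultant_length(angles_deg: np.ndarray) -> float:
    """Mean resultant length of doubled angles: |mean exp(2 i theta)|, in [0,1]."""
    angles_deg = np.asarray(angles_deg, dtype=float)
    if angles_deg.size == 0:
        return 0.0
    z = np.exp(2j * np.deg2rad(angles_deg))
    return float(abs(z.mean()))


def _sample_angle(spec: NetworkSpec, rng: np.random.Generator) -> float:
    if spec.orientation_mode == "single_angle":
        return float(spec.mean_angle)
    if spec.orientation_mode == "uniform_axial" or spec.dispersion == 0:
        return float(rng.uniform(0.0, 180.0))
    # wrapped_dispersion: von Mises on the doubled angle, halved back
    doubled = rng.vonmises(np.deg2rad(2.0 * spec.mean_angle), spec.dispersion)
    return float(np.mod(np.rad2deg(doubled) / 2.0, 180.0))


def _clip_line(anchor: np.ndarray, angle_deg: float, shape: tuple[int, int]):
    """Clip the infinite line through ``anchor`` at axial ``angle_deg`` to the
    frame [0, H-1] x [0, W-1]; returns (p0, p1) as (row, col) or None if the
    line misses the frame.

    Liang-Barsky style: walk t along the unit direction and intersect with the
    four frame edges.
    """
    h, w = shape
    theta = np.deg2rad(angle_deg)
    d = np.array([-np.sin(theta), np.cos(theta)])  # (dr, dc)
    t_lo, t_hi = -np.inf, np.inf
    for axis, limit in ((0, h - 1), (1, w - 1)):
        p, delta = anchor[axis], d[axis]
        if abs(delta) < 1e-12:
            if not (0.0 <= p <= limit):
                return None
            continue
        t0, t1 = (0.0 - p) / delta, (limit - p) / delta
        t_lo = max(t_lo, min(t0, t1))
        t_hi = min(t_hi, max(t0, t1))
    if t_lo >= t_hi:
        return None
    return anchor + t_lo * d, anchor + t_hi * d


def _segments_cross(p0, p1, q0, q1) -> bool:
    """True if open segments p and q intersect at a single interior point."""
    r = p1 - p0
    s = q1 - q0
    denom = r[0] * s[1] - r[1] * s[0]
    if abs(denom) < 1e-12:  # parallel or collinear: no point crossing
        return False
    qp = q0 - p0
    t = (qp[0] * s[1] - qp[1] * s[0]) / denom
    u = (qp[0] * r[1] - qp[1] * r[0]) / denom
    eps = 1e-9
    return eps < t < 1 - eps and eps < u < 1 - eps


def generate_filament_image(spec: NetworkSpec) -> tuple[FilamentImage, NetworkGroundTruth]:
    """Render a filament network and return it with its exact ground truth.

    Deterministic for a given spec: one seeded generator drives angle and
    anchor sampling and the noise field, in a fixed order.
    """
    spec.validate()
    h, w = spec.image_size
    n = spec.n_filaments
    # Per-filament substreams keyed by index: filament i of an n-filament
    # network is identical to filament i of an (n+1)-filament network with the
    # same seed, so networks with the same seed are nested.
    children = np.random.SeedSequence(spec.seed).spawn(n) if n else []

    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    if spec.placement == "spaced" and n > 0:
        # evenly spaced perpendicular offsets keep same-angle filaments apart
        extent = 0.9 * min(h, w)
        offsets = (np.arange(n) - (n - 1) / 2.0) / max(n, 1) * extent
    segments = []
    kept_angles = []
    for idx in range(n):
        rng_i = np.random.default_rng(children[idx])
        ang = _sample_angle(spec, rng_i)
        if spec.placement == "spaced":
            theta = np.deg2rad(ang)
            normal = np.array([np.cos(theta), np.sin(theta)])  # (dr, dc) unit normal
            anchor = center + offsets[idx] * normal
        else:
            anchor = rng_i.uniform([0.0, 0.0], [h - 1.0, w - 1.0])
        clipped = _clip_line(anchor, ang, (h, w))
        if clipped is None:  # cannot happen for interior anchors, kept for safety
            continue
        segments.append(clipped)
        kept_angles.append(ang)
    kept_angles = np.asarray(kept_angles, dtype=float)

    centerline = np.zeros((h, w), dtype=bool)
    for p0, p1 in segments:
        rr, cc = draw.line(
            int(round(p0[0])), int(round(p0[1])), int(round(p1[0])), int(round(p1[1]))
        )
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        centerline[rr[keep], cc[keep]] = True

    crossings = 0
    for i in range(len(segments)):
        for j in range(i + 1, len(segments)):
            if _segments_cross(*segments[i], *segments[j]):
                crossings += 1

    truth = NetworkGroundTruth(
        angles=kept_angles,
        segments=np.array(segments, dtype=float).reshape(-1, 2, 2),
        centerline=centerline,
        centerline_length=int(centerline.sum()),
        crossing_count=crossings,
        resultant_length=axial_resultant_length(kept_angles),
    )

    canvas = centerline.astype(float)
    if spec.filament_width > 1:
        radius = (spec.filament_width - 1) // 2
        canvas = morphology.dilation(
            centerline, footprint=morphology.disk(max(radius, 1))
        ).astype(float)
    if spec.blur_sigma > 0:
        canvas = ndi.gaussian_filter(canvas, spec.blur_sigma)
        peak = canvas.max()
        if peak > 0:
            canvas = canvas / peak
    img = spec.background_level + spec.foreground_level * canvas
    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng(
            spec.seed if spec.noise_seed is None else spec.noise_seed
        )
        img = img + noise_rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    return (
        FilamentImage(img, pixel_size=spec.pixel_size, identifier=f"synth_seed{spec.seed}"),
        truth,
    )


# ---------------------------------------------------------------------------
# AFM approach curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveSpec:
    """Recipe for one forward-modelled AFM approach curve.

    Defaults follow the instrument configuration of the experiments this
    emulates: a 4.5 um silica bead (radius 2250 nm) on a soft cantilever
    (k = 0.08 N/m), Poisson ratio 0.5 for the cell.
    """

    youngs_modulus: float = 1000.0  # Pa
    poisson_ratio: float = 0.5
    bead_radius: float = 2250.0  # nm
    spring_constant: float = 0.08  # N/m
    contact_point: float = 1000.0  # nm, within [0, z_range]
    z_range: float = 2500.0  # nm, approach sweep 0..z_range
    z_step: float = 2.0  # nm
    deflection_noise_sd: float = 1.0  # nm
    baseline_slope: float = 0.0  # nm deflection per nm z (pre-contact drift)
    seed: int = 0

    def validate(self) -> None:
        if not self.youngs_modulus > 0:
            raise ValueError("youngs_modulus must be positive")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        if not self.bead_radius > 0:
            raise ValueError("bead_radius must be positive")
        if not self.spring_constant > 0:
            raise ValueError("spring_constant must be positive")
        if not 0.0 <= self.contact_point <= self.z_range:
            raise ValueError("contact_point must lie within the z range")
        if not self.z_step > 0:
            raise ValueError("z_step must be positive")
        if self.deflection_noise_sd < 0:
            raise ValueError("deflection_noise_sd must be non-negative")


def _contact_deflection(dz: float, spec: CurveSpec) -> float:
    """Solve k d = F((dz) - d) for the physical deflection d at piezo travel dz
    past contact.  The solution is unique: the left side increases in d, the
    right side decreases."""
    if dz <= 0:
        return 0.0

    def g(d_val: float) -> float:
        return spec.spring_constant * d_val - sneddon_force(
            dz - d_val, spec.youngs_modulus, spec.poisson_ratio, spec.bead_radius
        )

    return optimize.brentq(g, 0.0, dz, xtol=1e-12, rtol=1e-10)


def generate_force_curve(spec: CurveSpec) -> ForceCurve:
    """Forward-model one approach curve from the Sneddon sphere contact law.

    Pre-contact deflection is the linear baseline (plus noise); past contact
    the noiseless deflection solves the cantilever/contact self-consistency and
    is monotone non-decreasing.  Raises when the sweep would drive the
    indentation to the bead radius.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    z = np.arange(0.0, spec.z_range + 0.5 * spec.z_step, spec.z_step)
    d = spec.baseline_slope * z
    dz_max = spec.z_range - spec.contact_point
    if dz_max > 0:
        d_end = _contact_deflection(dz_max, spec)
        if (dz_max - d_end) >= spec.bead_radius:
            raise ValueError("z_range drives indentation beyond the bead radius")
    past = z > spec.contact_point
    for i in np.nonzero(past)[0]:
        d[i] += _contact_deflection(z[i] - spec.contact_point, spec)
    if spec.deflection_noise_sd > 0:
        d = d + rng.normal(0.0, spec.deflection_noise_sd, size=d.shape)
    return ForceCurve(
        z=z,
        d=d,
        k=spec.spring_constant,
        Rs=spec.bead_radius,
        nu=spec.poisson_ratio,
        identifier=f"synth_seed{spec.seed}",
    )


def curve_metadata(spec: CurveSpec) -> dict:
    """Sidecar metadata for a generated curve (JSON-serializable)."""
    return asdict(spec)
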