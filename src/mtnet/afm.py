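"""AFM force-spectroscopy analysis: Sneddon spherical-indenter contact mechanics,
force-indentation conversion, and Young's-modulus estimation.

The contact model is the classical Sneddon solution for a rigid sphere of radius
``Rs`` indenting an elastic half-space of Young's modulus ``E`` and Poisson
ratio ``nu``, parametrized by the contact radius ``a``::

    F(a)     = E/(1-nu^2) * [ (a^2 + Rs^2)/2 * ln((Rs+a)/(Rs-a)) - a*Rs ]
    delta(a) = a/2 * ln((Rs+a)/(Rs-a))

``delta(a)`` is strictly increasing on (0, Rs) so the pair defines a unique
force-indentation law F(delta).  In the small-indentation limit (a << Rs) it
reduces to the Hertz formula F = (4/3) E/(1-nu^2) sqrt(Rs) delta^(3/2).

Units at the interface: nm for lengths and indentation, Pa for moduli, N/m for
the cantilever spring constant, nN for forces.  E in Pa times nm^2 is 1e-18 N,
hence the 1e-9 factor from Pa*nm^2 to nN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ForceCurve",
    "IndentationCurve",
    "HertzFitResult",
    "FitConfig",
    "sneddon_delta_of_a",
    "sneddon_force_of_a",
    "sneddon_contact_radius",
    "sneddon_force",
    "hertz_force",
    "to_force_indentation",
    "fit_hertz",
    "batch_fit",
    "summarize_cells",
    "compare_groups",
]

_PA_NM2_TO_NN = 1e-9  # Pa * nm^2 = 1e-18 N = 1e-9 nN


class ModelRangeError(ValueError):
    """Requested indentation is outside the sphere-contact model's range."""


class BaselineError(ValueError):
    """Pre-contact baseline cannot be determined from the curve."""


@dataclass(frozen=True)
class ForceCurve:
    """An AFM approach curve with its calibration constants.

    Parameters
    ----------
    z : ndarray
        Piezo displacement samples in nm, strictly increasing (approach).
    d : ndarray
        Cantilever deflection samples in nm, same length as ``z``.
    k : float
        Cantilever spring constant in N/m.  Force is ``k * d`` (nN for nm
        deflection).
    Rs : float
        Indenter bead radius in nm.
    nu : float
        Poisson ratio of the sample, in [0, 0.5].  0.5 (incompressible) is
        the usual choice for cells.
    identifier : str
        Label used in batch reports.
    """

    z: np.ndarray
    d: np.ndarray
    k: float
    Rs: float
    nu: float = 0.5
    identifier: str = ""

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "d", d)
        if z.ndim != 1 or z.shape != d.shape:
            raise ValueError("z and d must be 1-D arrays of equal length")
        if z.size and not np.all(np.diff(z) > 0):
            raise ValueError("z must be strictly increasing")
        if not self.k > 0:
            raise ValueError("k must be positive")
        if not self.Rs > 0:
            raise ValueError("Rs must be positive")
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError("nu must lie in [0, 0.5]")


@dataclass(frozen=True)
class IndentationCurve:
    """Force-indentation samples derived from an approach curve.

    ``delta`` is indentation in nm (negative before contact), ``F`` is force in
    nN (``k * baseline-corrected deflection``), ``z0`` the contact point in nm.
    ``pre_contact`` flags samples with delta < 0.
    """

    delta: np.ndarray
    F: np.ndarray
    z0: float
    pre_contact: np.ndarray


@dataclass(frozen=True)
class HertzFitResult:
    """Outcome of a Sneddon-model fit at one indentation depth."""

    E: float  # Young's modulus, Pa
    z0: float  # fitted contact point, nm
    fit_depth: float  # indentation window upper edge, nm
    rms: float  # residual RMS over the fit window, nN
    n_points: int  # samples inside the fit window


@dataclass(frozen=True)
class FitConfig:
    """Tunables of :func:`fit_hertz`.

    baseline_fraction : leading fraction of samples used for the straight-line
        pre-contact baseline (default 0.3).
    E_init / E_bounds : initial guess and box for the modulus, Pa.
    z0_init : optional explicit contact-point guess (nm); if None it is placed
        where force first exceeds ``contact_snr`` times the baseline residual SD.
    fit_z0 : set False to freeze z0 at its initial estimate (pre-estimation
        mode) instead of fitting it jointly with E.
    max_nfev : optimizer budget; exceeding it raises with the last iterate.
    min_points : minimum number of in-window samples required.
    """

    baseline_fraction: float = 0.3
    E_init: float = 1000.0
    E_bounds: tuple[float, float] = (1.0, 1e6)
    z0_init: float | None = None
    fit_z0: bool = True
    contact_snr: float = 3.0
    max_nfev: int = 10000
    min_points: int = 10
    window_iterations: int = 3


# ---------------------------------------------------------------------------
# Sneddon sphere model
# ---------------------------------------------------------------------------

def sneddon_delta_of_a(a: float, Rs: float) -> float:
    """Indentation depth delta(a) = (a/2) ln((Rs+a)/(Rs-a)), in nm."""
    a = np.asarray(a, dtype=float)
    return 0.5 * a * np.log((Rs + a) / (Rs - a))


def sneddon_force_of_a(a: float, E: float, nu: float, Rs: float) -> float:
    """Load F(a) in nN for contact radius ``a`` (nm) and modulus ``E`` (Pa)."""
    a = np.asarray(a, dtype=float)
    bracket = 0.5 * (a * a + Rs * Rs) * np.log((Rs + a) / (Rs - a)) - a * Rs
    return (E / (1.0 - nu * nu)) * bracket * _PA_NM2_TO_NN


def _contact_radius_newton(delta: np.ndarray, Rs: float) -> np.ndarray:
    """Vectorized inversion of delta(a) by safeguarded Newton iteration.

    delta(a) is strictly increasing and smooth on (0, Rs); the Hertzian guess
    a0 = sqrt(delta * Rs) starts Newton close to the root for delta << Rs, and
    iterates are clipped into (0, Rs) so the bracket is never left.
    """
    a_cap = Rs * (1.0 - 1e-12)
    a = np.clip(np.sqrt(delta * Rs), 0.0, Rs * (1.0 - 1e-6))
    for _ in range(100):
        log_term = np.log((Rs + a) / (Rs - a))
        f = 0.5 * a * log_term - delta
        fp = 0.5 * log_term + a * Rs / (Rs * Rs - a * a)
        step = np.divide(f, fp, out=np.zeros_like(f), where=fp > 0)
        a_new = np.clip(a - step, 0.0, a_cap)
        if np.all(np.abs(a_new - a) <= 1e-13 * Rs):
            a = a_new
            break
        a = a_new
    return a


def sneddon_contact_radius(delta: float, Rs: float) -> float:
    """Invert delta(a) for the contact radius ``a`` (unique on (0, Rs)).

    Raises :class:`ModelRangeError` when the requested depth would push the
    contact radius to the bead radius.
    """
    if delta < 0:
        raise ModelRangeError("indentation must be non-negative")
    if delta == 0:
        return 0.0
    hi = Rs * (1.0 - 1e-12)
    if delta >= sneddon_delta_of_a(hi, Rs):
        raise ModelRangeError("indentation out of model range (contact radius -> Rs)")
    return float(_contact_radius_newton(np.asarray([delta], dtype=float), Rs)[0])


def sneddon_force(delta, E: float, nu: float, Rs: float):
    """Force F(delta) of the Sneddon sphere model.

    Parameters are indentation ``delta`` in nm (scalar or array), modulus ``E``
    in Pa, Poisson ratio ``nu`` and bead radius ``Rs`` in nm.  Returns nN.
    """
    delta_arr = np.atleast_1d(np.asarray(delta, dtype=float))
    if np.any(delta_arr < 0):
        raise ModelRangeError("indentation must be non-negative")
    hi = Rs * (1.0 - 1e-12)
    if np.any(delta_arr >= sneddon_delta_of_a(hi, Rs)):
        raise ModelRangeError("indentation out of model range (contact radius -> Rs)")
    a = _contact_radius_newton(delta_arr, Rs)
    out = np.where(a > 0, sneddon_force_of_a(a, E, nu, Rs), 0.0)
    return out if np.ndim(delta) else float(out[0])


def hertz_force(delta, E: float, nu: float, Rs: float):
    """Hertzian small-indentation limit F = (4/3) E/(1-nu^2) sqrt(Rs) delta^1.5 (nN)."""
    delta = np.asarray(delta, dtype=float)
    return (4.0 / 3.0) * (E / (1.0 - nu * nu)) * np.sqrt(Rs) * delta**1.5 * _PA_NM2_TO_NN


# ---------------------------------------------------------------------------
# Approach curve -> force-indentation
# ---------------------------------------------------------------------------

def _fit_baseline(z: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares straight line through (z, d); returns (coeffs, residual SD)."""
    coeffs = np.polyfit(z, d, 1)
    resid = d - np.polyval(coeffs, z)
    return coeffs, float(np.std(resid))


def to_force_indentation(
    curve: ForceCurve, z0: float, min_pre_contact: int = 5
) -> IndentationCurve:
    """Convert an approach curve to force-indentation data at a known contact point.

    The pre-contact baseline (a straight line in z, capturing photodiode offset
    and drift) is fitted to the samples with ``z <= z0`` and subtracted from the
    deflection.  Then ``F = k * (d - baseline)`` and the indentation is the
    piezo travel past contact minus the cantilever bending,
    ``delta = (z - z0) - (d - baseline)``.
    """
    if not (curve.z[0] <= z0 <= curve.z[-1]):
        raise ValueError("z0 must lie within the recorded z range")
    pre = curve.z <= z0
    if int(pre.sum()) < min_pre_contact:
        raise BaselineError(
            f"baseline underdetermined: {int(pre.sum())} pre-contact samples "
            f"(minimum {min_pre_contact})"
        )
    coeffs, _ = _fit_baseline(curve.z[pre], curve.d[pre])
    d_corr = curve.d - np.polyval(coeffs, curve.z)
    F = curve.k * d_corr  # N/m * nm = nN
    delta = (curve.z - z0) - d_corr
    return IndentationCurve(delta=delta, F=F, z0=float(z0), pre_contact=delta < 0)


# ---------------------------------------------------------------------------
# Nonlinear least squares for (E, z0)
# ---------------------------------------------------------------------------

def _corrected_deflection(curve: ForceCurve, cfg: FitConfig) -> tuple[np.ndarray, float]:
    n_base = max(2, int(round(cfg.baseline_fraction * curve.z.size)))
    coeffs, noise_sd = _fit_baseline(curve.z[:n_base], curve.d[:n_base])
    return curve.d - np.polyval(coeffs, curve.z), noise_sd


def _initial_z0(curve: ForceCurve, d_corr: np.ndarray, noise_sd: float, cfg: FitConfig) -> float:
    """Place the initial contact point where the (smoothed) deflection last sits
    below ``contact_snr`` times the baseline noise SD.  Scanning for the *last*
    sub-threshold sample makes the estimate immune to isolated pre-contact
    noise spikes; the deflection past contact grows monotonically, so the last
    crossing is the physical one."""
    if cfg.z0_init is not None:
        return float(cfg.z0_init)
    width = min(11, max(1, d_corr.size // 10))
    smooth = np.convolve(d_corr, np.ones(width) / width, mode="same")
    thresh = max(cfg.contact_snr * noise_sd / np.sqrt(width), 1e-9)
    below = np.nonzero(smooth < thresh)[0]
    idx = below[-1] if below.size else curve.z.size // 2
    return float(curve.z[idx])


def fit_hertz(curve: ForceCurve, fit_depth: float, config: FitConfig | None = None) -> HertzFitResult:
    """Estimate Young's modulus by fitting the Sneddon sphere model to one curve.

    A bounded nonlinear least-squares problem over (E, z0) minimizes the force
    residuals over the samples with indentation in [0, ``fit_depth``] nm plus
    the pre-contact region (where the model force is zero).  Because the fit
    window itself depends on z0, the window is re-selected from the current z0
    estimate for a few outer iterations until it is stable.

    Raises on non-convergence (diagnostic carries the last iterate) and when
    fewer than ``config.min_points`` samples fall inside the window.
    """
    cfg = config or FitConfig()
    if not fit_depth > 0:
        raise ValueError("fit_depth must be positive")
    if curve.z.size < cfg.min_points:
        raise ValueError("curve too short to fit")

    d_corr, noise_sd = _corrected_deflection(curve, cfg)
    F_obs = curve.k * d_corr
    z0 = _initial_z0(curve, d_corr, noise_sd, cfg)
    E = float(cfg.E_init)
    z_lo, z_hi = float(curve.z[0]), float(curve.z[-1])

    sel = np.ones_like(curve.z, dtype=bool)
    for _ in range(cfg.window_iterations):
        delta_all = (curve.z - z0) - d_corr
        new_sel = delta_all <= fit_depth
        if int(new_sel.sum()) < cfg.min_points:
            raise ValueError(
                f"fewer than {cfg.min_points} samples inside the fit window"
            )
        z_sel = curve.z[new_sel]
        d_sel = d_corr[new_sel]
        F_sel = F_obs[new_sel]

        def residuals(params: np.ndarray) -> np.ndarray:
            E_p, z0_p = params
            delta = (z_sel - z0_p) - d_sel
            model = np.zeros_like(delta)
            pos = delta > 0
            if np.any(pos):
                model[pos] = sneddon_force(delta[pos], E_p, curve.nu, curve.Rs)
            return model - F_sel

        if cfg.fit_z0:
            x0 = np.array([E, z0])
            lower = np.array([cfg.E_bounds[0], z_lo])
            upper = np.array([cfg.E_bounds[1], z_hi])
        else:
            x0 = np.array([E])
            lower = np.array([cfg.E_bounds[0]])
            upper = np.array([cfg.E_bounds[1]])

            def residuals(params: np.ndarray, _z0=z0) -> np.ndarray:  # noqa: F811
                delta = (z_sel - _z0) - d_sel
                model = np.zeros_like(delta)
                pos = delta > 0
                if np.any(pos):
                    model[pos] = sneddon_force(delta[pos], params[0], curve.nu, curve.Rs)
                return model - F_sel

        res = optimize.least_squares(
            residuals,
            x0,
            bounds=(lower, upper),
            max_nfev=cfg.max_nfev,
            x_scale="jac",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        if res.status <= 0:
            raise RuntimeError(
                f"Hertz fit did not converge ({res.message}); last iterate {res.x}"
            )
        E = float(res.x[0])
        if cfg.fit_z0:
            z0 = float(res.x[1])
        if np.array_equal(new_sel, sel):
            break
        sel = new_sel

    delta_final = (curve.z[sel] - z0) - d_corr[sel]
    in_window = (delta_final >= 0) & (delta_final <= fit_depth)
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return HertzFitResult(
        E=E, z0=z0, fit_depth=float(fit_depth), rms=rms, n_points=int(in_window.sum())
    )


def batch_fit(
    curves,
    depths: tuple[float, ...] = (200.0, 400.0, 600.0),
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """Fit every curve at every configured depth; one row per curve x depth.

    Individual fit failures are recorded in the ``status`` column rather than
    aborting the batch.  Columns: curve_id, depth_nm, E_Pa, z0_nm, rms_nN,
    n_points, status.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to fit")
    rows = []
    for i, curve in enumerate(curves):
        cid = curve.identifier or f"curve{i:03d}"
        for depth in depths:
            try:
                r = fit_hertz(curve, depth, config)
                rows.append(
                    dict(curve_id=cid, depth_nm=depth, E_Pa=r.E, z0_nm=r.z0,
                         rms_nN=r.rms, n_points=r.n_points, status="ok")
                )
            except Exception as exc:  # recorded per row, not fatal
                rows.append(
                    dict(curve_id=cid, depth_nm=depth, E_Pa=np.nan, z0_nm=np.nan,
                         rms_nN=np.nan, n_points=0, status=f"error: {exc}")
                )
    return pd.DataFrame(rows)


def summarize_cells(
    table: pd.DataFrame, cell_of: dict[str, str] | None = None, statistic: str = "median"
) -> pd.DataFrame:
    """Aggregate per-curve moduli to per-cell values (median by default).

    ``cell_of`` maps curve_id -> cell id; when None, every curve is its own cell.
    The median is the default because the 8-10 curves per cell occasionally
    include bad contacts; the mean is available via ``statistic='mean'``.
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    ok = table[table["status"] == "ok"].copy()
    ok["cell_id"] = (
        ok["curve_id"].map(cell_of) if cell_of is not None else ok["curve_id"]
    )
    agg = (
        ok.groupby(["cell_id", "depth_nm"])["E_Pa"]
        .agg(statistic)
        .reset_index()
        .rename(columns={"E_Pa": f"E_Pa_{statistic}"})
    )
    return agg


# ---------------------------------------------------------------------------
# Two-group comparison (rank based)
# ---------------------------------------------------------------------------

def compare_groups(a, b) -> tuple[float, float]:
    """Mann-Whitney U comparison of two samples; returns (U of ``a``, two-sided p).

    Uses the exact rank-sum distribution when both groups have at most 10
    observations and there are no ties, otherwise the normal approximation with
    tie correction.  If every value in both groups is identical the statistic is
    its null mean and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(a.size, b.size) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
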