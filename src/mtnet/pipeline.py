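"""End-to-end orchestration: synthesize -> analyze -> report.

A run is described by a :class:`RunConfig` (usually loaded from YAML).  The
pipeline executes the requested stages in order, records a per-item status for
every input, and writes deterministic CSV tables plus a provenance block
(config echo, config hash, package version, seed) into the output directory.
Identical config + seed yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import afm, io, morphometry as mm, orientation as ori, synth

logger = logging.getLogger("mtnet")

MORPH_COLUMNS = [
    "id",
    "area_px2",
    "skeleton_length_px",
    "branchpoints",
    "mt_density",
    "crossing_density",
    "angular_alignment",
    "status",
]


@dataclass(frozen=True)
class MorphParams:
    # The threshold is the run's "manual threshold": chosen once by inspecting
    # the top-hat output (filament ridges sit well above the noise floor) and
    # applied to every image.  200 suits the synthetic default intensity scale.
    threshold: float = 200.0
    tophat_radius: int = 5
    smooth_sigma: float = 10.0
    spur_length: int = 10  # 0 disables skeleton spur pruning
    diagonal_weighting: bool = False


@dataclass(frozen=True)
class OrientationParams:
    element_length: int = 11
    angle_step: float = 10.0
    window_diameter: int = 51

    def to_config(self) -> ori.OrientationConfig:
        return ori.OrientationConfig(
            element_length=self.element_length,
            angle_step=self.angle_step,
            window_diameter=self.window_diameter,
        )


@dataclass(frozen=True)
class AfmParams:
    depths: tuple[float, ...] = (200.0, 400.0, 600.0)
    poisson_ratio: float = 0.5
    E_bounds: tuple[float, float] = (1.0, 1e6)

    def to_config(self) -> afm.FitConfig:
        return afm.FitConfig(E_bounds=tuple(self.E_bounds))


@dataclass(frozen=True)
class SynthParams:
    n_images: int = 3
    n_curves: int = 8
    network: dict = field(default_factory=dict)  # NetworkSpec overrides
    curve: dict = field(default_factory=dict)  # CurveSpec overrides


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one pipeline run."""

    out_dir: str = "results"
    stages: tuple[str, ...] = ("synth", "morph", "afm")
    images_dir: str | None = None  # None -> use the synth stage output
    curves_dir: str | None = None
    seed: int = 0
    overlays: bool = False
    morph: MorphParams = field(default_factory=MorphParams)
    orientation: OrientationParams = field(default_factory=OrientationParams)
    afm: AfmParams = field(default_factory=AfmParams)
    synth: SynthParams = field(default_factory=SynthParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("morph", MorphParams),
            ("orientation", OrientationParams),
            ("afm", AfmParams),
            ("synth", SynthParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                block = dict(kwargs[key])
                for tup_key in ("depths", "E_bounds"):
                    if tup_key in block:
                        block[tup_key] = tuple(block[tup_key])
                kwargs[key] = sub(**block)
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class Report:
    morphometry: pd.DataFrame
    elasticity: pd.DataFrame
    provenance: dict


# ---------------------------------------------------------------------------
# Per-item analysis
# ---------------------------------------------------------------------------

def analyze_image(
    img: mm.FilamentImage,
    morph_params: MorphParams | None = None,
    orientation_params: OrientationParams | None = None,
    overlay_dir: Path | None = None,
) -> dict:
    """Run the full morphometry + orientation analysis on one image.

    Returns the per-cell report row: area, skeleton length, branch points, MT
    density, crossing density, and the angle-doubled alignment statistic.
    With ``overlay_dir`` set, PNG renderings of the intermediate stages
    (binary mask, skeleton + branch points, orientation hue map) are written
    there.
    """
    mp = morph_params or MorphParams()
    op = orientation_params or OrientationParams()
    cell = mm.detect_cell_area(img, mm.CellAreaConfig(smooth_sigma=mp.smooth_sigma))
    enhanced = mm.enhance_tophat(img, mp.tophat_radius)
    binary = mm.binarize(enhanced, mp.threshold) & cell.mask
    skel = mm.skeletonize(binary)
    if mp.spur_length > 0:
        skel = mm.prune_spurs(skel, mp.spur_length)
    n_branch, branch_mask = mm.detect_branchpoints(skel)
    result = mm.measure(cell, skel, n_branch, mp.diagonal_weighting)

    cfg = op.to_config()
    alignment = float("nan")
    field_ = None
    if binary.any():
        field_ = ori.orientation_map(binary, cfg)
        amap = ori.alignment_map(field_, cfg)
        alignment = ori.cell_alignment(amap, binary)

    if overlay_dir is not None:
        _write_overlays(img, binary, skel, branch_mask, field_, overlay_dir)

    return {
        "id": img.identifier,
        "area_px2": cell.area,
        "skeleton_length_px": result.skeleton_length,
        "branchpoints": result.branchpoint_count,
        "mt_density": result.mt_density,
        "crossing_density": result.crossing_density,
        "angular_alignment": alignment,
        "status": "ok",
    }


def _write_overlays(img, binary, skel, branch_mask, field_, out_dir: Path) -> None:
    """PNG renderings of the analysis stages (binary, skeleton+branches, hue map)."""
    import imageio.v3 as iio
    from skimage import color, morphology as skmorph

    out_dir.mkdir(parents=True, exist_ok=True)
    stem = img.identifier or "image"
    lo, hi = float(img.pixels.min()), float(img.pixels.max())
    base = (img.pixels - lo) / (hi - lo) if hi > lo else np.zeros_like(img.pixels)
    overlay = np.stack([base, base, base], axis=-1)
    overlay[skel] = [0.2, 0.4, 1.0]
    overlay[skmorph.dilation(branch_mask, skmorph.disk(2))] = [1.0, 0.2, 0.2]
    iio.imwrite(out_dir / f"{stem}_skeleton.png", (overlay * 255).astype(np.uint8))
    iio.imwrite(out_dir / f"{stem}_binary.png", binary.astype(np.uint8) * 255)
    if field_ is not None:
        hsv = np.stack(
            [field_.angle / 180.0, np.ones_like(field_.angle), binary.astype(float)],
            axis=-1,
        )
        iio.imwrite(
            out_dir / f"{stem}_orientation.png",
            (color.hsv2rgb(hsv) * 255).astype(np.uint8),
        )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _run_synth(cfg: RunConfig, out: Path) -> tuple[Path, Path]:
    img_dir = out / "synthetic_images"
    crv_dir = out / "synthetic_curves"
    img_dir.mkdir(parents=True, exist_ok=True)
    crv_dir.mkdir(parents=True, exist_ok=True)
    for i in range(cfg.synth.n_images):
        spec = synth.NetworkSpec(**{**cfg.synth.network, "seed": cfg.seed + i})
        img, truth = synth.generate_filament_image(spec)
        io.write_image(
            img_dir / f"network_{i:03d}.tiff",
            img,
            ground_truth={
                "crossing_count": truth.crossing_count,
                "centerline_length": truth.centerline_length,
                "resultant_length": truth.resultant_length,
            },
        )
        logger.info("synth image %d: ok", i)
    for i in range(cfg.synth.n_curves):
        spec = synth.CurveSpec(**{**cfg.synth.curve, "seed": cfg.seed + 1000 + i})
        curve = synth.generate_force_curve(spec)
        io.write_curve(crv_dir / f"curve_{i:03d}.csv", curve, synth.curve_metadata(spec))
        logger.info("synth curve %d: ok", i)
    return img_dir, crv_dir


def _run_morph(cfg: RunConfig, images_dir: Path, out: Path) -> pd.DataFrame:
    rows = []
    paths = sorted(images_dir.glob("*.tif")) + sorted(images_dir.glob("*.tiff"))
    overlay_dir = (out / "overlays") if cfg.overlays else None
    for path in paths:
        img = io.read_image(path)
        try:
            row = analyze_image(img, cfg.morph, cfg.orientation, overlay_dir)
        except Exception as exc:
            row = {c: float("nan") for c in MORPH_COLUMNS}
            row.update({"id": img.identifier, "status": f"error: {exc}"})
        logger.info("morph %s: %s", img.identifier, row["status"])
        rows.append(row)
    return pd.DataFrame(rows, columns=MORPH_COLUMNS)


def _run_afm(cfg: RunConfig, curves_dir: Path) -> pd.DataFrame:
    curves = [io.read_curve(p) for p in sorted(curves_dir.glob("*.csv"))]
    if not curves:
        return pd.DataFrame(
            columns=["curve_id", "depth_nm", "E_Pa", "z0_nm", "rms_nN", "n_points", "status"]
        )
    return afm.batch_fit(curves, depths=cfg.afm.depths, config=cfg.afm.to_config())


def run_pipeline(cfg: RunConfig) -> Report:
    """Execute the configured stages and write the report tables.

    Configuration errors (missing inputs, bad parameters) abort the run;
    per-item analysis failures are recorded in the ``status`` column.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    images_dir = Path(cfg.images_dir) if cfg.images_dir else None
    curves_dir = Path(cfg.curves_dir) if cfg.curves_dir else None
    for p, label in ((images_dir, "images_dir"), (curves_dir, "curves_dir")):
        if p is not None and not p.exists():
            raise FileNotFoundError(f"configuration error: {label} {p} does not exist")

    if "synth" in cfg.stages:
        synth_img, synth_crv = _run_synth(cfg, out)
        images_dir = images_dir or synth_img
        curves_dir = curves_dir or synth_crv

    morph_df = pd.DataFrame(columns=MORPH_COLUMNS)
    if "morph" in cfg.stages:
        if images_dir is None:
            raise FileNotFoundError("configuration error: no images_dir for morph stage")
        morph_df = _run_morph(cfg, images_dir, out)

    elast_df = pd.DataFrame(
        columns=["curve_id", "depth_nm", "E_Pa", "z0_nm", "rms_nN", "n_points", "status"]
    )
    if "afm" in cfg.stages:
        if curves_dir is None:
            raise FileNotFoundError("configuration error: no curves_dir for afm stage")
        elast_df = _run_afm(cfg, curves_dir)

    provenance = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "mtnet_version": __version__,
    }
    morph_df.to_csv(out / "morphometry.csv", index=False)
    elast_df.to_csv(out / "elasticity.csv", index=False)
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=1, sort_keys=True, default=list)
    )
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    return Report(morphometry=morph_df, elasticity=elast_df, provenance=provenance)


# ---------------------------------------------------------------------------
# Group summaries
# ---------------------------------------------------------------------------

def summarize_groups(
    table: pd.DataFrame,
    grouping: str,
    metrics: list[str],
    test: str = "ttest",
) -> pd.DataFrame:
    """Per-group n/median/mean/SEM for each metric, plus a two-group test.

    ``test`` is ``'ttest'`` (two-sample t, the morphometry convention here) or
    ``'mannwhitney'`` (rank-sum, the elasticity convention).  The test columns
    are filled only when exactly two groups are present.  Singleton groups get
    SEM = NaN (flagged in the ``sem_defined`` column).
    """
    from scipy import stats as sps

    groups = sorted(table[grouping].dropna().unique().tolist())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for metric in metrics:
        samples = {
            g: table.loc[table[grouping] == g, metric].dropna().to_numpy() for g in groups
        }
        if any(v.size == 0 for v in samples.values()):
            raise ValueError(f"empty group for metric {metric}")
        stat = p = float("nan")
        if len(groups) == 2:
            a, b = (samples[g] for g in groups)
            if test == "mannwhitney":
                stat, p = afm.compare_groups(a, b)
            else:
                if np.all(np.concatenate([a, b]) == a[0]):
                    stat, p = 0.0, 1.0
                else:
                    res = sps.ttest_ind(a, b)
                    stat, p = float(res.statistic), float(res.pvalue)
        for g in groups:
            v = samples[g]
            rows.append(
                {
                    "metric": metric,
                    "group": g,
                    "n": v.size,
                    "median": float(np.median(v)),
                    "mean": float(np.mean(v)),
                    "sem": float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan"),
                    "sem_defined": v.size > 1,
                    "test": test,
                    "statistic": stat,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
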