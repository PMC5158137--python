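"""Reading and writing the pipeline's on-disk formats.

Images travel as single-page 16-bit grayscale TIFF with the pixel size in a
sidecar JSON; AFM curves as two-column CSV (z_nm, deflection_nm) with the
calibration constants (k, Rs, nu, and for synthetic curves the generating
parameters) in a sidecar JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .afm import ForceCurve
from .morphometry import FilamentImage


def write_image(path, img: FilamentImage, ground_truth: dict | None = None) -> None:
    """Write a 16-bit TIFF plus a sidecar JSON (pixel size, optional ground truth)."""
    path = Path(path)
    arr = np.clip(np.round(img.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr)
    meta = {"pixel_size_nm": img.pixel_size, "identifier": img.identifier}
    if ground_truth is not None:
        meta["ground_truth"] = ground_truth
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_image(path) -> FilamentImage:
    """Read a grayscale TIFF; pixel size comes from the sidecar JSON if present."""
    path = Path(path)
    arr = tifffile.imread(path).astype(float)
    pixel_size = 20.0
    identifier = path.stem
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size = float(meta.get("pixel_size_nm", pixel_size))
        identifier = meta.get("identifier", identifier)
    return FilamentImage(arr, pixel_size=pixel_size, identifier=identifier)


def write_curve(path, curve: ForceCurve, extra_meta: dict | None = None) -> None:
    """Write a curve as CSV (z_nm, deflection_nm) plus calibration sidecar JSON."""
    path = Path(path)
    pd.DataFrame({"z_nm": curve.z, "deflection_nm": curve.d}).to_csv(path, index=False)
    meta = {
        "spring_constant_N_per_m": curve.k,
        "bead_radius_nm": curve.Rs,
        "poisson_ratio": curve.nu,
        "identifier": curve.identifier,
    }
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_curve(path, meta: dict | None = None) -> ForceCurve:
    """Read a curve CSV; calibration from ``meta`` or the sidecar JSON."""
    path = Path(path)
    table = pd.read_csv(path)
    if meta is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"no calibration metadata for {path}")
        meta = json.loads(sidecar.read_text())
    return ForceCurve(
        z=table["z_nm"].to_numpy(),
        d=table["deflection_nm"].to_numpy(),
        k=float(meta["spring_constant_N_per_m"]),
        Rs=float(meta["bead_radius_nm"]),
        nu=float(meta.get("poisson_ratio", 0.5)),
        identifier=meta.get("identifier", path.stem),
    )
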