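"""NIfTI and table IO with fixed, reproducible formatting.

Slice pairs are written one file per slice per contrast
(``<subject>_<level>_<mt|nomt>.nii.gz``), the atlas as a 4-D NIfTI with a
JSON tract-name sidecar, and all tables as CSV with 6-significant-digit
floats so repeated runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from cordmt.phantom import TRACT_NAMES, TractAtlas
from cordmt.register import SlicePair

FLOAT_FORMAT = "%.6g"


def _level_tag(level: str) -> str:
    return level.replace("/", "")


def _affine(pixel_size_mm: float) -> np.ndarray:
    aff = np.diag([pixel_size_mm, pixel_size_mm, 1.0, 1.0])
    return aff


def save_image(image: np.ndarray, path: Path, pixel_size_mm: float) -> None:
    img = nib.Nifti1Image(np.asarray(image, dtype=np.float64), _affine(pixel_size_mm))
    nib.save(img, str(path))


def load_image(path: Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim > 2:
        data = data.squeeze()
    pixel_size = float(img.header.get_zooms()[0])
    return data, pixel_size


def save_slice_pair(pair: SlicePair, outdir: Path) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = _level_tag(pair.level)
    p_mt = outdir / f"{pair.subject_id}_{tag}_mt.nii.gz"
    p_nomt = outdir / f"{pair.subject_id}_{tag}_nomt.nii.gz"
    save_image(pair.i_mt, p_mt, pair.pixel_size_mm)
    save_image(pair.i_o, p_nomt, pair.pixel_size_mm)
    return p_nomt, p_mt


def load_slice_pair(
    outdir: Path, subject_id: str, level: str
) -> SlicePair:
    outdir = Path(outdir)
    tag = _level_tag(level)
    i_mt, px = load_image(outdir / f"{subject_id}_{tag}_mt.nii.gz")
    i_o, _ = load_image(outdir / f"{subject_id}_{tag}_nomt.nii.gz")
    return SlicePair(
        i_o=i_o, i_mt=i_mt, level=level, pixel_size_mm=px, subject_id=subject_id
    )


def save_atlas(atlas: TractAtlas, outdir: Path) -> Path:
    """Write the atlas as 4-D NIfTI (tracts + masks) with a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vols = [atlas.tract_maps[t] for t in atlas.tract_names]
    vols += [
        atlas.cord_mask.astype(float),
        atlas.wm_mask.astype(float),
        atlas.gm_mask.astype(float),
    ]
    stack = np.stack(vols, axis=-1)[:, :, None, :]
    path = outdir / "atlas.nii.gz"
    nib.save(nib.Nifti1Image(stack, _affine(atlas.pixel_size_mm)), str(path))
    sidecar = {
        "volumes": list(atlas.tract_names) + ["cord_mask", "wm_mask", "gm_mask"],
        "pixel_size_mm": atlas.pixel_size_mm,
    }
    (outdir / "atlas.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return path


def load_atlas(outdir: Path) -> TractAtlas:
    outdir = Path(outdir)
    sidecar = json.loads((outdir / "atlas.json").read_text())
    img = nib.load(str(outdir / "atlas.nii.gz"))
    stack = np.asarray(img.get_fdata())[:, :, 0, :]
    names = sidecar["volumes"]
    vols = {n: stack[:, :, i] for i, n in enumerate(names)}
    return TractAtlas(
        tract_names=TRACT_NAMES,
        tract_maps={t: vols[t] for t in TRACT_NAMES},
        cord_mask=vols["cord_mask"] > 0.5,
        wm_mask=vols["wm_mask"] > 0.5,
        gm_mask=vols["gm_mask"] > 0.5,
        pixel_size_mm=float(sidecar["pixel_size_mm"]),
        fractions={},
    )


def write_csv(df: pd.DataFrame, path: Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def config_hash(config_obj) -> str:
    """Stable hash of a configuration's repr for run manifests."""
    return hashlib.sha256(repr(config_obj).encode()).hexdigest()[:16]


def write_manifest(path: Path, *, seed: int, config_obj, extra: dict | None = None) -> None:
    from cordmt import __version__

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": config_hash(config_obj),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
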