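"""File I/O: NIfTI volumes, CSV/JSON tables, seed lists and checksums.

NIfTI is the sole volume format; phantoms are axis-aligned so the affine is
a plain diagonal of the voxel spacing.  Tables go to CSV, metadata and run
manifests to JSON, protocols to YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .segment import SeedSpec, SegmentationProtocol
from .volumes import DualEchoVolume, FatFractionMap, RegionMask, SignalMask


def _affine(spacing_mm) -> np.ndarray:
    return np.diag([*spacing_mm, 1.0])


def save_nifti(grid: np.ndarray, spacing_mm, path: str | Path, dtype=np.float32) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(grid).astype(dtype), _affine(spacing_mm))
    img.header.set_zooms(spacing_mm)
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=np.float64), spacing


def save_dual_echo(echoes: DualEchoVolume, prefix: str | Path) -> dict[str, str]:
    prefix = Path(prefix)
    paths = {
        "in_phase": str(save_nifti(echoes.in_phase, echoes.spacing_mm, f"{prefix}_ip.nii")),
        "opposed_phase": str(
            save_nifti(echoes.opposed_phase, echoes.spacing_mm, f"{prefix}_op.nii")
        ),
    }
    sidecar = Path(f"{prefix}_echoes.json")
    sidecar.write_text(json.dumps({"te_ms": echoes.te_ms, "spacing_mm": echoes.spacing_mm}))
    paths["sidecar"] = str(sidecar)
    return paths


def load_dual_echo(prefix: str | Path) -> DualEchoVolume:
    ip, spacing = load_nifti(f"{prefix}_ip.nii")
    op, _ = load_nifti(f"{prefix}_op.nii")
    meta_path = Path(f"{prefix}_echoes.json")
    te = (2.45, 3.675)
    if meta_path.exists():
        te = tuple(json.loads(meta_path.read_text())["te_ms"])
    return DualEchoVolume(ip, op, spacing, te)


def save_fat_fraction(ff: FatFractionMap, prefix: str | Path) -> dict[str, str]:
    return {
        "ff": str(save_nifti(ff.ff, ff.spacing_mm, f"{prefix}_ff.nii")),
        "valid": str(save_nifti(ff.valid, ff.spacing_mm, f"{prefix}_ffvalid.nii", np.uint8)),
    }


def save_region_mask(mask: RegionMask, path: str | Path) -> str:
    p = save_nifti(mask.mask, mask.spacing_mm, path, np.uint8)
    sidecar = Path(str(p).removesuffix(".nii") + ".json")
    sidecar.write_text(json.dumps({"label": mask.label, "provenance": mask.provenance}, default=str))
    return str(p)


def save_signal_mask(mask: SignalMask, path: str | Path) -> str:
    p = save_nifti(mask.mask, mask.spacing_mm, path, np.uint8)
    sidecar = Path(str(p).removesuffix(".nii") + ".json")
    sidecar.write_text(json.dumps({"mean": mask.mean, "sd": mask.sd, "k": mask.k}))
    return str(p)


def save_seeds_csv(seeds: list[SeedSpec], path: str | Path) -> str:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [
            {
                "region": s.region,
                "x_mm": s.center_mm[0],
                "y_mm": s.center_mm[1],
                "z_mm": s.center_mm[2],
                "radius_mm": s.radius_mm,
            }
            for s in seeds
        ]
    )
    df.to_csv(path, index=False)
    return str(path)


def load_seeds_csv(path: str | Path) -> list[SeedSpec]:
    df = pd.read_csv(path)
    return [
        SeedSpec(r["region"], (r["x_mm"], r["y_mm"], r["z_mm"]), r["radius_mm"])
        for _, r in df.iterrows()
    ]


def save_protocol_yaml(proto: SegmentationProtocol, path: str | Path) -> str:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(asdict(proto)))
    return str(path)


def load_protocol_yaml(path: str | Path) -> SegmentationProtocol:
    data = yaml.safe_load(Path(path).read_text())
    for key in ("ff_band", "spine_levels"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return SegmentationProtocol(**data)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
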