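"""Readers and writers: NIfTI volumes, TSV tables, YAML/JSON config and
manifests.

Volumes travel as ``.nii.gz`` with RAS+ affines (nibabel); the atlas is a
4D stack with a JSON name sidecar (a directory of per-tract files is
also accepted). Tables are UTF-8 tab-delimited TSV with a header row and
'.' decimals.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .exceptions import DataError
from .volumes import LesionVolume, TractAtlas, Volume


def write_volume(vol: Volume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), vol.affine), path)
    return path


def read_volume(path: str | Path, lesion: bool = False) -> Volume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise DataError(f"cannot read NIfTI {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=float)
    cls = LesionVolume if lesion else Volume
    return cls(values=data, affine=np.asarray(img.affine))


def write_atlas(atlas: TractAtlas, path: str | Path) -> Path:
    """4D NIfTI stack plus ``<stem>.names.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack([atlas.maps[n] for n in atlas.names], axis=-1).astype(np.float32)
    nib.save(nib.Nifti1Image(stack, atlas.affine), path)
    sidecar = path.parent / (path.name.split(".")[0] + ".names.json")
    sidecar.write_text(json.dumps(list(atlas.names)))
    return path


def read_atlas(path: str | Path) -> TractAtlas:
    """Read a 4D stack + sidecar, or a directory of ``<tract>.nii.gz``."""
    path = Path(path)
    if path.is_dir():
        maps, affine = {}, None
        for f in sorted(path.glob("*.nii*")):
            vol = read_volume(f)
            maps[f.name.split(".")[0]] = vol.values
            affine = vol.affine
        if not maps:
            raise DataError(f"no NIfTI files in atlas directory {path}")
        return TractAtlas(maps=maps, affine=affine)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise DataError("atlas file must be a 4D stack")
    sidecar = path.parent / (path.name.split(".")[0] + ".names.json")
    if not sidecar.exists():
        raise DataError(f"atlas name sidecar missing: {sidecar}")
    names = json.loads(sidecar.read_text())
    if len(names) != data.shape[-1]:
        raise DataError("atlas sidecar names do not match the stack depth")
    return TractAtlas(
        maps={n: data[..., i] for i, n in enumerate(names)},
        affine=np.asarray(img.affine),
    )


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"table not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise DataError(f"cannot parse TSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    return df


def write_yaml(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(obj, sort_keys=True))
    return path


def read_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise DataError(f"config not found: {path}")
    return yaml.safe_load(path.read_text())


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path


def read_json(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    return json.loads(path.read_text())


def checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
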