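"""NIfTI, CSV, YAML, and JSON I/O for the pipeline.

Volumes and masks are NIfTI-1 with a 2 mm isotropic affine by default;
subject tables are CSV with the documented column names; run configuration
is YAML; reports are JSON.  Genotype strings are validated and normalized
to the canonical ``e?/e?`` form (sorted alleles) on read.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .simulate import COGNITIVE_VARS, GroundTruth
from .volumes import BrainMask, GMVolume

__all__ = [
    "read_volumes",
    "write_volumes",
    "read_mask",
    "write_mask",
    "read_subject_table",
    "write_subject_table",
    "write_ground_truth",
    "load_config",
    "save_json",
    "normalize_genotype",
    "VALID_GENOTYPES",
]

VALID_GENOTYPES = {"e2/e2", "e2/e3", "e2/e4", "e3/e3", "e3/e4", "e4/e4"}

_REQUIRED_COLUMNS = ["subject_id", "ab_label"]


def _default_affine(voxel_size=(2.0, 2.0, 2.0)) -> np.ndarray:
    return np.diag([*voxel_size, 1.0])


def write_volumes(
    volumes: list[GMVolume], out_dir: str | Path, compress: bool = True
) -> list[Path]:
    """Write one ``<subject_id>.nii[.gz]`` per volume; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".nii.gz" if compress else ".nii"
    paths = []
    for i, vol in enumerate(volumes):
        stem = vol.subject_id or f"sub-{i:04d}"
        path = out_dir / f"{stem}{suffix}"
        img = nib.Nifti1Image(
            vol.values.astype(np.float32), _default_affine(vol.voxel_size)
        )
        nib.save(img, path)
        paths.append(path)
    return paths


def read_volumes(dir_or_list) -> list[GMVolume]:
    """Load NIfTI volumes (sorted by filename when given a directory).

    The subject id is the filename stem.  Raises ``ValueError`` listing the
    offending files when the grids are inconsistent, and ``IOError`` naming
    an unreadable file.
    """
    if isinstance(dir_or_list, (str, Path)):
        root = Path(dir_or_list)
        paths = sorted(
            p for p in root.iterdir()
            if p.name.endswith((".nii", ".nii.gz"))
        )
    else:
        paths = [Path(p) for p in dir_or_list]
    if not paths:
        raise IOError(f"no NIfTI volumes found in {dir_or_list}")
    volumes = []
    for path in paths:
        try:
            img = nib.load(path)
            data = np.asarray(img.get_fdata(), dtype=float)
        except Exception as exc:  # noqa: BLE001 - surface the file name
            raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        stem = re.sub(r"\.nii(\.gz)?$", "", path.name)
        volumes.append(GMVolume(values=data, voxel_size=vox, subject_id=stem))
    shapes = {v.grid_shape for v in volumes}
    if len(shapes) > 1:
        offenders = {
            s: [v.subject_id for v in volumes if v.grid_shape == s]
            for s in shapes
        }
        raise ValueError(f"inconsistent volume grids: {offenders}")
    return volumes


def write_mask(mask: BrainMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.include.astype(np.uint8), _default_affine())
    nib.save(img, path)
    return path


def read_mask(path: str | Path) -> BrainMask:
    img = nib.load(path)
    return BrainMask(np.asarray(img.get_fdata()) > 0.5)


def normalize_genotype(value: str) -> str:
    """Map genotype spellings ('ε3/ε4', 'E3/e4', '3/4') to canonical form."""
    if pd.isna(value):
        return value
    s = str(value).strip().lower().replace("ε", "e").replace("ε", "e")
    parts = re.split(r"[/|,;-]", s)
    alleles = []
    for part in parts:
        m = re.fullmatch(r"e?([234])", part.strip())
        if not m:
            raise ValueError(f"unrecognized APOE genotype {value!r}")
        alleles.append(int(m.group(1)))
    if len(alleles) != 2:
        raise ValueError(f"APOE genotype {value!r} must list two alleles")
    a, b = sorted(alleles)
    canon = f"e{a}/e{b}"
    if canon not in VALID_GENOTYPES:
        raise ValueError(f"invalid APOE genotype {value!r}")
    return canon


def write_subject_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_subject_table(csv_path: str | Path) -> pd.DataFrame:
    """Load and validate a subject table CSV.

    Requires ``subject_id`` and ``ab_label`` columns; rejects duplicate
    subject ids and unknown genotype strings; preserves missing values
    (blank cells stay NaN, never 0).
    """
    table = pd.read_csv(csv_path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"subject table {csv_path} lacks columns {missing}")
    dupes = table["subject_id"][table["subject_id"].duplicated()]
    if len(dupes):
        raise ValueError(
            f"duplicate subject_id values: {sorted(set(dupes))}"
        )
    bad_labels = set(table["ab_label"].dropna()) - {"positive", "negative"}
    if bad_labels:
        raise ValueError(f"unknown ab_label values: {sorted(bad_labels)}")
    if "apoe" in table.columns:
        table["apoe"] = table["apoe"].map(normalize_genotype)
    for col in ["age", "education", *COGNITIVE_VARS]:
        if col in table.columns:
            table[col] = pd.to_numeric(table[col], errors="raise")
    return table


def write_ground_truth(
    truth: GroundTruth, out_dir: str | Path
) -> tuple[Path, list[Path]]:
    """Sidecar JSON (loadings, labels, ages, centers) + NIfTI source maps."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    src_paths = []
    for k, src in enumerate(truth.sources):
        path = out_dir / f"source-{k:02d}.nii.gz"
        nib.save(
            nib.Nifti1Image(src.weights.astype(np.float32), _default_affine()),
            path,
        )
        src_paths.append(path)
    meta = {
        "loadings": truth.loadings.tolist(),
        "labels": truth.labels.tolist(),
        "ages": truth.ages.tolist(),
        "source_centers": [list(s.center) for s in truth.sources],
        "source_extents": [s.extent for s in truth.sources],
        "source_files": [p.name for p in src_paths],
    }
    json_path = out_dir / "ground_truth.json"
    json_path.write_text(json.dumps(meta, indent=1))
    return json_path, src_paths


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict())
    if isinstance(obj, pd.Series):
        return _jsonify(obj.to_dict())
    return obj


def save_json(obj: dict, path: str | Path) -> Path:
    """Serialize a report to JSON (NaN -> null, deterministic key order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonify(obj), indent=1, sort_keys=True))
    return path
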