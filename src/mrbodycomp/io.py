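"""NIfTI / CSV / JSON / YAML readers and writers, run configuration, provenance.

Cohorts are written one NIfTI pair per scan (a 3-slice image stack and the
matching integer label stack), indexed by a manifest CSV with one row per
scan; the programmed ground truth goes to JSON. Integer grids round-trip
bit-exactly; in-plane spacing is carried in the NIfTI header.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_volume", "write_volume", "write_cohort", "read_manifest",
    "RunConfig", "load_config", "save_config", "config_hash",
    "provenance_block",
]


def write_volume(path, data: np.ndarray, spacing: float) -> None:
    """Write a 2D slice or (H, W, S) stack as NIfTI with isotropic in-plane
    spacing (mm). Integer arrays are stored as int16/uint8 so label maps
    round-trip exactly."""
    path = Path(path)
    arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int16 if arr.max(initial=0) > 255 else np.uint8)
    else:
        arr = arr.astype(np.float32)
    affine = np.diag([spacing, spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def read_volume(path) -> tuple[np.ndarray, float]:
    """Read a NIfTI volume; returns ``(array, in-plane spacing)``. Warns when
    the in-plane spacing is anisotropic (the mean is used)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:2]
    if not np.isclose(zooms[0], zooms[1]):
        warnings.warn(
            f"non-isotropic in-plane spacing {zooms}; using the mean",
            stacklevel=2)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    return data, float(np.mean(zooms))


def write_cohort(ds, outdir) -> Path:
    """Write a simulated cohort: per-scan NIfTI image/label stacks, a manifest
    CSV, and the ground-truth log JSON. Returns the manifest path."""
    outdir = Path(outdir)
    (outdir / "scans").mkdir(parents=True, exist_ok=True)
    rows = []
    for p in ds.patients:
        for scan in p.scans:
            stem = f"{p.patient_id}_t{scan.timepoint_index}"
            img_path = outdir / "scans" / f"{stem}_image.nii"
            lab_path = outdir / "scans" / f"{stem}_labels.nii"
            img = np.stack([s.image for s in scan.slices], axis=-1)
            lab = np.stack([s.labels for s in scan.slices], axis=-1)
            spacing = scan.slices[0].spacing
            write_volume(img_path, img, spacing)
            write_volume(lab_path, lab, spacing)
            rows.append({
                "patient_id": p.patient_id,
                "group": p.group,
                "timepoint_index": scan.timepoint_index,
                "acquisition_day": scan.acquisition_day,
                "image_path": str(img_path.relative_to(outdir)),
                "label_path": str(lab_path.relative_to(outdir)),
                "s1_slice_index": len(scan.slices) // 2,
            })
    manifest = pd.DataFrame(rows)
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    with open(outdir / "truth_log.json", "w") as fh:
        json.dump(ds.truth_log(), fh, indent=1)
    return manifest_path


def read_manifest(path) -> pd.DataFrame:
    """Load a cohort manifest and validate its key invariants."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"patient_id", "group", "timepoint_index", "acquisition_day",
                "image_path", "label_path", "s1_slice_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df.duplicated(["patient_id", "timepoint_index"]).any():
        raise ValueError("(patient_id, timepoint_index) must be unique")
    return df


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """One end-to-end run: simulate → (segment|oracle) → register → analyze."""

    preset_groups: tuple = ("20adt", "5adt", "5noadt")
    grid_size: int = 256
    n_slices: int = 3
    n_patients: int | None = None     # override preset cohort sizes (desk scale)
    seed: int = 0
    mode: str = "oracle"              # oracle | model
    register: bool = True
    outlier_threshold_pct: float = 10.0
    output_dir: str = "results"
    train: dict = field(default_factory=dict)   # TrainConfig overrides

    def to_dict(self) -> dict:
        d = asdict(self)
        d["preset_groups"] = list(self.preset_groups)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "preset_groups" in d:
            d["preset_groups"] = tuple(d["preset_groups"])
        return cls(**d)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the canonicalized configuration."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_block(cfg: RunConfig) -> dict:
    import mrbodycomp

    return {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "package_version": mrbodycomp.__version__,
        "numpy_version": np.__version__,
    }
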