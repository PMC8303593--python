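"""Reading and writing volumes, landmarks and cohort manifests.

Volumes are exchanged as NIfTI (via nibabel) with the voxel spacing carried
in the header, or read-only as DICOM series directories (via pydicom).
Landmarks travel as JSON, cohort manifests as CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import InputError, MetadataError
from .phantom import ImageVolume, PhantomTruth, SubjectSide

DEFAULT_AXES = {"mesiodistal": 0, "superoinferior": 1, "buccolingual": 2}


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI with the spacing in the header affine."""
    path = Path(path)
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), affine)
    img.header.set_zooms(volume.spacing)
    img.header["descrip"] = volume.modality.encode()[:79]
    nib.save(img, str(path))
    return path


def read_volume(
    path: str | Path,
    modality: str = "MRI",
    axes: dict[str, int] | None = None,
    reference_slices: dict[str, int] | None = None,
) -> ImageVolume:
    """Read a NIfTI file or a DICOM series directory into an ImageVolume.

    The axis mapping defaults to (mesiodistal, superoinferior, buccolingual)
    in array order and can be overridden with ``axes``.

    Raises
    ------
    InputError
        If the path does not exist.
    MetadataError
        If voxel spacing is missing or invalid — there is no silent default.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file or directory: {path}")
    if path.is_dir():
        data, spacing = _read_dicom_series(path)
    else:
        try:
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj).astype(np.float32)
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        except Exception as exc:  # corrupt header / not a NIfTI
            raise MetadataError(f"cannot read volume {path}: {exc}") from exc
    if len(spacing) != 3 or any((not np.isfinite(s)) or s <= 0 for s in spacing):
        raise MetadataError(f"{path}: missing or invalid voxel spacing {spacing}")
    if data.ndim != 3:
        raise MetadataError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return ImageVolume(
        data=data,
        spacing=spacing,  # type: ignore[arg-type]
        modality=modality,
        axes=dict(axes or DEFAULT_AXES),
        reference_slices=dict(reference_slices or {}),
    )


def _read_dicom_series(directory: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ""))
    slices = []
    for f in files:
        try:
            slices.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not slices:
        raise MetadataError(f"{directory}: no readable DICOM slices")
    slices.sort(key=lambda d: float(getattr(d, "InstanceNumber", 0)))
    try:
        px = [float(v) for v in slices[0].PixelSpacing]
        dz = float(
            getattr(slices[0], "SpacingBetweenSlices", getattr(slices[0], "SliceThickness"))
        )
    except AttributeError as exc:
        raise MetadataError(f"{directory}: DICOM series lacks spacing metadata") from exc
    data = np.stack([s.pixel_array.astype(np.float32) for s in slices])
    return data, (dz, px[0], px[1])


# ---------------------------------------------------------------------------
# landmarks and manifests


def landmarks_from_truth(truth: PhantomTruth) -> dict:
    """Landmark record (JSON-serializable) for one subject side."""
    return {
        "subject": truth.subject_id,
        "side": truth.side,
        "crest_xy_mm": list(truth.crest_mm),
        "nerve_midpoint_xy_mm": list(truth.nerve_center_mm),
        "baseline_angle_deg": truth.params.baseline_angle_deg,
        "reference_slices": truth.reference_slices,
        "retention_label": truth.retention_label,
    }


def write_landmarks(records: list[dict], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(records, indent=2, sort_keys=True))
    return path


def read_landmarks(path: str | Path) -> list[dict]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such landmark file: {path}")
    records = json.loads(path.read_text())
    for rec in records:
        for key in ("subject", "side", "crest_xy_mm", "nerve_midpoint_xy_mm"):
            if key not in rec:
                raise MetadataError(f"landmark record missing {key!r}: {rec}")
    return records


def export_cohort(cohort: list[SubjectSide], out_dir: str | Path) -> pd.DataFrame:
    """Write a cohort to disk: NIfTI volumes, landmarks JSON, manifest CSV.

    Returns the manifest frame (subject_id, side, file paths,
    retention_label).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, landmarks = [], []
    for ss in cohort:
        stem = f"{ss.subject_id}_{ss.side}"
        mri_path = write_volume(ss.mri, out_dir / f"{stem}_mri.nii.gz")
        cbct_path = write_volume(ss.cbct, out_dir / f"{stem}_cbct.nii.gz")
        (out_dir / f"{stem}_truth.json").write_text(
            json.dumps(_truth_to_json(ss.truth), indent=2, sort_keys=True)
        )
        landmarks.append(landmarks_from_truth(ss.truth))
        rows.append(
            {
                "subject_id": ss.subject_id,
                "side": ss.side,
                "mri_path": mri_path.name,
                "cbct_path": cbct_path.name,
                "retention_label": ss.truth.retention_label,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    write_landmarks(landmarks, out_dir / "landmarks.json")
    return manifest


def _truth_to_json(truth: PhantomTruth) -> dict:
    d = asdict(truth)
    d["true_diameters"] = {
        f"{k[0]}|{k[1]}|{k[2]}": v for k, v in truth.true_diameters.items()
    }
    return d


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such manifest: {path}")
    manifest = pd.read_csv(path)
    required = {"subject_id", "side", "mri_path"}
    missing = required - set(manifest.columns)
    if missing:
        raise MetadataError(f"manifest lacks columns {sorted(missing)}")
    return manifest
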