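"""File I/O: NIfTI volumes, JSON sidecars, YAML cohort specs.

On-disk layout of a dataset directory::

    <root>/sub-<id>/<field>T_<offset>Hz_tp<k>/
        m0.nii.gz  mt.nii.gz  anatomical.nii.gz
        labels.nii.gz  kidney_left.nii.gz  kidney_right.nii.gz
        [muscle_mask.nii.gz]          # optional user-drawn muscle ROI
        meta.json                     # acquisition metadata sidecar

Volumes are written as ``(n_slices, rows, cols)`` float64 / int16 arrays
(slice axis first, matching the in-memory convention) so write-then-read
round-trips are bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import nibabel as nib
import numpy as np
import yaml

from .errors import ValidationError
from .mtr import MTImageSet
from .phantom import (
    AcquisitionMeta,
    AcquisitionRecord,
    CohortSpec,
    PhantomDataset,
    SIDES,
    SubjectRecord,
)
from .segmentation import ROILabelMap

_SIDECAR_REQUIRED = (
    "subject",
    "group",
    "roles",
    "field_strength",
    "offset_frequency",
    "timepoint",
)


def write_nifti(array: np.ndarray, path: Path, pixel_spacing_mm: float = 2.34) -> None:
    """Write an array volume as NIfTI (slice axis first)."""
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    affine = np.diag([2.6, pixel_spacing_mm, pixel_spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def read_nifti(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def _acq_dirname(field_T: float, offset_hz: int, timepoint: int) -> str:
    return f"{field_T:g}T_{offset_hz}Hz_tp{timepoint}"


def write_acquisition(
    acq_dir: Path,
    subject_id: str,
    group: str,
    roles: Dict[str, str],
    record: AcquisitionRecord,
    geometry: ROILabelMap,
) -> None:
    """Write one acquisition (volumes + JSON sidecar) to ``acq_dir``."""
    acq_dir.mkdir(parents=True, exist_ok=True)
    meta = record.meta
    sp = meta.pixel_spacing_mm
    write_nifti(record.images.m0, acq_dir / "m0.nii.gz", sp)
    write_nifti(record.images.mt, acq_dir / "mt.nii.gz", sp)
    if record.anatomical is not None:
        write_nifti(record.anatomical, acq_dir / "anatomical.nii.gz", sp)
    write_nifti(geometry.labels.astype(np.int16), acq_dir / "labels.nii.gz", sp)
    for side in SIDES:
        if side in geometry.kidney_masks:
            write_nifti(geometry.kidney_masks[side], acq_dir / f"kidney_{side}.nii.gz", sp)
    sidecar = dict(
        subject=subject_id,
        group=group,
        roles=dict(roles),
        field_strength=meta.field_strength,
        offset_frequency=meta.offset_frequency,
        timepoint=meta.timepoint,
        matrix_size=meta.matrix_size,
        n_slices=meta.n_slices,
        pixel_spacing_mm=meta.pixel_spacing_mm,
    )
    if record.norm_truth is not None:
        sidecar["norm_truth"] = {
            f"{side}:{region}": v for (side, region), v in record.norm_truth.items()
        }
    (acq_dir / "meta.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def write_dataset(dataset: PhantomDataset, out_dir: Path) -> Path:
    """Write a whole cohort to ``out_dir``; returns the root path."""
    out_dir = Path(out_dir)
    for subj in dataset.subjects:
        for (f, off, tp), record in subj.acquisitions.items():
            acq_dir = out_dir / f"sub-{subj.subject_id}" / _acq_dirname(f, off, tp)
            write_acquisition(
                acq_dir, subj.subject_id, subj.group, subj.roles, record, subj.geometry
            )
    return out_dir


def read_acquisition(acq_dir: Path) -> Tuple[AcquisitionRecord, ROILabelMap, Dict]:
    """Read one acquisition directory back into in-memory objects.

    The anatomical volume and the user muscle mask are optional (the
    pipeline's segmentation stage reports their absence when it needs
    them). Missing required sidecar fields and M0/MT shape disagreements
    raise descriptive :class:`ValidationError`.
    """
    acq_dir = Path(acq_dir)
    sidecar_path = acq_dir / "meta.json"
    if not sidecar_path.exists():
        raise ValidationError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in _SIDECAR_REQUIRED:
        if key not in sidecar:
            raise ValidationError(f"sidecar {sidecar_path} missing field '{key}'")

    m0 = read_nifti(acq_dir / "m0.nii.gz")
    mt = read_nifti(acq_dir / "mt.nii.gz")
    if m0.shape != mt.shape:
        raise ValidationError(
            f"{acq_dir}: M0 shape {m0.shape} does not match MT shape {mt.shape}"
        )
    meta = AcquisitionMeta(
        field_strength=float(sidecar["field_strength"]),
        offset_frequency=int(sidecar["offset_frequency"]),
        timepoint=int(sidecar["timepoint"]),
        matrix_size=int(sidecar.get("matrix_size", m0.shape[1])),
        n_slices=int(sidecar.get("n_slices", m0.shape[0])),
        pixel_spacing_mm=float(sidecar.get("pixel_spacing_mm", 2.34)),
    )
    if meta.n_slices != m0.shape[0]:
        raise ValidationError(
            f"{acq_dir}: sidecar n_slices {meta.n_slices} != stack depth {m0.shape[0]}"
        )
    anatomical = None
    if (acq_dir / "anatomical.nii.gz").exists():
        anatomical = read_nifti(acq_dir / "anatomical.nii.gz")
        if anatomical.shape != m0.shape:
            raise ValidationError(f"{acq_dir}: anatomical shape mismatch")

    labels = read_nifti(acq_dir / "labels.nii.gz").astype(np.int16)
    kidney_masks = {}
    for side in SIDES:
        p = acq_dir / f"kidney_{side}.nii.gz"
        if p.exists():
            kidney_masks[side] = read_nifti(p).astype(bool)
    geometry = ROILabelMap(labels=labels, kidney_masks=kidney_masks)

    user_muscle = None
    if (acq_dir / "muscle_mask.nii.gz").exists():
        user_muscle = read_nifti(acq_dir / "muscle_mask.nii.gz").astype(bool)

    norm_truth = None
    if "norm_truth" in sidecar:
        norm_truth = {
            tuple(k.split(":")): v for k, v in sidecar["norm_truth"].items()
        }
    record = AcquisitionRecord(
        meta=meta,
        images=MTImageSet(m0=m0, mt=mt, meta=meta),
        anatomical=anatomical,
        b1_field=None,
        truth=None,
        norm_truth=norm_truth,
        user_muscle=user_muscle,
    )
    return record, geometry, sidecar


def read_dataset(root: Path) -> PhantomDataset:
    """Read a dataset directory tree written by :func:`write_dataset`."""
    root = Path(root)
    subject_dirs = sorted(p for p in root.iterdir() if p.is_dir() and p.name.startswith("sub-"))
    if not subject_dirs:
        raise ValidationError(f"no sub-* directories under {root}")
    subjects = []
    for sdir in subject_dirs:
        acqs = {}
        geometry = None
        sidecar = None
        for adir in sorted(p for p in sdir.iterdir() if p.is_dir()):
            record, geo, sc = read_acquisition(adir)
            key = (record.meta.field_strength, record.meta.offset_frequency, record.meta.timepoint)
            acqs[key] = record
            geometry, sidecar = geo, sc
        if not acqs:
            raise ValidationError(f"no acquisitions under {sdir}")
        subjects.append(
            SubjectRecord(
                subject_id=sidecar["subject"],
                group=sidecar["group"],
                roles=dict(sidecar["roles"]),
                geometry=geometry,
                acquisitions=acqs,
            )
        )
    return PhantomDataset(spec=None, master_seed=-1, subjects=subjects)


# ---------------------------------------------------------------------------
# YAML cohort specs
# ---------------------------------------------------------------------------

def _parse_stratum_key(key: str) -> Tuple[float, int]:
    """'3.0-600' or '3T-600Hz' -> (3.0, 600)."""
    cleaned = key.replace("T", "").replace("Hz", "").replace("hz", "")
    parts = cleaned.split("-")
    if len(parts) != 2:
        raise ValidationError(f"bad stratum key {key!r}; expected '<field>-<offset>'")
    return float(parts[0]), int(parts[1])


def cohort_spec_from_yaml(path: Path) -> CohortSpec:
    """Load a :class:`CohortSpec` from YAML.

    Top-level keys mirror the dataclass fields; ``truth_table`` uses
    stratum keys like ``"3.0-600"`` with ``{region: {role: [mean, sd]}}``
    values, and ``b1_amplitude`` / ``snr`` use field-strength keys.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(CohortSpec.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown cohort-spec keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "truth_table" in kwargs:
        kwargs["truth_table"] = {
            _parse_stratum_key(k): {
                region: {role: tuple(ms) for role, ms in roles.items()}
                for region, roles in v.items()
            }
            for k, v in kwargs["truth_table"].items()
        }
    for key in ("b1_amplitude", "snr"):
        if key in kwargs:
            kwargs[key] = {float(k): float(v) for k, v in kwargs[key].items()}
    for key in ("field_strengths", "offset_frequencies", "timepoints"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return CohortSpec(**kwargs)
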