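"""Readers and writers: NIfTI study directories and cohort CSV tables.

A study directory holds one NIfTI volume per channel (``b0``, ``b1000``,
``adc``, ``fat``, ``in_phase``) plus uint8 mask volumes
(``truth_lesion_mask``, ``exclusion_mask``) and a ``meta.json`` sidecar
with voxel geometry and the vertebral ROI rectangles.  Volumes are stored
with an affine that maps the in-memory (SI, LR, AP) index order into RAS+
millimetre coordinates; all files of a study must agree on shape and
affine.  Round-trips preserve voxel data bit-exactly and geometry to
1e-6 mm.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import COHORT_COLUMNS, ImageStudy, VertebraRoi
from .segmentation import compute_adc_map

__all__ = ["write_study", "read_study", "write_cohort", "read_cohort",
           "study_affine"]

log = logging.getLogger("marrowquant")

_VOLUMES = ("b0", "b1000", "adc", "fat", "in_phase")
_MASKS = ("truth_lesion_mask", "exclusion_mask")


def study_affine(voxel_size_mm) -> np.ndarray:
    """Affine taking (SI, LR, AP) voxel indices to RAS+ mm coordinates.

    Axis 0 (SI) advances toward Superior, axis 1 (LR) toward Right
    (anatomical left-to-right when viewed from the front), axis 2 (AP)
    toward Anterior.
    """
    si, lr, ap = (float(v) for v in voxel_size_mm)
    aff = np.zeros((4, 4))
    aff[0, 1] = lr   # R <- LR axis
    aff[1, 2] = ap   # A <- AP axis
    aff[2, 0] = si   # S <- SI axis
    aff[3, 3] = 1.0
    return aff


def write_study(study: ImageStudy, directory) -> Path:
    """Write an :class:`ImageStudy` as NIfTI volumes plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = study_affine(study.voxel_size_mm)
    for name in _VOLUMES:
        data = np.asarray(getattr(study, name), dtype=np.float64)
        nib.save(nib.Nifti1Image(data, aff), directory / f"{name}.nii.gz")
    for name in _MASKS:
        data = np.asarray(getattr(study, name), dtype=np.uint8)
        nib.save(nib.Nifti1Image(data, aff), directory / f"{name}.nii.gz")
    meta = {
        "voxel_size_mm": list(study.voxel_size_mm),
        "axes": ["SI", "LR", "AP"],
        "vertebra_rois": [
            {"label": r.label, "si_range_mm": list(r.si_range_mm),
             "lr_range_mm": list(r.lr_range_mm)}
            for r in study.vertebra_rois
        ],
        "truth_lesion_voxels": int(np.asarray(study.truth_lesion_mask, bool).sum()),
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    return directory


def read_study(directory) -> ImageStudy:
    """Read a study directory back into an :class:`ImageStudy`.

    All volumes must share shape and affine (1e-6 tolerance); offending
    files are named in the error.  A missing ADC volume is recomputed
    from b0/b1000 with a logged notice.
    """
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    voxel_size = tuple(float(v) for v in meta["voxel_size_mm"])

    arrays: dict[str, np.ndarray] = {}
    ref_shape, ref_affine, ref_name = None, None, None
    bad = []
    for name in _VOLUMES + _MASKS:
        path = directory / f"{name}.nii.gz"
        if not path.exists():
            path = directory / f"{name}.nii"
        if not path.exists():
            if name == "adc":
                continue  # recomputed below
            if name in _MASKS:
                arrays[name] = None
                continue
            raise FileNotFoundError(f"study volume missing: {path}")
        img = nib.load(path)
        data = np.asarray(img.dataobj)
        if ref_shape is None:
            ref_shape, ref_affine, ref_name = data.shape, img.affine, path.name
        else:
            if data.shape != ref_shape or not np.allclose(img.affine, ref_affine,
                                                          atol=1e-6):
                bad.append(path.name)
        arrays[name] = data
    if bad:
        raise ValueError(
            f"shape/affine mismatch against {ref_name}: {', '.join(bad)}")

    if "adc" not in arrays:
        log.info("ADC volume missing in %s: recomputing from b0/b1000", directory)
        arrays["adc"] = compute_adc_map(arrays["b0"], arrays["b1000"])
    for name in _MASKS:
        if arrays.get(name) is None:
            arrays[name] = np.zeros(ref_shape, dtype=bool)

    rois = tuple(
        VertebraRoi(r["label"], tuple(r["si_range_mm"]), tuple(r["lr_range_mm"]))
        for r in meta.get("vertebra_rois", [])
    )
    return ImageStudy(
        b0=np.asarray(arrays["b0"], float),
        b1000=np.asarray(arrays["b1000"], float),
        adc=np.asarray(arrays["adc"], float),
        fat=np.asarray(arrays["fat"], float),
        in_phase=np.asarray(arrays["in_phase"], float),
        truth_lesion_mask=np.asarray(arrays["truth_lesion_mask"], bool),
        exclusion_mask=np.asarray(arrays["exclusion_mask"], bool),
        vertebra_rois=rois,
        voxel_size_mm=voxel_size,
    )


def write_cohort(cohort: pd.DataFrame, path) -> Path:
    """Write a cohort table as CSV with the documented column set."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False)
    return path


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, checking the core columns are present."""
    df = pd.read_csv(path)
    missing = [c for c in ("mobilization_class", "median_adc_mm2_s")
               if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV lacks required columns: {missing}")
    # keep any extra columns; order known ones first for stable output
    known = [c for c in COHORT_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in known]
    return df[known + extra]
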