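"""Per-patient MRI indices and mobilization classification.

Derives the three imaging markers used for mobilization prediction —
total diffusion volume (tDV, ml), median ADC of the tDV (mm^2/s), and
mean Dixon fat fraction (%) — and classifies mobilization outcome from
the CD34+ yield (adequate at or above 4.0e6 cells/kg) or predicts it from
median ADC against a cutoff (poor strictly above the cutoff).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .segmentation import VoxelMask

__all__ = [
    "ImagingIndices",
    "MobilizationClass",
    "ADEQUACY_CUTOFF_CELLS_PER_KG",
    "ADC_CUTOFF_MM2_S",
    "ROI_AREA_RANGE_MM2",
    "tdv_volume_ml",
    "median_adc_of_tdv",
    "fat_fraction_map",
    "roi_mean_ff",
    "classify_yield",
    "predict_mobilization",
    "quantify_study",
]

#: adequate mobilization requires a total yield of at least this many CD34+ cells/kg
ADEQUACY_CUTOFF_CELLS_PER_KG = 4.0e6

#: ROC-derived median-ADC cutoff (mm^2/s); above it predicts poor mobilization
ADC_CUTOFF_MM2_S = 1.18e-3

#: observed range of lumbar ROI areas (mm^2); outside it a warning is emitted
ROI_AREA_RANGE_MM2 = (270.0, 485.0)


@dataclass
class ImagingIndices:
    """Per-patient derived markers."""

    tdv_ml: float
    median_adc: float | None  # mm^2/s; None when no lesion voxels exist
    ff_mean_percent: float | None
    roi_area_mm2: float | None = None
    n_rois: int = 0
    no_lesion_flag: bool = False


@dataclass(frozen=True)
class MobilizationClass:
    """Mobilization outcome: 'poor' iff yield < 4.0e6 CD34+ cells/kg."""

    label: str
    yield_cells_per_kg: float

    def __post_init__(self) -> None:
        if self.label not in ("adequate", "poor"):
            raise ValueError(f"label must be 'adequate' or 'poor', got {self.label!r}")


def tdv_volume_ml(mask: VoxelMask) -> float:
    """Total diffusion volume in ml: voxel count x voxel volume (mm^3) / 1000."""
    return mask.count * mask.voxel_volume_mm3 / 1000.0


def median_adc_of_tdv(adc: np.ndarray, tdv_mask: VoxelMask) -> float:
    """Exact sample median ADC over the tDV voxels (mean of middle two if even)."""
    values = np.asarray(adc, dtype=float)[tdv_mask.data]
    if values.size == 0:
        raise ValueError("tDV mask is empty: median ADC undefined (no-lesion study)")
    return float(np.median(values))


def fat_fraction_map(fat: np.ndarray, in_phase: np.ndarray,
                     floor_fraction: float = 1e-6) -> np.ndarray:
    """Fat-fraction map in percent: 100 * fat / in_phase, clipped to [0, 100].

    Voxels whose in-phase signal falls below ``floor_fraction`` of the
    in-phase maximum are undefined and returned as NaN.
    """
    fat = np.asarray(fat, dtype=float)
    in_phase = np.asarray(in_phase, dtype=float)
    if fat.shape != in_phase.shape:
        raise ValueError(f"shape mismatch: fat {fat.shape} vs in_phase {in_phase.shape}")
    floor = floor_fraction * in_phase.max() if in_phase.size else 0.0
    defined = in_phase > floor
    ff = np.full(fat.shape, np.nan)
    ff[defined] = np.clip(100.0 * fat[defined] / in_phase[defined], 0.0, 100.0)
    return ff


def roi_mean_ff(ff_map: np.ndarray, roi,
                voxel_size_mm: tuple[float, float, float]) -> tuple[float, float]:
    """Mean FF (%) and area (mm^2) of a rectangular midcoronal ROI.

    ``roi`` carries mm ranges along the SI and LR axes (``si_range_mm``,
    ``lr_range_mm``); the ROI is evaluated on the midcoronal slice (middle
    AP index).  Undefined (NaN) voxels are skipped; a fully undefined ROI
    is an error.  An area outside the typical lumbar range emits a warning.
    """
    ff_map = np.asarray(ff_map, dtype=float)
    si_sp, lr_sp, _ = voxel_size_mm
    mid_ap = ff_map.shape[2] // 2

    def idx(range_mm, spacing, n):
        lo = int(np.floor(range_mm[0] / spacing))
        hi = int(np.ceil(range_mm[1] / spacing))
        if lo < 0 or hi > n or hi <= lo:
            raise ValueError(f"ROI range {range_mm} mm out of image bounds")
        return lo, hi

    si0, si1 = idx(roi.si_range_mm, si_sp, ff_map.shape[0])
    lr0, lr1 = idx(roi.lr_range_mm, lr_sp, ff_map.shape[1])
    patch = ff_map[si0:si1, lr0:lr1, mid_ap]
    area = patch.size * si_sp * lr_sp
    if not (ROI_AREA_RANGE_MM2[0] <= area <= ROI_AREA_RANGE_MM2[1]):
        warnings.warn(
            f"ROI area {area:.0f} mm^2 outside the typical lumbar range "
            f"{ROI_AREA_RANGE_MM2[0]:.0f}-{ROI_AREA_RANGE_MM2[1]:.0f} mm^2",
            stacklevel=2,
        )
    defined = patch[np.isfinite(patch)]
    if defined.size == 0:
        raise ValueError("ROI contains no defined fat-fraction voxels")
    return float(defined.mean()), float(area)


def classify_yield(total_yield: float) -> MobilizationClass:
    """Classify a CD34+ yield: poor iff strictly below 4.0e6 cells/kg."""
    if total_yield < 0:
        raise ValueError(f"yield must be >= 0, got {total_yield}")
    label = "poor" if total_yield < ADEQUACY_CUTOFF_CELLS_PER_KG else "adequate"
    return MobilizationClass(label, float(total_yield))


def predict_mobilization(median_adc: float, cutoff: float = ADC_CUTOFF_MM2_S,
                         no_lesion_flag: bool = False) -> str:
    """Predict mobilization from median ADC: poor iff strictly above cutoff."""
    if no_lesion_flag or median_adc is None:
        raise ValueError("median ADC undefined (no-lesion study): prediction undefined")
    return "poor" if median_adc > cutoff else "adequate"


def quantify_study(study, seg_result) -> ImagingIndices:
    """Full index extraction for one study from its segmentation result.

    Computes tDV and median ADC from the tDV mask, and the mean FF over
    all supplied vertebral ROIs (the per-ROI means are averaged, and the
    number of ROIs used is recorded).
    """
    tdv = seg_result.tdv_mask
    tdv_ml = tdv_volume_ml(tdv)
    if seg_result.no_lesion:
        median_adc = None
    else:
        median_adc = median_adc_of_tdv(study.adc, tdv)

    ff = fat_fraction_map(study.fat, study.in_phase)
    roi_means, areas = [], []
    for roi in study.vertebra_rois:
        try:
            m, a = roi_mean_ff(ff, roi, study.voxel_size_mm)
        except ValueError:
            continue
        roi_means.append(m)
        areas.append(a)
    ff_mean = float(np.mean(roi_means)) if roi_means else None
    area = float(np.mean(areas)) if areas else None
    return ImagingIndices(
        tdv_ml=tdv_ml, median_adc=median_adc, ff_mean_percent=ff_mean,
        roi_area_mm2=area, n_rois=len(roi_means),
        no_lesion_flag=seg_result.no_lesion,
    )
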