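"""Semi-automated segmentation of diffusion-bright marrow lesions.

The workflow mirrors the clinical semi-automated procedure for whole-body
DWI of myeloma: a coronal maximum-intensity projection (MIP) of the b=1000
s/mm^2 volume is rescaled to 8 bits, background is removed at a fixed
threshold, the surviving pixels are binarized with Otsu's discriminant
method, non-skeletal high-signal structures are removed via an exclusion
mask, T2 shine-through is suppressed by an upper ADC bound, and the total
diffusion volume (tDV) is the set of surviving voxels above a lower ADC
bound.

All ADC values are in mm^2/s (so 1.0e-3, not 1.0, for typical marrow
lesions).  Volumes are indexed (SI, LR, AP): axis 0 runs along the
superior-inferior direction, axis 1 left-right, axis 2 anterior-posterior,
so a coronal projection collapses axis 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SegmentationParams",
    "VoxelMask",
    "SegmentationResult",
    "compute_adc_map",
    "coronal_mip",
    "normalize_to_8bit",
    "background_mask",
    "otsu_threshold",
    "segment_lesions",
]

#: canonical in-memory axis labels for 3-D volumes
AXES = ("SI", "LR", "AP")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable thresholds of the lesion-segmentation workflow.

    Parameters
    ----------
    background_threshold:
        Intensity on the min-max normalized 0-255 MIP scale below or at
        which a pixel is background.  Default 97.
    adc_shine_max:
        Upper ADC bound (mm^2/s) for the T2 shine-through filter; voxels
        with ADC <= this bound are kept.  Default 2.0e-3.
    adc_tdv_min:
        Lower ADC bound (mm^2/s); tDV voxels must exceed it strictly.
        Default 0.55e-3.
    histogram_bins:
        Number of histogram bins for the Otsu threshold.  Default 256.
    """

    background_threshold: float = 97.0
    adc_shine_max: float = 2.0e-3
    adc_tdv_min: float = 0.55e-3
    histogram_bins: int = 256

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_threshold <= 255.0:
            raise ValueError(
                f"background_threshold must lie in [0, 255], got {self.background_threshold}"
            )
        if not 0.0 < self.adc_tdv_min < self.adc_shine_max:
            raise ValueError(
                "ADC window must satisfy 0 < adc_tdv_min < adc_shine_max, got "
                f"({self.adc_tdv_min}, {self.adc_shine_max})"
            )
        if self.histogram_bins < 1:
            raise ValueError("histogram_bins must be >= 1")


@dataclass
class VoxelMask:
    """Binary voxel mask with geometry and provenance.

    ``provenance`` records which filter produced the mask, e.g.
    ``"otsu"`` or ``"tdv"``.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be positive")

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def with_provenance(self, tag: str) -> "VoxelMask":
        return replace(self, provenance=tag)


@dataclass
class SegmentationResult:
    """Output of :func:`segment_lesions`: the tDV mask plus intermediates."""

    tdv_mask: VoxelMask
    intermediates: dict[str, VoxelMask]
    mip_8bit: np.ndarray
    otsu_threshold: float
    no_lesion: bool = False


def compute_adc_map(b0: np.ndarray, b1000: np.ndarray) -> np.ndarray:
    """ADC map (mm^2/s) from signal volumes at b=0 and b=1000 s/mm^2.

    ADC = ln(S0 / S_b) / b per voxel.  Voxels with non-positive signal in
    either input are set to 0 (flagged as no-signal); negative ADC values
    (signal increase with b, i.e. pure noise) are clamped to 0.
    """
    b0 = np.asarray(b0, dtype=float)
    b1000 = np.asarray(b1000, dtype=float)
    if b0.shape != b1000.shape:
        raise ValueError(f"shape mismatch: b0 {b0.shape} vs b1000 {b1000.shape}")
    valid = (b0 > 0) & (b1000 > 0)
    adc = np.zeros_like(b0)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc[valid] = np.log(b0[valid] / b1000[valid]) / 1000.0
    np.clip(adc, 0.0, None, out=adc)
    return adc


def coronal_mip(volume: np.ndarray, axes: tuple[str, ...] = AXES) -> np.ndarray:
    """Coronal maximum intensity projection of a 3-D volume.

    Collapses the anterior-posterior axis, returning an (SI, LR) image.
    ``axes`` labels the volume's axes; it must contain ``"AP"``.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got ndim={volume.ndim}")
    if axes is None or "AP" not in axes or len(axes) != 3:
        raise ValueError(f"axis labels must name the 'AP' axis, got {axes!r}")
    ap = axes.index("AP")
    mip = volume.max(axis=ap)
    # reorder remaining axes to (SI, LR)
    remaining = [a for a in axes if a != "AP"]
    if remaining == ["LR", "SI"]:
        mip = mip.T
    return mip


def normalize_to_8bit(image: np.ndarray) -> np.ndarray:
    """Linearly rescale intensities so min -> 0 and max -> 255.

    A constant image maps to all zeros.  Values stay float (no rounding);
    the 8-bit scale is a display convention, not a dtype.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite intensities")
    lo = image.min()
    hi = image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) * (255.0 / (hi - lo))


def background_mask(
    mip_8bit: np.ndarray,
    background_threshold: float = 97.0,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> VoxelMask:
    """Foreground mask of a normalized MIP: pixels strictly above threshold."""
    fg = np.asarray(mip_8bit, dtype=float) > background_threshold
    return VoxelMask(fg, voxel_size_mm, provenance="background_removed")


def otsu_threshold(intensities: np.ndarray, bins: int = 256) -> float:
    """Otsu's discriminant threshold over histogram bin edges.

    Candidate thresholds are the edges (except the last, which would leave
    class 1 empty) of a ``bins``-bin histogram of the data.  For each
    candidate t, class 0 holds the samples <= t and class 1 the rest; the
    returned t maximizes the between-class variance
    sigma_b^2(t) = w0 * w1 * (mu0 - mu1)^2, computed from the exact sample
    moments of each class (not bin-center approximations).  Ties break
    toward the lowest t.  An all-equal input returns that single value.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("otsu_threshold requires at least one sample")
    if x.min() == x.max():
        return float(x[0])
    edges = np.histogram_bin_edges(x, bins=bins)
    candidates = edges[:-1]
    xs = np.sort(x)
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    n = xs.size
    total = csum[-1]
    # class 0 = values <= t  ->  count via searchsorted(side="right")
    n0 = np.searchsorted(xs, candidates, side="right").astype(float)
    n1 = n - n0
    valid = (n0 > 0) & (n1 > 0)
    sigma_b = np.zeros(candidates.size)
    s0 = csum[n0.astype(int)]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / n0
        mu1 = (total - s0) / n1
        sigma_b[valid] = (n0 * n1 / (n * n) * (mu0 - mu1) ** 2)[valid]
    best = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer
    return float(candidates[best])


def segment_lesions(study, params: SegmentationParams | None = None) -> SegmentationResult:
    """Run the full MIP -> background -> Otsu -> exclusion -> ADC-window chain.

    Stages, in order:

    (a) coronal MIP of the b1000 volume, min-max normalized to 0-255,
        background removed at ``params.background_threshold`` (strict >);
    (b) Otsu threshold computed on the surviving MIP pixels;
    (c) that threshold applied to the normalized 3-D b1000 volume,
        restricted to the coronal columns surviving (a);
    (d) the study's exclusion mask removed;
    (e) T2 shine-through filter: keep voxels with ADC <= adc_shine_max;
    (f) tDV: surviving voxels with ADC > adc_tdv_min (strict).

    Each stage's mask is a subset of the previous one.  An empty tDV mask
    is returned with ``no_lesion=True`` rather than raised.
    """
    if params is None:
        params = SegmentationParams()
    vs = tuple(study.voxel_size_mm)
    b1000 = np.asarray(study.b1000, dtype=float)
    adc = np.asarray(study.adc, dtype=float)
    if b1000.shape != adc.shape:
        raise ValueError("b1000 and adc volumes must share a shape")

    mip = coronal_mip(b1000)
    mip8 = normalize_to_8bit(mip)
    fg2d = background_mask(mip8, params.background_threshold, vs)

    surviving = mip8[fg2d.data]
    if surviving.size == 0:
        empty = VoxelMask(np.zeros_like(b1000, dtype=bool), vs, "tdv")
        return SegmentationResult(empty, {"columns": fg2d}, mip8, float("nan"), no_lesion=True)
    t_otsu = otsu_threshold(surviving, params.histogram_bins)

    vol8 = normalize_to_8bit(b1000)
    columns_3d = np.broadcast_to(fg2d.data[:, :, None], b1000.shape)
    m_otsu = VoxelMask((vol8 > t_otsu) & columns_3d, vs, "otsu")

    exclusion = np.asarray(getattr(study, "exclusion_mask", None), dtype=bool) \
        if getattr(study, "exclusion_mask", None) is not None \
        else np.zeros_like(b1000, dtype=bool)
    if exclusion.shape != b1000.shape:
        raise ValueError("exclusion mask shape does not match the b1000 volume")
    m_excl = VoxelMask(m_otsu.data & ~exclusion, vs, "exclusion_removed")

    m_shine = VoxelMask(m_excl.data & (adc <= params.adc_shine_max), vs, "shine_through")
    tdv = VoxelMask(m_shine.data & (adc > params.adc_tdv_min), vs, "tdv")

    no_lesion = tdv.count == 0
    if no_lesion:
        warnings.warn("tDV mask is empty: no lesion voxels survive the ADC window", stacklevel=2)
    intermediates = {
        "columns": fg2d,
        "otsu": m_otsu,
        "exclusion_removed": m_excl,
        "shine_through": m_shine,
    }
    return SegmentationResult(tdv, intermediates, mip8, t_otsu, no_lesion=no_lesion)
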