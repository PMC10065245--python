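"""Synthetic phantoms and cohorts with known ground truth.

No imaging dataset accompanies the clinical study this package
operationalizes, so every downstream stage is exercised on synthetic
inputs with known truth:

* :func:`generate_phantom_study` builds a 3-D "skeletal" phantom — a
  parametric skeleton containing focal lesions of prescribed ADC, plus
  non-skeletal high-signal blobs (brain/bladder analogues) that the
  exclusion mask must remove — and synthesizes the b=0 / b=1000 DWI pair
  through the mono-exponential signal model S_b = S0 * exp(-b * ADC),
  together with Dixon fat-only / in-phase volumes.

* :func:`generate_cohort` draws per-patient marker values (median ADC,
  tDV, fat fraction) group-conditionally from the published per-group
  normal summaries (adequate harvest: median ADC 0.96 +/- 0.24e-3 mm^2/s;
  relatively poor mobilization: 1.24 +/- 0.26e-3), assigns an M-protein
  category with Bence-Jones confined to the poor group, and links CD34+
  yield to median ADC through a configurable monotone-decreasing
  linear-with-floor model.

Seeding is hierarchical: a single cohort seed spawns one substream per
patient, so enlarging a cohort never perturbs earlier patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import classify_yield

__all__ = [
    "Lesion",
    "Organ",
    "Shape",
    "PhantomSpec",
    "YieldModel",
    "CohortSpec",
    "ImageStudy",
    "VertebraRoi",
    "generate_phantom_study",
    "generate_cohort",
    "cd34_yield_from_adc",
    "COHORT_COLUMNS",
]


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Shape:
    """Axis-aligned box or ellipsoid, in mm, used for skeleton geometry."""

    kind: str  # "box" | "ellipsoid"
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, float, float]  # full box edge lengths, or ellipsoid semi-axes

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        d = np.abs(points_mm - np.asarray(self.center_mm))
        if self.kind == "box":
            return np.all(d <= np.asarray(self.size_mm) / 2.0, axis=-1)
        if self.kind == "ellipsoid":
            return np.sum((d / np.asarray(self.size_mm)) ** 2, axis=-1) <= 1.0
        raise ValueError(f"unknown shape kind {self.kind!r}")


@dataclass(frozen=True)
class Lesion:
    """Focal marrow lesion: a sphere of prescribed ADC and DWI brightness."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    target_adc: float = 1.0e-3  # mm^2/s
    dwi_intensity: float = 230.0  # b1000 signal


@dataclass(frozen=True)
class Organ:
    """Non-skeletal high-signal blob (brain/bladder analogue)."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    adc: float = 0.9e-3
    dwi_intensity: float = 240.0


@dataclass(frozen=True)
class VertebraRoi:
    """Rectangular ROI on the midcoronal plane, in mm, for marrow FF."""

    label: str
    si_range_mm: tuple[float, float]
    lr_range_mm: tuple[float, float]


def _default_skeleton() -> tuple[Shape, ...]:
    # a spine-like central column inside the default 64 mm cube
    return (Shape("box", (32.0, 32.0, 32.0), (56.0, 20.0, 20.0)),)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic skeletal DWI/Dixon phantom.

    Intensities are arbitrary signal units on the b=1000 image; the b=0
    volume is derived through the mono-exponential model so that
    ``b1000 = b0 * exp(-1000 * ADC)`` holds exactly before noise.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    skeleton_geometry: tuple[Shape, ...] = field(default_factory=_default_skeleton)
    lesions: tuple[Lesion, ...] = ()
    organs: tuple[Organ, ...] = ()
    marrow_ff_percent: float = 40.0
    marrow_adc: float = 0.4e-3      # fatty/normal marrow, below the tDV window
    marrow_dwi_intensity: float = 110.0
    lesion_ff_percent: float = 5.0
    air_dwi_intensity: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be positive")
        if not 0.0 <= self.marrow_ff_percent <= 100.0:
            raise ValueError("marrow_ff_percent must lie in [0, 100]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        centers = np.array([l.center_mm for l in self.lesions], dtype=float).reshape(-1, 3)
        if len(self.lesions):
            inside = np.zeros(len(self.lesions), dtype=bool)
            for shape in self.skeleton_geometry:
                inside |= shape.contains(centers)
            bad = np.nonzero(~inside)[0]
            if bad.size:
                raise ValueError(f"lesion {bad[0]} center lies outside the skeleton geometry")
        for i, organ in enumerate(self.organs):
            c = np.asarray(organ.center_mm, dtype=float)
            if any(shape.contains(c[None, :])[0] for shape in self.skeleton_geometry):
                raise ValueError(f"organ {i} center lies inside the skeleton geometry")


@dataclass
class ImageStudy:
    """One patient's registered volumes, masks, and geometry.

    All volumes share shape and are indexed (SI, LR, AP).  ADC is in
    mm^2/s.  ``truth_lesion_mask`` and ``exclusion_mask`` are disjoint.
    """

    b0: np.ndarray
    b1000: np.ndarray
    adc: np.ndarray
    fat: np.ndarray
    in_phase: np.ndarray
    truth_lesion_mask: np.ndarray
    exclusion_mask: np.ndarray
    vertebra_rois: tuple[VertebraRoi, ...]
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        vols = [self.b0, self.b1000, self.adc, self.fat, self.in_phase,
                self.truth_lesion_mask, self.exclusion_mask]
        shapes = {np.asarray(v).shape for v in vols}
        if len(shapes) != 1:
            raise ValueError(f"volumes do not share a shape: {sorted(shapes)}")
        if np.any(np.asarray(self.adc) < 0):
            raise ValueError("ADC map contains negative values")
        if np.any(np.asarray(self.truth_lesion_mask, bool) & np.asarray(self.exclusion_mask, bool)):
            raise ValueError("truth_lesion_mask and exclusion_mask overlap")


def _voxel_centers_mm(grid_shape, voxel_size_mm) -> np.ndarray:
    axes = [
        (np.arange(n) + 0.5) * s
        for n, s in zip(grid_shape, voxel_size_mm)
    ]
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack(g, axis=-1)


def generate_phantom_study(spec: PhantomSpec) -> ImageStudy:
    """Build an :class:`ImageStudy` from a :class:`PhantomSpec`.

    Deterministic for a fixed ``spec.seed``.  Voxel membership is decided
    by voxel centers; lesion voxels are additionally clipped to the
    skeleton, so the truth mask is exactly the set of voxels whose tDV
    membership the segmentation chain should recover.
    """
    pts = _voxel_centers_mm(spec.grid_shape, spec.voxel_size_mm)
    flat = pts.reshape(-1, 3)

    skeleton = np.zeros(flat.shape[0], dtype=bool)
    for shape in spec.skeleton_geometry:
        skeleton |= shape.contains(flat)
    skeleton = skeleton.reshape(spec.grid_shape)

    adc = np.zeros(spec.grid_shape, dtype=float)
    b1000 = np.full(spec.grid_shape, spec.air_dwi_intensity, dtype=float)
    ff = np.zeros(spec.grid_shape, dtype=float)  # percent

    adc[skeleton] = spec.marrow_adc
    b1000[skeleton] = spec.marrow_dwi_intensity
    ff[skeleton] = spec.marrow_ff_percent

    truth = np.zeros(spec.grid_shape, dtype=bool)
    for i, lesion in enumerate(spec.lesions):
        r2 = np.sum((pts - np.asarray(lesion.center_mm)) ** 2, axis=-1)
        inside = (r2 <= lesion.radius_mm**2)
        if not inside.any():
            raise ValueError(f"lesion {i} covers no voxel of the grid")
        inside &= skeleton
        truth |= inside
        adc[inside] = lesion.target_adc
        b1000[inside] = lesion.dwi_intensity
        ff[inside] = spec.lesion_ff_percent

    exclusion = np.zeros(spec.grid_shape, dtype=bool)
    for organ in spec.organs:
        r2 = np.sum((pts - np.asarray(organ.center_mm)) ** 2, axis=-1)
        inside = (r2 <= organ.radius_mm**2) & ~skeleton
        exclusion |= inside
        adc[inside] = organ.adc
        b1000[inside] = organ.dwi_intensity

    # mono-exponential DWI signal model, run backwards: S0 = S_b * exp(b*ADC)
    b0 = b1000 * np.exp(1000.0 * adc)

    in_phase = np.where(skeleton | exclusion, 100.0, 0.0)
    fat = ff / 100.0 * in_phase

    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
        for vol in (b0, b1000, fat, in_phase):
            vol += rng.normal(0.0, spec.noise_sd, size=vol.shape)
            np.clip(vol, 0.0, None, out=vol)
        # ADC as a scanner would report it: recomputed from the noisy signals
        from .segmentation import compute_adc_map

        adc = compute_adc_map(b0, b1000)

    rois = _default_vertebra_rois(spec)
    return ImageStudy(
        b0=b0, b1000=b1000, adc=adc, fat=fat, in_phase=in_phase,
        truth_lesion_mask=truth, exclusion_mask=exclusion,
        vertebra_rois=rois, voxel_size_mm=tuple(spec.voxel_size_mm),
    )


def _default_vertebra_rois(spec: PhantomSpec) -> tuple[VertebraRoi, ...]:
    """Three stacked lumbar-analogue ROIs inside the first skeleton shape."""
    shape = spec.skeleton_geometry[0]
    c = shape.center_mm
    half_si = shape.size_mm[0] / 2.0
    half_lr = shape.size_mm[1] / 2.0
    # three ~18x18 mm ROIs stacked along SI, shrunk to fit small grids
    h = min(18.0, 2 * half_si / 3.0 * 0.9)
    w = min(18.0, 2 * half_lr * 0.9)
    rois = []
    for k, label in enumerate(("L1", "L2", "L3")):
        si_c = c[0] + (k - 1) * h
        rois.append(VertebraRoi(label, (si_c - h / 2, si_c + h / 2),
                                (c[1] - w / 2, c[1] + w / 2)))
    return tuple(rois)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: documented CSV column names of a cohort table
COHORT_COLUMNS = [
    "patient_id", "group", "mprotein_type", "age_years",
    "wbc_10e3_per_ul", "neutrophil_10e3_per_ul", "platelet_10e4_per_ul",
    "hemoglobin_g_dl", "prior_lines", "diagnosis_to_harvest_months",
    "tdv_ml", "median_adc_mm2_s", "ff_percent",
    "cd34_yield_cells_per_kg", "mobilization_class",
]

MPROTEIN_CATEGORIES = ("IgG", "IgA", "IgD", "BJ")


@dataclass(frozen=True)
class YieldModel:
    """Monotone-decreasing link from median ADC to CD34+ yield.

    yield = max(0, intercept - slope * median_adc + noise).  Defaults put
    the zero-noise crossing of the 4.0e6 cells/kg adequacy cutoff at
    ADC 1.18e-3 mm^2/s.
    """

    intercept: float = 9.9e6   # cells/kg
    slope: float = 5.0e9       # cells/kg per (mm^2/s)
    noise_sd: float = 1.0e6    # cells/kg

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError("slope must be >= 0 (yield decreases with ADC)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def cd34_yield_from_adc(median_adc: float, yield_model: YieldModel,
                        noise_draw: float = 0.0) -> float:
    """CD34+ yield (cells/kg) from median ADC via the linear-with-floor link."""
    if median_adc <= 0:
        raise ValueError("median_adc must be positive")
    raw = yield_model.intercept - yield_model.slope * median_adc + noise_draw
    return max(0.0, raw)


_GROUPS = ("adequate", "poor")


def _default_group_params() -> dict:
    return {
        # published per-group mean +/- sd of the three imaging markers
        "adc": {"adequate": (0.96e-3, 0.24e-3), "poor": (1.24e-3, 0.26e-3)},
        "tdv": {"adequate": (95.3, 81.0), "poor": (57.8, 59.1)},
        "ff": {"adequate": (34.3, 23.1), "poor": (45.6, 25.6)},
    }


def _default_mprotein_probs() -> dict:
    # category counts per group: adequate IgG 13, IgA 3, IgD 0, BJ 0 (of 16);
    # poor IgG 9, IgA 5, IgD 1, BJ 7 (of 22)
    return {
        "adequate": (13 / 16, 3 / 16, 0.0, 0.0),
        "poor": (9 / 22, 5 / 22, 1 / 22, 7 / 22),
    }


def _default_covariate_params() -> dict:
    # (mean, sd), identical across groups: the published clinical
    # covariates showed no significant between-group differences
    return {
        "age_years": (60.5, 9.0),
        "wbc_10e3_per_ul": (2.81, 2.48),
        "neutrophil_10e3_per_ul": (1.84, 1.88),
        "platelet_10e4_per_ul": (156.0, 86.0),
        "hemoglobin_g_dl": (11.1, 1.7),
        "diagnosis_to_harvest_months": (9.0, 8.0),
    }


def _default_prior_lines_probs() -> dict:
    # adequate mobilizers mostly had a single prior line (12/16 vs 10/22)
    return {"adequate": (12 / 16, 3 / 16, 1 / 16), "poor": (10 / 22, 8 / 22, 4 / 22)}


@dataclass(frozen=True)
class CohortSpec:
    """Distributional parameters of a synthetic patient cohort.

    Defaults reproduce the published per-group summaries: 16 adequate
    harvesters vs 22 relatively poor mobilizers, group-wise marker
    normals, and Bence-Jones M protein confined to the poor group.
    """

    n_adequate: int = 16
    n_poor: int = 22
    group_params: dict = field(default_factory=_default_group_params)
    mprotein_probs: dict = field(default_factory=_default_mprotein_probs)
    yield_model: YieldModel = field(default_factory=YieldModel)
    covariate_params: dict = field(default_factory=_default_covariate_params)
    prior_lines_probs: dict = field(default_factory=_default_prior_lines_probs)
    adc_floor: float = 0.1e-3  # truncation keeping draws physically plausible
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_adequate < 1 or self.n_poor < 1:
            raise ValueError("group sizes must be >= 1")
        for marker, groups in self.group_params.items():
            for g, (_, sd) in groups.items():
                if sd < 0:
                    raise ValueError(f"sd for {marker}/{g} must be >= 0")
        for g, probs in self.mprotein_probs.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"mprotein_probs for group {g!r} must sum to 1")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, max_tries: int = 1000) -> float:
    """Draw N(mean, sd) conditioned on >= low, by rejection; clamp if starved."""
    if sd == 0:
        return max(mean, low)
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if x >= low:
            return float(x)
    return low


def _gamma_from_moments(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Non-negative draw with exactly the requested mean and sd.

    A gamma with shape (mean/sd)^2 and scale sd^2/mean matches both
    moments on [0, inf); tumor-burden-like markers whose sd rivals the
    mean are naturally right-skewed, which the gamma reflects.
    """
    if sd == 0 or mean <= 0:
        return max(float(mean), 0.0)
    shape = (mean / sd) ** 2
    return float(rng.gamma(shape, sd**2 / mean))


def _beta_from_moments(rng: np.random.Generator, mean: float, sd: float,
                       lo: float = 0.0, hi: float = 100.0) -> float:
    """Draw on [lo, hi] with the requested mean and sd via a scaled beta.

    Falls back to a clipped normal when the moments are infeasible for a
    beta on that interval.
    """
    span = hi - lo
    m = (mean - lo) / span
    v = (sd / span) ** 2
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    if not 0.0 < m < 1.0 or v >= m * (1.0 - m):
        return float(np.clip(rng.normal(mean, sd), lo, hi))
    k = m * (1.0 - m) / v - 1.0
    return float(lo + span * rng.beta(m * k, (1.0 - m) * k))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table, group-conditionally, reproducibly under seed.

    The mobilization group is drawn first (fixed sizes); median ADC comes
    from the per-group normal truncated below at ``spec.adc_floor``, tDV
    from a moment-matched gamma (non-negative), FF from a moment-matched
    beta on [0, 100], and the CD34+ yield is drawn from the ADC-linked
    model conditioned on landing on the group-consistent side of the
    4.0e6 cells/kg cutoff; the recorded class is then obtained from the
    yield through :func:`classify_yield` and always agrees with the group.
    """
    n_total = spec.n_adequate + spec.n_poor
    streams = np.random.SeedSequence(spec.seed).spawn(n_total)
    rows = []
    gp = spec.group_params
    for i in range(n_total):
        group = "adequate" if i < spec.n_adequate else "poor"
        rng = np.random.default_rng(streams[i])
        adc = _truncated_normal(rng, *gp["adc"][group], low=spec.adc_floor)
        tdv = _gamma_from_moments(rng, *gp["tdv"][group])
        ff = _beta_from_moments(rng, *gp["ff"][group])
        mprotein = MPROTEIN_CATEGORIES[
            rng.choice(len(MPROTEIN_CATEGORIES), p=spec.mprotein_probs[group])
        ]
        cov = {k: float(rng.normal(m, s)) for k, (m, s) in spec.covariate_params.items()}
        cov["age_years"] = float(np.clip(round(cov["age_years"]), 30, 85))
        for k in ("wbc_10e3_per_ul", "neutrophil_10e3_per_ul",
                  "platelet_10e4_per_ul", "hemoglobin_g_dl",
                  "diagnosis_to_harvest_months"):
            cov[k] = max(cov[k], 0.1)
        prior_lines = int(rng.choice((1, 2, 3), p=spec.prior_lines_probs[group]))

        total_yield = _draw_group_consistent_yield(rng, adc, spec.yield_model, group)
        mclass = classify_yield(total_yield).label
        rows.append({
            "patient_id": f"P{i + 1:03d}",
            "group": group,
            "mprotein_type": mprotein,
            "prior_lines": prior_lines,
            **cov,
            "tdv_ml": tdv,
            "median_adc_mm2_s": adc,
            "ff_percent": ff,
            "cd34_yield_cells_per_kg": total_yield,
            "mobilization_class": mclass,
        })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def _draw_group_consistent_yield(rng: np.random.Generator, adc: float,
                                 model: YieldModel, group: str,
                                 cutoff: float = 4.0e6,
                                 max_tries: int = 1000) -> float:
    """Yield from the ADC link, rejection-sampled onto the group's side of the cutoff."""
    for _ in range(max_tries):
        y = cd34_yield_from_adc(adc, model, rng.normal(0.0, model.noise_sd))
        adequate = y >= cutoff
        if adequate == (group == "adequate"):
            return y
    # degenerate model (e.g. zero noise on the wrong side): clamp to the boundary
    return cutoff if group == "adequate" else max(0.0, np.nextafter(cutoff, 0.0))
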