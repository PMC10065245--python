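# marrowquant

Whole-body diffusion-weighted MRI (DWI) quantification of multiple-myeloma
marrow burden, and prediction of hematopoietic stem-cell mobilization
failure from the derived imaging indices.

## The problem

Autologous stem-cell transplantation for multiple myeloma requires
harvesting enough CD34⁺ cells from peripheral blood; patients yielding
fewer than 4.0×10⁶ CD34⁺ cells/kg are *relatively poor mobilizers*, and
identifying them before mobilization is clinically valuable.  Whole-body
DWI characterizes the marrow non-invasively: the apparent diffusion
coefficient (ADC), estimated per voxel from the mono-exponential decay
S_b = S₀·exp(−b·ADC) between b = 0 and b = 1000 s/mm², is low in
hypercellular tissue and high where water diffuses freely, and the
chemical-shift (Dixon) fat fraction FF = fat / in-phase measures marrow
fat replacement.

`marrowquant` implements, as a tested and reusable pipeline:

1. **Semi-automated lesion segmentation** — coronal maximum-intensity
   projection (MIP) of the b=1000 volume, min–max normalization to a
   0–255 scale, background removal at a fixed threshold of 97, Otsu
   binarization of the surviving pixels, removal of non-skeletal
   high-signal structures through an exclusion mask, a T2 shine-through
   filter (keep ADC ≤ 2.0×10⁻³ mm²/s), and extraction of the **total
   diffusion volume** (tDV): surviving voxels with ADC > 0.55×10⁻³ mm²/s.
2. **Per-patient indices** — tDV in ml, the median ADC of the tDV, and
   the mean FF of rectangular lumbar (L1–L3) vertebral ROIs.
3. **Cohort statistics** — Mann–Whitney U (exact for small tie-free
   samples) and Fisher exact tests for the univariate screen, stepwise
   forward/backward regression of the CD34⁺ yield, and empirical ROC
   analysis of median ADC with a Youden-index cutoff (predicted poor when
   median ADC strictly exceeds the cutoff).
4. **Synthetic data** — skeletal DWI/Dixon phantoms with ground-truth
   lesion masks, and cohorts whose group-wise marker distributions match
   published summary statistics (median ADC 0.96 ± 0.24 vs
   1.24 ± 0.26 ×10⁻³ mm²/s in 16 adequate vs 22 poor mobilizers), so the
   whole chain is testable without patient data.

## Worked example

```python
import numpy as np
from marrowquant import (PhantomSpec, Lesion, Organ, generate_phantom_study,
                         segment_lesions, quantify_study, predict_mobilization)

spec = PhantomSpec(
    lesions=(Lesion(center_mm=(32, 32, 32), radius_mm=10, target_adc=1.0e-3),),
    organs=(Organ(center_mm=(32, 56, 32), radius_mm=5),),  # bladder analogue
    noise_sd=0.0, seed=7,
)
study = generate_phantom_study(spec)
seg = segment_lesions(study)
idx = quantify_study(study, seg)
print(f"tDV {idx.tdv_ml:.1f} ml, median ADC {idx.median_adc*1e3:.2f}e-3 mm^2/s,"
      f" mean FF {idx.ff_mean_percent:.1f}%")
print("predicted mobilization:", predict_mobilization(idx.median_adc))
```

prints

```
tDV 4.2 ml, median ADC 1.00e-3 mm^2/s, mean FF 28.3%
predicted mobilization: adequate
```

The 10-mm lesion's analytic volume is 4.19 ml, and every lesion voxel
carries the prescribed ADC of 1.0×10⁻³ mm²/s on this noise-free phantom,
so the chain recovers both exactly (up to voxel discretization); the
organ blob is removed by the exclusion mask and never enters the tDV.
The prediction is *adequate* because 1.0×10⁻³ does not exceed the
1.18×10⁻³ mm²/s cutoff.

On the statistical side:

```python
from marrowquant import CohortSpec, generate_cohort, run_full_analysis
report = run_full_analysis(generate_cohort(CohortSpec(seed=11)))
print(f"AUC {report.roc.auc:.3f}, Youden cutoff "
      f"{report.roc.youden_cutoff*1e3:.2f}e-3 mm^2/s")
```

prints `AUC 0.707, Youden cutoff 1.24e-3 mm^2/s` for that seed — a single
38-patient cohort scatters around the population AUC of
Φ(0.28/√(0.24²+0.26²)) ≈ 0.786 implied by the two group normals.

A command-line interface chains the stages
(`marrowquant simulate-phantom | simulate-cohort | segment | quantify |
analyze | run-all`); `run-all` takes a YAML config and writes the cohort
CSV, a JSON report, and a provenance log, deterministically for a fixed
seed.

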