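# gratiokit

Longitudinal quantitative MRI of myelin and axonal integrity: parametric
MTR/MTsat mapping, aggregate MRI g-ratio construction, ROI summarisation,
test–retest agreement and longitudinal mixed-model statistics — plus a
synthetic two-timepoint cohort generator with known ground truth for
validating every stage.

It is aimed at neuroimaging researchers who track microstructural change
in white matter — for example in recently diagnosed relapsing-remitting
multiple sclerosis (RRMS), where subtle demyelination in
normal-appearing white matter (NAWM) precedes atrophy — and who need the
full chain from raw FLASH volumes to covariate-adjusted group statistics
in one tested, scriptable package.

## The measurements

**MTsat.** Three spoiled gradient-echo (FLASH) volumes — a
proton-density-weighted pair with and without an off-resonance MT pulse
(MT_on, MT_off; flip α₁ = 5°, TR₁ = 30 ms) and a T1-weighted volume
(α₂ = 18°, TR₂ = 15 ms) — allow voxelwise estimation of the apparent
amplitude and longitudinal relaxation rate,

    R1_app = ½ (S_T1w α₂/TR₂ − S_off α₁/TR₁) / (S_off/α₁ − S_T1w/α₂)
    A_app  = S_off S_T1w (TR₁ α₂/α₁ − TR₂ α₁/α₂) / (S_T1w TR₁ α₂ − S_off TR₂ α₁)

and from them the per-excitation MT saturation fraction

    δ = (A_app α₁ / S_on − 1) R1_app TR₁ − α₁²/2,

reported ×100 as MTsat (%). Unlike the classical ratio
MTR = 100 (S_off − S_on)/S_off, MTsat analytically corrects for flip-angle
and T1 effects. Echoes are summed before fitting to raise SNR.

**g-ratio.** With the myelin volume fraction taken as linearly scaled
MTsat (MVF = k·MTsat) and the axonal volume fraction assembled from
NODDI's restricted and free-water fractions,
AVF = (1 − MVF)(1 − ISOVF)·ICVF, the aggregate g-ratio per voxel is

    g = √( AVF / (AVF + MVF) ).

The constant k is calibrated so that pooled healthy-control white-matter
mean g hits a target (default 0.581).

**Statistics.** Control test–retest pairs give Bland–Altman limits of
agreement (mean difference ± 1.96 SD) and exact binomial sign tests.
Patient change is screened with paired t-tests, then modelled with
random-intercept linear mixed models (ML) adjusting for age, sex,
disease-modifying-therapy initiation and time-varying lesion load, with
Benjamini–Hochberg FDR correction per region and Nakagawa marginal R²
as a fit summary.

## Worked example

```python
from gratiokit import CohortConfig, generate_cohort, analyze_cohort

cohort = generate_cohort(CohortConfig(seed=0))   # 62 patients + 11 controls
res = analyze_cohort(cohort)
print(f"k = {res['k']:.4f}")
print(res["agreement"][["metric", "mean_t1", "mean_diff", "loa_half_width", "sign_test_p"]].round(4))
print(res["pattern"])
```

prints

```
k = 0.1364
   metric  mean_t1  mean_diff  loa_half_width  sign_test_p
0  gratio   0.5810     0.0016          0.0144       1.0000
1    icvf   0.6071    -0.0001          0.0045       1.0000
2   isovf   0.0856    -0.0014          0.0066       1.0000
3     mtr  54.5684    -0.2170          0.9101       0.5488
4   mtsat   3.8218    -0.0131          0.1365       1.0000
{('nawm', 'mtsat'): '-', ('nawm', 'mtr'): '0', ('nawm', 'gratio'): '+',
 ('nawm', 'icvf'): '+', ('nawm', 'isovf'): '0', ('wml', 'mtsat'): '+',
 ('wml', 'mtr'): '0', ('wml', 'gratio'): '0', ('wml', 'icvf'): '+',
 ('wml', 'isovf'): '+'}
```

`k` is the calibrated MVF scaling constant (control WM mean g lands on
0.581 by construction). The agreement table shows control test–retest
means, mean differences and 95% limits of agreement per metric; none of
the sign tests rejects, as expected when no true change is simulated.
The pattern dictionary gives the direction of FDR-significant adjusted
longitudinal change per region and metric: here NAWM loses MTsat while
g-ratio and ICVF rise, lesions gain MTsat/ICVF/ISOVF, and MTR shows no
adjusted change in either region.

The same stages are exposed on the command line:

```sh
gratiokit simulate --out sim/ --seed 1
gratiokit fit-mt --mt-on on.nii.gz --mt-off off.nii.gz --t1w t1w.nii.gz --out maps/
gratiokit fit-gratio --mtsat maps/mtsat.nii.gz --icvf icvf.nii.gz --isovf isovf.nii.gz --k 0.139 --out gr/
gratiokit run --out run1/ --seed 1    # full pipeline with manifest
```

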