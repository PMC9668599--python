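# Methods

## Signal model and estimators

The MT protocol is modelled as three spoiled gradient-echo (FLASH)
steady states. Two forward models are implemented:

* **exact** — the ideally spoiled Ernst steady state,
  `S = A sin α (1 − E1) / (1 − cos α (1 − δ) E1)` with `E1 = exp(−TR·R1)`,
  where the off-resonance MT pulse removes the fraction δ of
  longitudinal magnetisation each TR;
* **rational** — the small-angle, short-TR approximation
  `S = A α TR R1 / (α²/2 + δ + TR·R1)`.

The dual-flip-angle estimators for `A_app`, `R1_app` and δ (see the
README for the formulas) are *exact* algebraic inverses of the rational
model. Keeping both models separates two questions: estimator
correctness (tested as machine-precision round trips on rational
signals) and model approximation error (characterised against exact-SPGR
signals; at 5°/18°, TR 30/15 ms the MTsat bias is below 0.2 percentage
points and shrinks with flip angle). The synthetic cohort uses the
rational model by default so that every downstream discrepancy is
attributable to noise, not to the forward/inverse mismatch.

No B1 correction is applied: the emulated protocol acquires no B1 map,
and MTsat is comparatively robust to transmit-field error. Echo
summation assumes magnitude data; with a tissue-independent T2* (50 ms
default) the three-echo decay factors cancel in MTR and MTsat, which are
invariant to any common scaling of the inputs.

Voxels where an inversion is undefined — non-positive signals, singular
flip-angle denominators, zero AVF — are flagged NaN and excluded from
ROI statistics, never clamped or zero-filled; negative MTsat values
(noise floor) are retained.

## g-ratio chain and calibration

`MVF = k·MTsat[%]` (slope-only; no intercept), `AVF = (1 − MVF)(1 −
ISOVF)·ICVF`, `g = √(AVF/(AVF+MVF))`. The aggregate g-ratio ignores
fibre-orientation dispersion and is undefined where AVF = 0. The
scaling constant k is not observable directly; it is chosen by bracketed
1-D root-finding (tolerance 1e-6 on the mean) so that pooled control
white-matter mean g equals a configurable target, default 0.581, a
standard healthy-WM operating point. The pooled mean is strictly
decreasing in k, so the root is unique; during calibration only, fully
myelinated voxels take the limiting value g = 0 to keep the objective
monotone across the whole bracket.

The cerebellum stand-in region is excluded from NODDI and g-ratio
statistics via an exclusion mask (diffusion coverage of the cerebellum
is typically unreliable); MTsat/MTR statistics use the full masks.

## ROI summarisation

NAWM = (white matter − lesions) eroded by one voxel with a 3×3×3 box
(26-connectivity) kernel, the common neuroimaging default, to limit
partial-volume contamination. Region statistics (mean, median, SD,
voxel count) ignore NaN-flagged voxels; the subject-level statistic
carried into group analyses is the region **mean**. The brain
parenchymal fraction is brain volume including lesions divided by
intracranial volume, from voxel counts.

## Agreement and longitudinal statistics

* **Bland–Altman**: differences retest − test; SD with n−1 denominator;
  limits mean ± 1.96 SD (fixed multiplier, the 95% convention — not a
  t-quantile).
* **Sign test**: exact two-sided binomial, `p = min(1, 2·min(P(X≤k),
  P(X≥k)))`, zero differences dropped. At test–retest sample sizes
  around n = 10 the normal approximation is inaccurate, so the exact
  form is required.
* **Paired t** screens each metric/region at α = 0.05; screened metrics
  get a random-intercept linear mixed model fitted by maximum
  likelihood: `value ~ time + age + sex + lesion_load + dmt + (1 |
  subject)`. Lesion load is time-varying (% of ICV at each visit); DMT
  is a baseline initiation flag; interaction terms are configurable and
  off by default. Mixed-model time-effect p-values are
  Benjamini–Hochberg-corrected within each region's family of fitted
  metrics — the narrowest defensible family. Nakagawa marginal R² is
  computed from the variance components as σ²_f/(σ²_f+σ²_r+σ²_e), with
  σ²_f the variance of the fixed-effect linear predictor. Wald
  (normal) p-values are reported for fixed effects; Satterthwaite
  degrees of freedom and estimated marginal means are out of scope.
* **Correlations of change** use Pearson's r (reported with r²);
  subgroup comparisons (e.g. new lesions vs none) use Welch's t-test
  with Satterthwaite df.

## The synthetic cohort

The generator emulates a two-arm longitudinal study on a 32×32×16,
1 mm-isotropic axial slab: concentric ellipsoidal ICV/brain/white-matter
compartments, up to three spherical lesions placed in the white-matter
interior (lesion volume set by a lognormal lesion load, median 0.572%
of ICV), an inferior cap standing in for the cerebellum, and volumes
born co-registered (registration is out of scope). Masks are fixed
across timepoints by default; options exist to grow lesions with the
lesion-load trajectory and to shrink the brain by an annual atrophy
fraction (default 0 — no atrophy is simulated).

Subject-level metric values (MTsat %, MTR %, ICVF, ISOVF) are drawn per
region from Gaussian distributions whose defaults are healthy-control
white matter (3.74/54.51/0.605/0.086, SDs 0.13/0.66/0.022/0.008) and
patient NAWM/lesion values (NAWM 3.80/54.25/0.577/0.075; WML
2.35/47.33/0.379/0.095; between-subject SDs set to a quarter of the
observed ranges). Patients' follow-up values shift by the configured
annual effects (NAWM: MTsat −0.03, MTR −0.01, ICVF +0.002, ISOVF 0;
WML: MTsat +0.08, ICVF +0.021, ISOVF +0.010 per year).

Every acquisition adds ROI-level measurement noise of SD s/√2 per
metric, where s is the target SD of a test–retest *difference*
(defaults 0.09/0.68/0.003/0.003) — so a control pair differs with
exactly SD s. No additional patient change-heterogeneity is modelled.
Voxel noise is additive Gaussian by default (SD 0.5 signal units
against amplitudes near 1000, i.e. high SNR, so ROI means are dominated
by the subject-level terms; a Rician mode is available), and NODDI maps
carry 0.01 additive noise, clipped to [0, 1].

**Lesion MTR and confounding.** The lesion-region MTR is coupled in
level to the lesion-load covariate (slope ≈ 2.1 MTR% per %ICV, centred
at the population mean load and scaled so the marginal one-year change
is 0.47%), while its pure time effect is zero. Because the same slope
acts between and within subjects, a mixed model that includes
time-varying lesion load attributes the change to the covariate
(β_time ≈ 0) even though the unadjusted paired t-test detects it — the
situation where adjusted and unadjusted longitudinal inference
genuinely diverge, which the generator is designed to exhibit. A
side-effect is extra between-subject lesion-MTR variance beyond the
configured SD.

Metric-scale draws are converted to tissue parameters by δ = MTsat/100
and `R1 = (δ/f − δ − α₁²/2)/TR₁` with f the MTR fraction — the exact
inversion under the rational model — so the painted voxels reproduce
the drawn metrics through the full fitting chain.

**What the generator does not emulate**, and hence what passing tests
cannot show about scanner data: k-space/coil physics and artefacts,
B1/B0 inhomogeneity, registration error, partial-volume mixing beyond
the one-voxel erosion, diffusion signal formation (NODDI maps are
generated directly as parameter fields), spatially varying T2*, lesion
heterogeneity, and real covariate–outcome confounding beyond the single
lesion-load coupling described above.

## Problem sizes and determinism

Defaults mirror the emulated study: 62 patients, 11 controls, two
timepoints. Statistical calibration checks use 10⁴ Monte-Carlo
replicates (Bland–Altman coverage, paired-t type-I error); estimator
round-trips use 2,000 random tissues; the end-to-end pattern-recovery
rate uses 20 full cohort replicates. All randomness flows from a single
`numpy` Generator seed; the same seed reproduces bit-identical volumes,
tables and CSV outputs.

## Known limitations

* The per-replicate probability that *every* component of the expected
  longitudinal significance pattern is simultaneously FDR-significant
  is materially below 1 at the default effect sizes and noise levels:
  the NAWM MTsat effect (−0.03/yr against a 0.09 difference SD at
  n = 62) carries ≈ 70% power at α = 0.05, and the NAWM g-ratio effect
  ≈ 85%, so the joint pattern reproduces in roughly half to two-thirds
  of replicates. This is a property of the emulated study conditions
  themselves, not of the estimators.
* Mixed-model inference uses Wald z p-values (no small-sample df
  correction); with 62 subjects × 2 visits the difference is minor.
* MVF scaling is slope-only; any true MTsat offset in real data would
  bias MVF multiplicatively through the calibration.
* The sign test and Bland–Altman limits assume exchangeable pairs;
  no repeatability coefficient or ICC variants are provided.
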