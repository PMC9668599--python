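"""Synthetic two-timepoint RRMS-like cohort with known ground truth.

The generator emulates the data a longitudinal MT / NODDI / g-ratio study
would acquire, with every downstream estimand known by construction:

* a patient arm (default n=62) imaged at baseline (M0) and one year
  (M12), with white-matter lesions, region-wise tissue parameters drawn
  from published white-matter distributions, and configurable annual
  effects;
* a healthy-control test-retest arm (default n=11) imaged twice with no
  true change, providing agreement reference limits and the g-ratio
  calibration set.

Per subject, timepoint and region, metric-scale values (MTsat %, MTR %,
ICVF, ISOVF) are drawn at subject level, perturbed by per-acquisition
measurement noise, converted to FLASH tissue parameters (A, R1, delta),
and painted into co-registered volumes; three-echo MT_on / MT_off /
MT_T1w series are forward-simulated (rational model by default, so the
map estimators are exact inverses) with additive voxel noise.  WML MTR
change is mediated by the time-varying lesion-load covariate rather than
a pure time effect, so that covariate-adjusted mixed models absorb it
while paired t-tests detect it.

Volumes are born co-registered on a 1 mm isotropic axial slab; no
k-space, coil or artefact simulation, and NODDI maps are generated
directly as parameter fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import DEFAULT_PROTOCOL, AcquisitionParams
from .flash import simulate_flash_signal
from .roi import nawm_mask
from .volume import MaskSet, VolumeMap

__all__ = [
    "TissueParams",
    "CohortConfig",
    "SubjectScan",
    "Subject",
    "SyntheticCohort",
    "generate_cohort",
]

METRICS = ("mtsat", "mtr", "icvf", "isovf")

# --- Default study conditions (white-matter metric distributions) ---------

#: Patient region means at baseline.
PATIENT_MEANS = {
    "nawm": {"mtsat": 3.80, "mtr": 54.25, "icvf": 0.577, "isovf": 0.075},
    "wml": {"mtsat": 2.35, "mtr": 47.33, "icvf": 0.379, "isovf": 0.095},
}
#: Between-subject SDs (quarter of the published ranges).
PATIENT_BETWEEN_SD = {
    "nawm": {"mtsat": 0.16, "mtr": 1.37, "icvf": 0.034, "isovf": 0.011},
    "wml": {"mtsat": 0.32, "mtr": 2.30, "icvf": 0.046, "isovf": 0.0365},
}
#: Healthy-control white matter.
CONTROL_MEANS = {"wm": {"mtsat": 3.74, "mtr": 54.51, "icvf": 0.605, "isovf": 0.086}}
CONTROL_BETWEEN_SD = {"wm": {"mtsat": 0.13, "mtr": 0.66, "icvf": 0.022, "isovf": 0.008}}
#: Annual effects (metric units / year); WML MTR change enters through
#: lesion-load coupling instead of a pure time effect.
ANNUAL_EFFECTS = {
    "nawm": {"mtsat": -0.03, "mtr": -0.01, "icvf": 0.002, "isovf": 0.0},
    "wml": {"mtsat": 0.08, "mtr": 0.0, "icvf": 0.021, "isovf": 0.010},
}
#: SD of a control test-retest *difference* per metric; per-acquisition
#: noise is this divided by sqrt(2).
RETEST_DIFF_SD = {"mtsat": 0.09, "mtr": 0.68, "icvf": 0.003, "isovf": 0.003}
#: Non-WM brain tissue (grey-matter-like filler; not analysed).
GM_PARAMS = {"mtsat": 1.8, "mtr": 38.0, "icvf": 0.40, "isovf": 0.15}

#: Marginal WML MTR change (percent/year) delivered via lesion-load coupling.
WML_MTR_MARGINAL_CHANGE = 0.47


@dataclass(frozen=True)
class TissueParams:
    """Voxel-level FLASH + NODDI ground truth for one tissue."""

    a: float  # signal amplitude, arbitrary units, > 0
    r1: float  # apparent longitudinal relaxation rate, 1/s
    delta: float  # per-excitation MT saturation fraction (x100 = MTsat %)
    icvf: float
    isovf: float

    def __post_init__(self) -> None:
        vals = (self.a, self.r1, self.delta, self.icvf, self.isovf)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("tissue parameters must be finite")
        if self.a <= 0 or self.r1 <= 0 or self.delta < 0:
            raise ValueError("require a > 0, r1 > 0, delta >= 0")
        if not (0 <= self.icvf <= 1 and 0 <= self.isovf <= 1):
            raise ValueError("icvf and isovf must lie in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Everything that defines a simulated cohort."""

    n_patients: int = 62
    n_controls: int = 11
    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size_mm: float = 1.0
    acq: AcquisitionParams = DEFAULT_PROTOCOL
    signal_model: str = "rational"  # "rational" | "exact"
    noise_model: str = "gaussian"  # "gaussian" | "rician"

    region_means: dict = field(default_factory=lambda: {**PATIENT_MEANS, **CONTROL_MEANS})
    between_sd: dict = field(
        default_factory=lambda: {**PATIENT_BETWEEN_SD, **CONTROL_BETWEEN_SD}
    )
    annual_effects: dict = field(default_factory=lambda: ANNUAL_EFFECTS)
    retest_diff_sd: dict = field(default_factory=lambda: RETEST_DIFF_SD)

    #: additive noise SD per echo image, in signal units (amplitude ~ 1000)
    voxel_noise_sd: float = 0.5
    #: additive noise SD on NODDI parameter maps
    noddi_voxel_noise_sd: float = 0.01
    #: echo decay time constant used for the multi-echo readout, seconds
    t2_star_s: float = 0.05
    amplitude_mean: float = 1000.0
    amplitude_sd: float = 50.0

    # demographics / covariates
    dmt_fraction: float = 38 / 62
    female_fraction: float = 48 / 62
    age_mean: float = 37.6
    age_sd: float = 10.0
    age_range: tuple[float, float] = (21.0, 68.0)
    #: lognormal lesion-load (% of ICV): median at baseline and of the
    #: one-year increase, with log-scale sigmas
    lesion_load_median: float = 0.572
    lesion_load_sigma_log: float = 0.9
    lesion_growth_median: float = 0.165
    lesion_growth_sigma_log: float = 0.8
    #: MTR percent per lesion-load %ICV; default scaled so the marginal
    #: WML MTR change equals WML_MTR_MARGINAL_CHANGE
    wml_mtr_lesion_slope: float | None = None
    new_lesion_fraction: float = 0.5
    #: annual brain-volume loss fraction (0 = no atrophy simulated)
    atrophy_per_year: float = 0.0
    grow_lesions: bool = False

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least two subjects per arm")
        if self.signal_model not in ("rational", "exact"):
            raise ValueError("signal_model must be 'rational' or 'exact'")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        if self.voxel_noise_sd < 0 or self.noddi_voxel_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        for region, sds in self.between_sd.items():
            if any(v < 0 for v in sds.values()):
                raise ValueError(f"negative between-subject SD in region {region!r}")
        if any(v < 0 for v in self.retest_diff_sd.values()):
            raise ValueError("negative test-retest SD")

    @property
    def mtr_lesion_slope(self) -> float:
        if self.wml_mtr_lesion_slope is not None:
            return self.wml_mtr_lesion_slope
        mean_growth = self.lesion_growth_median * math.exp(
            self.lesion_growth_sigma_log**2 / 2
        )
        return WML_MTR_MARGINAL_CHANGE / mean_growth


@dataclass
class SubjectScan:
    """All volumes acquired at one visit (co-registered by construction)."""

    mt_on_echoes: list[VolumeMap]
    mt_off_echoes: list[VolumeMap]
    mt_t1w_echoes: list[VolumeMap]
    icvf: VolumeMap
    isovf: VolumeMap


@dataclass
class Subject:
    subject_id: str
    arm: str  # "patient" | "control"
    masks: dict[str, MaskSet]  # keyed by timepoint label
    scans: dict[str, SubjectScan]
    meta: dict[str, dict]  # timepoint label -> covariate dict
    truth: dict  # (timepoint, region, metric) -> subject-level true value

    @property
    def timepoints(self) -> list[str]:
        return list(self.scans)


@dataclass
class SyntheticCohort:
    config: CohortConfig
    subjects: list[Subject]
    affine: np.ndarray

    @property
    def patients(self) -> list[Subject]:
        return [s for s in self.subjects if s.arm == "patient"]

    @property
    def controls(self) -> list[Subject]:
        return [s for s in self.subjects if s.arm == "control"]

    def meta_table(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for tp, cov in s.meta.items():
                rows.append({"subject": s.subject_id, "arm": s.arm, "timepoint": tp, **cov})
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        """Write NIfTI volumes, masks and the metadata CSV to a directory."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s in self.subjects:
            sdir = outdir / s.subject_id
            for tp, scan in s.scans.items():
                tdir = sdir / tp
                tdir.mkdir(parents=True, exist_ok=True)
                s.masks[tp].save(tdir)
                for name in ("mt_on", "mt_off", "mt_t1w"):
                    for i, echo in enumerate(getattr(scan, f"{name}_echoes"), 1):
                        echo.save(tdir / f"{name}_e{i}.nii.gz")
                scan.icvf.save(tdir / "icvf.nii.gz")
                scan.isovf.save(tdir / "isovf.nii.gz")
        self.meta_table().to_csv(outdir / "metadata.csv", index=False)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _ellipsoid(shape, semi_axes, centre=None) -> np.ndarray:
    nx, ny, nz = shape
    if centre is None:
        centre = ((nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2)
    x, y, z = np.ogrid[:nx, :ny, :nz]
    ax, ay, az = semi_axes
    d = (
        ((x - centre[0]) / ax) ** 2
        + ((y - centre[1]) / ay) ** 2
        + ((z - centre[2]) / az) ** 2
    )
    return d <= 1.0


def _sphere(shape, centre, radius) -> np.ndarray:
    return _ellipsoid(shape, (radius, radius, radius), centre)


@dataclass(frozen=True)
class _Geometry:
    """Per-subject random geometry, drawn once and reused across timepoints."""

    brain_scale: float
    lesion_centres: tuple[tuple[int, int, int], ...]


def _draw_geometry(
    config: CohortConfig, rng: np.random.Generator, with_lesions: bool
) -> _Geometry:
    shape = config.grid_shape
    nx, ny, nz = shape
    brain_scale = float(np.clip(rng.normal(0.97, 0.008), 0.94, 0.995))
    centres: tuple[tuple[int, int, int], ...] = ()
    if with_lesions:
        wm = _ellipsoid(shape, (0.44 * 0.72 * nx, 0.44 * 0.72 * ny, 0.44 * 0.72 * nz))
        interior = np.argwhere(nawm_mask(wm, None, iterations=2))
        n_lesions = 3
        picks = interior[rng.choice(len(interior), size=n_lesions, replace=False)]
        centres = tuple(tuple(int(v) for v in c) for c in picks)
    return _Geometry(brain_scale=brain_scale, lesion_centres=centres)


def _make_masks(
    config: CohortConfig,
    geom: _Geometry,
    lesion_load_pct: float | None,
    affine: np.ndarray,
    atrophy_factor: float = 1.0,
) -> MaskSet:
    shape = config.grid_shape
    nx, ny, nz = shape
    icv_axes = (0.44 * nx, 0.44 * ny, 0.44 * nz)
    icv = _ellipsoid(shape, icv_axes)
    # volume-preserving interpretation: linear scale is cube root of volume
    lin = geom.brain_scale * atrophy_factor ** (1.0 / 3.0)
    brain = _ellipsoid(shape, tuple(a * lin for a in icv_axes))
    wm = _ellipsoid(shape, tuple(a * 0.72 for a in icv_axes))

    # inferior cap standing in for the cerebellum (excluded from dMRI / g)
    z = np.arange(nz).reshape(1, 1, nz)
    exclude = brain & np.broadcast_to(z < max(2, nz // 6), shape)

    wml = None
    if lesion_load_pct is not None:
        target_vox = max(7, int(round(lesion_load_pct / 100.0 * icv.sum())))
        n_lesions = int(np.clip(round(target_vox / 30), 1, len(geom.lesion_centres)))
        per_lesion = target_vox / n_lesions
        radius = max(1.45, (3.0 * per_lesion / (4.0 * np.pi)) ** (1.0 / 3.0))
        wml = np.zeros(shape, dtype=bool)
        for c in geom.lesion_centres[:n_lesions]:
            wml |= _sphere(shape, c, radius)
        wml &= wm

    masks = MaskSet(brain=brain, icv=icv, wm=wm, wml=wml, exclude=exclude, affine=affine)
    if not nawm_mask(masks.wm, masks.wml).any():
        raise ValueError("degenerate grid: NAWM is empty after one-voxel erosion")
    return masks


# ---------------------------------------------------------------------------
# metric-scale -> tissue parameters
# ---------------------------------------------------------------------------


def _r1_from_metrics(mtsat_pct: float, mtr_pct: float, acq: AcquisitionParams) -> float:
    """Invert the rational-model MTR to the R1 consistent with both metrics."""
    delta = mtsat_pct / 100.0
    f = mtr_pct / 100.0
    tr_r1 = delta / f - delta - acq.alpha1**2 / 2.0
    if tr_r1 <= 0:
        raise ValueError(
            f"inconsistent metric pair (MTsat={mtsat_pct}, MTR={mtr_pct}): implied R1 <= 0"
        )
    return tr_r1 / acq.tr1


def _noisy(
    signal: np.ndarray, sd: float, rng: np.random.Generator, noise_model: str
) -> np.ndarray:
    if sd == 0:
        return signal
    if noise_model == "gaussian":
        return signal + rng.normal(0.0, sd, size=signal.shape)
    re = signal + rng.normal(0.0, sd, size=signal.shape)
    im = rng.normal(0.0, sd, size=signal.shape)
    return np.hypot(re, im)


def _simulate_scan(
    config: CohortConfig,
    amplitude: float,
    region_metrics: dict[str, dict[str, float]],
    labels: np.ndarray,
    affine: np.ndarray,
    rng: np.random.Generator,
) -> SubjectScan:
    """Paint regional tissue params and forward-simulate all volumes.

    ``region_metrics`` maps integer region label -> metric dict; label 0
    is background (zero signal).
    """
    acq = config.acq
    shape = labels.shape
    a_map = np.zeros(shape)
    r1_map = np.zeros(shape)
    d_map = np.zeros(shape)
    icvf_map = np.zeros(shape)
    isovf_map = np.zeros(shape)

    for label, metrics in region_metrics.items():
        sel = labels == label
        a_map[sel] = amplitude
        d_map[sel] = metrics["mtsat"] / 100.0
        r1_map[sel] = _r1_from_metrics(metrics["mtsat"], metrics["mtr"], acq)
        icvf_map[sel] = metrics["icvf"]
        isovf_map[sel] = metrics["isovf"]

    inside = labels > 0

    def contrasts(flip, tr, mt_on):
        steady = np.zeros(shape)
        steady[inside] = simulate_flash_signal(
            a_map[inside],
            r1_map[inside],
            d_map[inside],
            flip=flip,
            tr=tr,
            model=config.signal_model,
            mt_on=mt_on,
        )
        echoes = []
        for te in acq.echo_times:
            echo = steady * np.exp(-te / config.t2_star_s)
            echo = _noisy(echo, config.voxel_noise_sd, rng, config.noise_model)
            echoes.append(VolumeMap(echo, affine))
        return echoes

    mt_off = contrasts(acq.alpha1, acq.tr1, mt_on=False)
    mt_on = contrasts(acq.alpha1, acq.tr1, mt_on=True)
    mt_t1w = contrasts(acq.alpha2, acq.tr2, mt_on=False)

    noddi = []
    for fld in (icvf_map, isovf_map):
        noisy = _noisy(fld, config.noddi_voxel_noise_sd, rng, "gaussian")
        noisy = np.clip(noisy, 0.0, 1.0)
        noisy[~inside] = 0.0
        noddi.append(VolumeMap(noisy, affine))

    return SubjectScan(
        mt_on_echoes=mt_on,
        mt_off_echoes=mt_off,
        mt_t1w_echoes=mt_t1w,
        icvf=noddi[0],
        isovf=noddi[1],
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_LABELS = {"background": 0, "gm": 1, "wm": 2, "wml": 3}


def _region_labels(masks: MaskSet) -> np.ndarray:
    labels = np.zeros(masks.brain.shape, dtype=np.int8)
    labels[masks.brain] = _LABELS["gm"]
    labels[masks.wm] = _LABELS["wm"]
    if masks.wml is not None:
        labels[masks.wml] = _LABELS["wml"]
    return labels


def _acquisition_noise(config: CohortConfig, rng: np.random.Generator) -> dict[str, float]:
    return {
        m: float(rng.normal(0.0, config.retest_diff_sd[m] / math.sqrt(2.0)))
        for m in METRICS
    }


def _draw_baseline(
    config: CohortConfig, region: str, rng: np.random.Generator
) -> dict[str, float]:
    means = config.region_means[region]
    sds = config.between_sd[region]
    return {m: float(rng.normal(means[m], sds[m])) for m in METRICS}


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate the full two-arm cohort; bit-identical for a fixed seed."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    affine = np.diag([config.voxel_size_mm] * 3 + [1.0])

    subjects: list[Subject] = []

    for i in range(config.n_patients):
        sid = f"P{i + 1:03d}"
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), *config.age_range))
        sex = "F" if rng.random() < config.female_fraction else "M"
        dmt = bool(rng.random() < config.dmt_fraction)
        new_lesions = bool(rng.random() < config.new_lesion_fraction)
        ll0 = float(
            config.lesion_load_median
            * math.exp(rng.normal(0.0, config.lesion_load_sigma_log))
        )
        ll_growth = float(
            config.lesion_growth_median
            * math.exp(rng.normal(0.0, config.lesion_growth_sigma_log))
        )
        amplitude = float(max(rng.normal(config.amplitude_mean, config.amplitude_sd), 1.0))

        geom = _draw_geometry(config, rng, with_lesions=True)
        masks_m0 = _make_masks(config, geom, lesion_load_pct=ll0, affine=affine)

        baseline = {r: _draw_baseline(config, r, rng) for r in ("nawm", "wml")}
        scans, meta, truth, masks_by_tp = {}, {}, {}, {}
        for tp, time in (("M0", 0.0), ("M12", 1.0)):
            ll_t = ll0 + ll_growth * time
            if time > 0 and (config.grow_lesions or config.atrophy_per_year > 0):
                masks = _make_masks(
                    config,
                    geom,
                    lesion_load_pct=ll_t if config.grow_lesions else ll0,
                    affine=affine,
                    atrophy_factor=1.0 - config.atrophy_per_year * time,
                )
            else:
                masks = masks_m0
            masks_by_tp[tp] = masks
            labels = _region_labels(masks)
            region_metrics: dict[int, dict[str, float]] = {
                _LABELS["gm"]: dict(GM_PARAMS)
            }
            for region, label in (("nawm", _LABELS["wm"]), ("wml", _LABELS["wml"])):
                eps = _acquisition_noise(config, rng)
                values = {}
                for m in METRICS:
                    v = baseline[region][m] + config.annual_effects[region][m] * time
                    if region == "wml" and m == "mtr":
                        # lesion-load-coupled component: couples in *level*
                        # (same between- and within-subject slope), so a
                        # mixed model with time-varying lesion load absorbs
                        # the marginal change while paired t-tests detect it
                        ll_mean = config.lesion_load_median * math.exp(
                            config.lesion_load_sigma_log**2 / 2
                        )
                        v += config.mtr_lesion_slope * (ll_t - ll_mean)
                    v += eps[m]
                    if m in ("icvf", "isovf"):
                        v = float(np.clip(v, 0.0, 1.0))
                    values[m] = v
                    truth[(tp, region, m)] = v
                region_metrics[label] = values
            scans[tp] = _simulate_scan(config, amplitude, region_metrics, labels, affine, rng)
            meta[tp] = {
                "time": time,
                "age": age,
                "sex": sex,
                "dmt": dmt,
                "lesion_load": ll_t,
                "new_lesions": new_lesions,
            }
        subjects.append(
            Subject(
                subject_id=sid,
                arm="patient",
                masks=masks_by_tp,
                scans=scans,
                meta=meta,
                truth=truth,
            )
        )

    for i in range(config.n_controls):
        sid = f"C{i + 1:03d}"
        age = float(np.clip(rng.normal(44.0, config.age_sd), 27.0, 58.0))
        sex = "F" if rng.random() < 7 / 11 else "M"
        amplitude = float(max(rng.normal(config.amplitude_mean, config.amplitude_sd), 1.0))
        geom = _draw_geometry(config, rng, with_lesions=False)
        masks = _make_masks(config, geom, lesion_load_pct=None, affine=affine)
        labels = _region_labels(masks)
        baseline = _draw_baseline(config, "wm", rng)
        scans, meta, truth = {}, {}, {}
        for tp, time in (("test", 0.0), ("retest", 0.0)):
            eps = _acquisition_noise(config, rng)
            values = {m: baseline[m] + eps[m] for m in METRICS}
            for m in ("icvf", "isovf"):
                values[m] = float(np.clip(values[m], 0.0, 1.0))
            for m in METRICS:
                truth[(tp, "wm", m)] = values[m]
            region_metrics = {_LABELS["gm"]: dict(GM_PARAMS), _LABELS["wm"]: values}
            scans[tp] = _simulate_scan(config, amplitude, region_metrics, labels, affine, rng)
            meta[tp] = {
                "time": time,
                "age": age,
                "sex": sex,
                "dmt": False,
                "lesion_load": 0.0,
                "new_lesions": False,
            }
        subjects.append(
            Subject(
                subject_id=sid,
                arm="control",
                masks={tp: masks for tp in scans},
                scans=scans,
                meta=meta,
                truth=truth,
            )
        )

    return SyntheticCohort(config=config, subjects=subjects, affine=affine)
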