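"""End-to-end orchestration: simulate -> fit maps -> ROI table -> statistics.

The in-memory entry points (``fit_scan_maps``, ``calibrate_cohort``,
``build_cohort_table``, ``analyze_cohort``) run the whole analysis on a
:class:`~gratiokit.synthetic.SyntheticCohort` without touching disk; the
file-based :func:`run_pipeline` wraps them with a YAML-configurable run
directory, CSV/JSON outputs and a provenance manifest.
"""

from __future__ import annotations

import json
import platform
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acquisition import AcquisitionParams
from .agreement import bland_altman
from .gratio import DEFAULT_G_TARGET, calibrate_k, fit_gratio_maps
from .longitudinal import (
    DEFAULT_COVARIATES,
    longitudinal_analysis,
    significance_pattern,
)
from .mt_mapping import MtMaps, fit_mt_maps, sum_echoes
from .roi import compute_bpf, nawm_mask, summarise_region
from .sensitivity import DEFAULT_FIXED, DEFAULT_RANGES, sweep_g
from .synthetic import CohortConfig, Subject, SubjectScan, SyntheticCohort, generate_cohort
from .volume import MaskSet

__all__ = [
    "fit_scan_maps",
    "calibrate_cohort",
    "build_cohort_table",
    "analyze_cohort",
    "RunConfig",
    "run_pipeline",
]

#: metrics summarised per region; g-ratio and NODDI metrics additionally
#: apply the cerebellum-exclusion mask
METRICS = ("mtsat", "mtr", "gratio", "icvf", "isovf")
EXCLUDE_CEREBELLUM = {"gratio", "icvf", "isovf"}


def fit_scan_maps(scan: SubjectScan, acq: AcquisitionParams) -> MtMaps:
    """Echo summation followed by the MTR/MTsat fitting chain."""
    s_on = sum_echoes(scan.mt_on_echoes)
    s_off = sum_echoes(scan.mt_off_echoes)
    s_t1w = sum_echoes(scan.mt_t1w_echoes)
    return fit_mt_maps(s_on, s_off, s_t1w, acq)


def _control_wm_mask(subject: Subject, tp: str) -> np.ndarray:
    masks = subject.masks[tp]
    wm = masks.wm.copy()
    if masks.exclude is not None:
        wm &= ~masks.exclude
    return wm


def calibrate_cohort(
    cohort: SyntheticCohort, g_target: float = DEFAULT_G_TARGET, timepoint: str = "test"
) -> float:
    """Calibrate the MVF scaling constant k on the control arm's WM."""
    mtsat_maps, icvf_maps, isovf_maps, wm_masks = [], [], [], []
    for s in cohort.controls:
        scan = s.scans[timepoint]
        mtsat_maps.append(fit_scan_maps(scan, cohort.config.acq).mtsat)
        icvf_maps.append(scan.icvf)
        isovf_maps.append(scan.isovf)
        wm_masks.append(_control_wm_mask(s, timepoint))
    return calibrate_k(mtsat_maps, icvf_maps, isovf_maps, wm_masks, g_target=g_target)


def _subject_regions(subject: Subject, masks: MaskSet) -> dict[str, np.ndarray]:
    if subject.arm == "control":
        return {"wm": masks.wm}
    return {
        "nawm": nawm_mask(masks.wm, masks.wml),
        "wml": masks.wml,
    }


def build_cohort_table(cohort: SyntheticCohort, k: float) -> pd.DataFrame:
    """Tidy per subject x timepoint x region x metric summary table.

    Columns: subject, arm, timepoint, time, region, metric, mean, median,
    sd, n_voxels, bpf plus the covariates carried in the metadata.
    """
    rows = []
    for s in cohort.subjects:
        for tp, scan in s.scans.items():
            masks = s.masks[tp]
            mt = fit_scan_maps(scan, cohort.config.acq)
            gr = fit_gratio_maps(mt.mtsat, scan.icvf, scan.isovf, k)
            maps = {
                "mtsat": mt.mtsat,
                "mtr": mt.mtr,
                "gratio": gr.g,
                "icvf": scan.icvf,
                "isovf": scan.isovf,
            }
            bpf = compute_bpf(masks.brain, masks.icv, masks.affine[0, 0] ** 3)
            regions = _subject_regions(s, masks)
            for region, mask in regions.items():
                for metric, vol in maps.items():
                    exclusion = masks.exclude if metric in EXCLUDE_CEREBELLUM else None
                    summ = summarise_region(vol, mask, exclusion)
                    rows.append(
                        {
                            "subject": s.subject_id,
                            "arm": s.arm,
                            "timepoint": tp,
                            "region": region,
                            "metric": metric,
                            "mean": summ.mean,
                            "median": summ.median,
                            "sd": summ.sd,
                            "n_voxels": summ.n_voxels,
                            "bpf": bpf,
                            **s.meta[tp],
                        }
                    )
    return pd.DataFrame(rows)


def agreement_analysis(table: pd.DataFrame) -> pd.DataFrame:
    """Bland-Altman + sign-test agreement per metric on the control arm."""
    ctrl = table[table["arm"] == "control"]
    if ctrl.empty:
        raise ValueError("no control-arm rows in the table")
    rows = []
    for metric in sorted(ctrl["metric"].unique()):
        sub = ctrl[ctrl["metric"] == metric]
        wide = sub.pivot_table(index="subject", columns="timepoint", values="mean")
        wide = wide.dropna()
        res = bland_altman(wide["test"], wide["retest"])
        rows.append(
            {
                "metric": metric,
                "region": "wm",
                "n": res.n,
                "mean_t1": float(wide["test"].mean()),
                "mean_t2": float(wide["retest"].mean()),
                "mean_diff": res.mean_diff,
                "sd_diff": res.sd_diff,
                "loa_half_width": res.loa_half_width,
                "loa_low": res.loa_low,
                "loa_high": res.loa_high,
                "sign_test_p": res.sign_test_p,
            }
        )
    return pd.DataFrame(rows)


def analyze_cohort(
    cohort: SyntheticCohort,
    g_target: float = DEFAULT_G_TARGET,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    extra_terms: tuple[str, ...] = (),
) -> dict:
    """Full statistical analysis of a simulated cohort.

    Returns a dict with the calibration constant ``k``, the tidy cohort
    ``table``, control-arm ``agreement``, patient ``paired`` and ``lmm``
    tables, and the FDR-corrected ``pattern`` of significant changes.
    """
    k = calibrate_cohort(cohort, g_target=g_target)
    table = build_cohort_table(cohort, k)
    agreement = agreement_analysis(table)
    patients = table[table["arm"] == "patient"]
    paired, lmm = longitudinal_analysis(
        patients,
        metrics=METRICS,
        regions=("nawm", "wml"),
        covariates=covariates,
        extra_terms=extra_terms,
    )
    return {
        "k": k,
        "table": table,
        "agreement": agreement,
        "paired": paired,
        "lmm": lmm,
        "pattern": significance_pattern(paired, lmm),
    }


# ---------------------------------------------------------------------------
# file-based run
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a pipeline run (YAML-serialisable)."""

    outdir: str | Path = "gratiokit_run"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    g_target: float = DEFAULT_G_TARGET
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    extra_terms: tuple[str, ...] = ()
    write_volumes: bool = False
    run_sensitivity: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_kwargs = raw.pop("cohort", {})
        seed = raw.pop("seed", 0)
        cohort = CohortConfig(seed=seed, **cohort_kwargs)
        return cls(seed=seed, cohort=cohort, **raw)


def run_pipeline(config: RunConfig) -> Path:
    """Run simulate -> fit -> summarise -> statistics, writing outputs.

    Deterministic given the seed; writes a manifest recording inputs,
    package version, parameters and per-stage status.  Any stage failure
    aborts with a stage-tagged error and no partial tables are kept.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "gratiokit",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "g_target": config.g_target,
        "cohort": {
            "n_patients": config.cohort.n_patients,
            "n_controls": config.cohort.n_controls,
            "grid_shape": list(config.cohort.grid_shape),
            "signal_model": config.cohort.signal_model,
            "seed": config.cohort.seed,
        },
        "stages": {},
        "outputs": [],
    }
    staged: dict[str, Path] = {}

    def stage(name, fn):
        t0 = _time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
            for path in staged.values():
                path.unlink(missing_ok=True)
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        manifest["stages"][name] = {"status": "ok", "seconds": round(_time.perf_counter() - t0, 3)}
        return result

    cohort_cfg = config.cohort
    if cohort_cfg.seed != config.seed:
        from dataclasses import replace as _replace

        cohort_cfg = _replace(cohort_cfg, seed=config.seed)
    cohort = stage("simulate", lambda: generate_cohort(cohort_cfg))
    if config.write_volumes:
        stage("write_volumes", lambda: cohort.write(outdir / "volumes"))

    results = stage(
        "analyze",
        lambda: analyze_cohort(
            cohort,
            g_target=config.g_target,
            covariates=config.covariates,
            extra_terms=config.extra_terms,
        ),
    )

    def _write_tables():
        for name in ("table", "agreement", "paired", "lmm"):
            path = outdir / f"{name if name != 'table' else 'cohort_table'}.csv"
            results[name].to_csv(path, index=False)
            staged[name] = path
        calib = outdir / "calibration.json"
        calib.write_text(
            json.dumps({"k": results["k"], "g_target": config.g_target}, indent=2)
        )
        staged["calibration"] = calib

    stage("write_tables", _write_tables)

    if config.run_sensitivity:
        def _sensitivity():
            frames = []
            for axis, rng_ in DEFAULT_RANGES.items():
                grid = sweep_g(axis, rng_, DEFAULT_FIXED, k=results["k"])
                frames.append(
                    pd.DataFrame(
                        {"axis": axis, "value": grid.values, "g": grid.g}
                    )
                )
            path = outdir / "sensitivity.csv"
            pd.concat(frames).to_csv(path, index=False)
            staged["sensitivity"] = path

        stage("sensitivity", _sensitivity)

    manifest["outputs"] = sorted(str(p.relative_to(outdir)) for p in staged.values())
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
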