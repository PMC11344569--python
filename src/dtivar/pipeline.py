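"""End-to-end orchestration: phantom → scalar maps → per-ROI σ → models.

Also houses the scan-vs-rescan motion comparison (mean shift Δμ, relative
shift Δμ/μ, and the R² of regressing rescan motion on first-scan motion).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dti_core import LabelMap, ScalarMap, fit_tensor, compute_scalars
from .lmm import RegionwiseConfig, run_region_wise, standardize_response
from .noise_est import estimate_roi, region_report
from .synthdata import (CohortSpec, PhantomSpec, default_gradient_table,
                        generate_cohort, generate_dwi, two_roi_phantom)

logger = logging.getLogger("dtivar")

COVARIATE_CSV_COLUMNS = [
    # artifact-native covariate schema, one row per (subject, session, scan)
    "subject", "session", "scan", "scanner", "age_baseline_years",
    "interval_years", "motion_mm", "sex", "rescan",
]


@dataclass
class MotionComparison:
    """Scan-vs-rescan head-motion summary over complete session pairs."""

    n_pairs: int
    delta_mu: float            # mean(rescan) − mean(scan), mm per volume
    rel_delta_mu: float | None  # Δμ / mean(scan); None when mean(scan) <= 0
    r_squared: float           # R² of rescan-on-scan simple regression
    n_dropped: int = 0


def compare_scan_rescan_motion(pairs: np.ndarray | pd.DataFrame
                               ) -> MotionComparison:
    """Δμ, Δμ/μ and R² for per-session (scan, rescan) motion pairs in mm.

    Incomplete pairs (any NaN) are dropped and counted.  R² comes from the
    ordinary least-squares regression of rescan motion on scan motion.
    """
    if isinstance(pairs, pd.DataFrame):
        arr = pairs[["motion_scan", "motion_rescan"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
    complete = np.all(np.isfinite(arr), axis=1)
    dropped = int((~complete).sum())
    arr = arr[complete]
    if len(arr) < 2:
        raise ValueError("need at least 2 complete motion pairs")
    scan, rescan = arr[:, 0], arr[:, 1]
    delta = float(rescan.mean() - scan.mean())
    rel = float(delta / scan.mean()) if scan.mean() > 0 else None
    # simple-regression R² equals the squared Pearson correlation
    if scan.std() == 0 or rescan.std() == 0:
        r2 = 1.0 if np.allclose(rescan - rescan.mean(), 0) and np.allclose(
            scan - scan.mean(), 0) else 0.0
    else:
        r2 = float(np.corrcoef(scan, rescan)[0, 1] ** 2)
    return MotionComparison(n_pairs=len(arr), delta_mu=delta,
                            rel_delta_mu=rel, r_squared=r2,
                            n_dropped=dropped)


def extract_sigma_table(scalar_maps: dict[tuple, dict[str, ScalarMap]],
                        labels: LabelMap,
                        covariates: pd.DataFrame,
                        min_voxels: int = 5,
                        zero_tol: float = 1e-12) -> tuple[pd.DataFrame, list[dict]]:
    """Build the long-format cohort table from per-scan scalar maps.

    ``scalar_maps`` maps (subject, session, scan) to {scalar name: map}.
    Each ROI contributes one row per scalar with σ from the ROI-based
    estimator; covariates are joined by (subject, session, scan) and ages
    converted from years to decades here (and only here).  ROIs below
    ``min_voxels`` or with zero variance are excluded with a flag record.
    """
    cov = covariates.set_index(["subject", "session", "scan"])
    rows: list[dict] = []
    flagged: list[dict] = []
    for key, maps in scalar_maps.items():
        if key not in cov.index:
            raise ValueError(f"missing covariate row for scan {key}")
        c = cov.loc[key]
        for scalar_name, smap in maps.items():
            for lab in labels.present_labels():
                mask = labels.labels == lab
                if int(mask.sum()) < min_voxels:
                    flagged.append({"scan": key, "roi": lab,
                                    "scalar": scalar_name,
                                    "reason": "below_min_voxels"})
                    continue
                try:
                    est = estimate_roi(smap, mask, roi_label=lab)
                except ValueError:
                    flagged.append({"scan": key, "roi": lab,
                                    "scalar": scalar_name,
                                    "reason": "unusable_voxels"})
                    continue
                if est.sigma <= zero_tol:   # constant up to round-off
                    flagged.append({"scan": key, "roi": lab,
                                    "scalar": scalar_name,
                                    "reason": "zero_variance"})
                    continue
                rows.append({
                    "subject": key[0], "session": key[1], "scan": key[2],
                    "scanner": c["scanner"],
                    "age_baseline_dec": c["age_baseline_years"] / 10.0,
                    "interval_dec": c["interval_years"] / 10.0,
                    "motion_mm": c["motion_mm"],
                    "sex": int(c["sex"]), "rescan": int(c["rescan"]),
                    "roi": labels.names.get(lab, str(lab)),
                    "scalar": scalar_name,
                    "sigma": est.sigma,
                })
    for f in flagged:
        logger.info("extract_sigma_table: excluded %s", f)
    return pd.DataFrame(rows), flagged


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full synthetic end-to-end run."""

    out_dir: str = "dtivar_run"
    seed: int = 0
    n_subjects: int = 4
    sessions_per_subject: int = 2
    scans_per_session: int = 2
    n_scanners: int = 2
    grid_shape: tuple[int, int, int] = (10, 10, 6)
    noise_sigma: float = 0.02
    scalars: tuple[str, ...] = ("FA", "MD")
    covariates: tuple[str, ...] = ("baseline", "interval", "motion",
                                   "sex", "rescan")
    alpha_random: float = 0.1
    alpha_fixed: float = 0.05
    fdr_q: float = 0.05
    fdr_pooling: str = "per_term"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        for key in ("grid_shape", "scalars", "covariates"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(config: RunConfig) -> Path:
    """Simulate, fit, extract, model and report; returns the output dir.

    Stages: (1) simulate a small phantom cohort where the per-scan image
    noise grows with motion and interval so the region models have signal;
    (2) tensor-fit each scan and compute scalar maps; (3) extract per-ROI σ
    into the cohort table; (4) region-wise mixed models with selection and
    FDR; (5) scan-vs-rescan motion comparison and ROI SNR report.  All
    outputs land under ``config.out_dir`` with a manifest recording seed,
    version and config hash; a rerun of the same manifest reproduces them.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    logger.info("run_all: stage=simulate")

    cohort_spec = CohortSpec(
        n_subjects=config.n_subjects,
        sessions_per_subject=config.sessions_per_subject,
        scans_per_session=config.scans_per_session,
        n_scanners=config.n_scanners,
        seed=int(rng.integers(2**31)),
    )
    base, _ = generate_cohort(cohort_spec)
    scans = base[["subject", "session", "scan", "scanner", "age_baseline_dec",
                  "interval_dec", "motion_mm", "sex", "rescan"]].drop_duplicates(
        ["subject", "session", "scan"]).reset_index(drop=True)

    gradients = default_gradient_table()
    scalar_maps: dict[tuple, dict[str, ScalarMap]] = {}
    labels = None
    for _, row in scans.iterrows():
        key = (int(row["subject"]), int(row["session"]), int(row["scan"]))
        # image noise responsive to covariates: more motion / longer interval
        # -> noisier acquisition
        sigma = config.noise_sigma * (1.0 + 1.0 * row["motion_mm"]
                                      + 0.5 * row["interval_dec"])
        phantom = two_roi_phantom(grid=config.grid_shape,
                                  noise_model="gaussian", sigma=float(sigma),
                                  seed=int(rng.integers(2**31)))
        dwi, labels, _ = generate_dwi(phantom, gradients)
        fit = fit_tensor(dwi, labels)
        maps = compute_scalars(fit)
        scalar_maps[key] = {s: maps[s] for s in config.scalars}

    logger.info("run_all: stage=extract")
    covariates = scans.rename(columns={
        "age_baseline_dec": "age_baseline_years",
        "interval_dec": "interval_years"})
    covariates["age_baseline_years"] *= 10.0
    covariates["interval_years"] *= 10.0
    table, flagged = extract_sigma_table(scalar_maps, labels, covariates)
    table.to_csv(out / "cohort.csv", index=False)

    logger.info("run_all: stage=model")
    rw_cfg = RegionwiseConfig(covariates=config.covariates,
                              alpha_random=config.alpha_random,
                              alpha_fixed=config.alpha_fixed,
                              fdr_q=config.fdr_q,
                              fdr_pooling=config.fdr_pooling)
    result = run_region_wise(table, rw_cfg)
    result.table.to_csv(out / "region_results.csv", index=False)
    with open(out / "selection_traces.jsonl", "w") as fh:
        for (roi, scalar), steps in result.traces.items():
            fh.write(json.dumps({"roi": roi, "scalar": scalar,
                                 "steps": [asdict(s) for s in steps]}) + "\n")

    logger.info("run_all: stage=report")
    if config.scans_per_session == 2:
        wide = scans.pivot_table(index=["subject", "session"], columns="scan",
                                 values="motion_mm")
        pairs = wide.rename(columns={0: "motion_scan", 1: "motion_rescan"})
        motion = compare_scan_rescan_motion(pairs)
        (out / "motion_comparison.json").write_text(json.dumps(asdict(motion)))

    first_key = min(scalar_maps)
    snr_rows = []
    for s in config.scalars:
        for rs in region_report(scalar_maps[first_key][s], labels):
            snr_rows.append({"scalar": s, "roi": rs.name, "mean": rs.mean,
                             "sd": rs.sd, "n_voxels": rs.n_voxels,
                             "snr": rs.snr,
                             "snr_definition": "roi_mean_over_roi_sample_sd"})
    pd.DataFrame(snr_rows).to_csv(out / "snr_report.csv", index=False)

    manifest = {
        "seed": config.seed,
        "dtivar_version": __version__,
        "config_hash": _config_hash(config),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_flagged_rows": len(flagged),
        "n_model_failures": len(result.failures),
        "outputs": ["cohort.csv", "region_results.csv",
                    "selection_traces.jsonl", "snr_report.csv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
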