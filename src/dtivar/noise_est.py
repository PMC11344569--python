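"""Variance / noise estimation for DTI scalar maps.

Implements the four estimator families that differ in what data they need
and what they assume:

* ``multi_acquisition`` — many aligned repeats; per-voxel sample SD, or
  bootstrap / jackknife resampling of a per-ROI statistic.  No assumption
  on the noise field.
* ``scan_rescan`` — two repeats; SD of the difference image over a region,
  divided by √2.  Assumes spatially constant noise over the region.
* ``roi_based`` — a single acquisition; sample SD within a homogeneous
  ROI.  Assumes both signal and noise constant across the ROI.  This is
  the σ fed to the region-wise mixed models.
* ``wild_bootstrap`` — a single acquisition; tensor-model residuals flipped
  by Rademacher signs and refit.  Assumes the tensor model captures the
  signal.

Plus :func:`region_report`, the per-ROI mean/SD/SNR summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dti_core import (DWIVolume, LabelMap, ScalarMap, fit_tensor,
                       scalars_from_eigenvalues, tensors_from_coeffs)

METHODS = ("multi_acquisition", "scan_rescan", "roi_based", "wild_bootstrap")


@dataclass
class NoiseEstimate:
    """One variance estimate: which method, the σ, and an optional CI.

    ``ci`` brackets σ itself; ``statistic_ci`` (bootstrap methods) is the
    percentile interval of the resampled statistic, a different quantity.
    """

    method: str
    sigma: float
    ci: tuple[float, float] | None = None
    ci_level: float | None = None
    n_samples: int = 0
    roi_label: int | None = None
    statistic_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.ci is not None and not (self.ci[0] <= self.sigma <= self.ci[1]):
            raise ValueError("CI must contain the point estimate")


@dataclass
class RegionStats:
    """Per-ROI first moments of a scalar map; SNR = mean/SD (sample SD,
    denominator n−1).  ``snr`` is None when the region is constant."""

    label: int
    name: str
    mean: float
    sd: float
    n_voxels: int
    snr: float | None


def _as_mask(mask: np.ndarray | LabelMap) -> np.ndarray:
    if isinstance(mask, LabelMap):
        return mask.mask()
    return np.asarray(mask, dtype=bool)


def _masked_values(smap: ScalarMap | np.ndarray, mask: np.ndarray) -> np.ndarray:
    arr = smap.values if isinstance(smap, ScalarMap) else np.asarray(smap, float)
    if arr.shape != mask.shape:
        raise ValueError("scalar grid does not match mask grid")
    vals = arr[mask]
    return vals[np.isfinite(vals)]    # voxels excluded by the fit are skipped


def estimate_multi_acquisition(scalar_stack: list[ScalarMap | np.ndarray],
                               mask: np.ndarray | LabelMap,
                               method: str = "sd",
                               n_boot: int = 1000,
                               seed: int | None = None,
                               roi_label: int | None = None) -> NoiseEstimate:
    """Variance from repeated aligned acquisitions.

    ``method="sd"``: per-voxel sample SD across repeats, averaged over the
    mask (for a single-voxel mask this is simply that voxel's SD).
    ``method="bootstrap"`` / ``"jackknife"``: resample the repeats and track
    the ROI mean; σ is the SD of the resampled statistic, with a percentile
    CI for the bootstrap.
    """
    if len(scalar_stack) < 2:
        raise ValueError("need at least 2 repeats")
    mask = _as_mask(mask)
    arrs = []
    for s in scalar_stack:
        a = s.values if isinstance(s, ScalarMap) else np.asarray(s, float)
        if a.shape != mask.shape:
            raise ValueError("misaligned grids in scalar stack")
        arrs.append(a[mask])
    stack = np.vstack(arrs)                      # (n_rep, n_vox)
    n_rep = stack.shape[0]

    if method == "sd":
        per_voxel_sd = stack.std(axis=0, ddof=1)
        return NoiseEstimate(method="multi_acquisition",
                             sigma=float(per_voxel_sd.mean()),
                             n_samples=n_rep, roi_label=roi_label)

    roi_means = stack.mean(axis=1)               # statistic per repeat
    if method == "jackknife":
        loo = (roi_means.sum() - roi_means) / (n_rep - 1)
        se = np.sqrt((n_rep - 1) / n_rep * ((loo - loo.mean()) ** 2).sum())
        return NoiseEstimate(method="multi_acquisition", sigma=float(se),
                             n_samples=n_rep, roi_label=roi_label)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n_rep, size=(n_boot, n_rep))
        boots = roi_means[idx].mean(axis=1)
        sigma = float(boots.std(ddof=1))
        lo, hi = np.percentile(boots, [2.5, 97.5])
        return NoiseEstimate(method="multi_acquisition", sigma=sigma,
                             statistic_ci=(float(lo), float(hi)),
                             ci_level=0.95, n_samples=n_rep,
                             roi_label=roi_label)
    raise ValueError("method must be 'sd', 'bootstrap' or 'jackknife'")


def estimate_scan_rescan(scan: ScalarMap | np.ndarray,
                         rescan: ScalarMap | np.ndarray,
                         mask: np.ndarray | LabelMap,
                         roi_label: int | None = None) -> NoiseEstimate:
    """σ = SD(scan − rescan) / √2 over the mask.

    The difference of two acquisitions carries the noise of both, hence the
    √2; symmetric in its two arguments.
    """
    mask = _as_mask(mask)
    a = _masked_values(scan, mask)
    b = _masked_values(rescan, mask)
    if len(a) != len(b):
        raise ValueError("scan and rescan expose different masked voxels")
    if len(a) < 2:
        raise ValueError("mask must contain at least 2 usable voxels")
    sigma = float(np.std(a - b, ddof=1) / np.sqrt(2.0))
    return NoiseEstimate(method="scan_rescan", sigma=sigma,
                         n_samples=len(a), roi_label=roi_label)


def estimate_roi(scalar: ScalarMap | np.ndarray,
                 mask: np.ndarray | LabelMap,
                 roi_label: int | None = None) -> NoiseEstimate:
    """σ = sample SD of the scalar within the ROI (single acquisition)."""
    mask = _as_mask(mask)
    vals = _masked_values(scalar, mask)
    if len(vals) < 2:
        raise ValueError("mask must contain at least 2 usable voxels")
    return NoiseEstimate(method="roi_based", sigma=float(np.std(vals, ddof=1)),
                         n_samples=len(vals), roi_label=roi_label)


@dataclass
class WildBootstrapEstimate:
    """Voxel-wise wild-bootstrap σ of one scalar with percentile CIs.

    Arrays live on the input grid; NaN marks voxels outside the fitted mask.
    """

    scalar: str
    sigma: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    ci_level: float
    n_boot: int


def estimate_wild_bootstrap(dwi: DWIVolume,
                            mask: np.ndarray | LabelMap,
                            target_scalar: str = "FA",
                            n_boot: int = 500,
                            seed: int | None = None,
                            ci_level: float = 0.95,
                            flavor: str = "hc0") -> WildBootstrapEstimate:
    """Model-based resampling of the tensor fit.

    Per voxel: fit the tensor, flip each log-space residual (every design
    row, b0 included) by an independent Rademacher sign (±1 with
    probability ½), add back to the fitted log-signals, refit, and
    recompute the target scalar.  σ is the SD of the replicate distribution
    and the CI its percentiles.  ``flavor="hc0"`` uses raw residuals;
    ``"hc2"`` rescales each by 1/√(1−h) to undo the hat-matrix deflation
    (rows with leverage ≈ 1, e.g. a lone b0 on a single shell, contribute
    nothing under either flavor — see :class:`~dtivar.dti_core.TensorFit`).
    Fully vectorized across voxels and replicates; seeded.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if flavor not in ("hc0", "hc2"):
        raise ValueError("flavor must be 'hc0' or 'hc2'")
    fit = fit_tensor(dwi, mask)
    rng = np.random.default_rng(seed)
    X = fit.design
    pinv = np.linalg.pinv(X)
    fitted = fit.coeffs @ X.T                     # (n_vox, n_rows)
    n_vox, n_rows = fit.residuals.shape

    resid = fit.residuals
    if flavor == "hc2":
        scale = 1.0 / np.sqrt(np.clip(1.0 - fit.leverages, 1e-12, None))
        scale = np.where(fit.leverages > 1.0 - 1e-8, 0.0, scale)
        resid = resid * scale[None, :]
    signs = rng.choice([-1.0, 1.0], size=(n_vox, n_boot, n_rows))
    y_boot = fitted[:, None, :] + signs * resid[:, None, :]
    coeffs = y_boot @ pinv.T                      # (n_vox, n_boot, 7)
    D = tensors_from_coeffs(coeffs.reshape(-1, 7))
    evals = np.linalg.eigvalsh(D)[:, ::-1]
    vals = scalars_from_eigenvalues(evals)[target_scalar]
    vals = vals.reshape(n_vox, n_boot)

    sig = np.full(fit.mask.shape, np.nan)
    lo = np.full(fit.mask.shape, np.nan)
    hi = np.full(fit.mask.shape, np.nan)
    alpha = 100.0 * (1.0 - ci_level) / 2.0
    sig[fit.mask] = vals.std(axis=1, ddof=1)
    lo[fit.mask] = np.percentile(vals, alpha, axis=1)
    hi[fit.mask] = np.percentile(vals, 100.0 - alpha, axis=1)
    return WildBootstrapEstimate(scalar=target_scalar, sigma=sig,
                                 ci_lower=lo, ci_upper=hi,
                                 ci_level=ci_level, n_boot=n_boot)


def region_report(scalar: ScalarMap | np.ndarray,
                  labels: LabelMap) -> list[RegionStats]:
    """Per-ROI mean, sample SD, voxel count and SNR = mean/SD.

    A constant region gets ``snr=None`` (undefined) rather than infinity.
    The mean/SD definition of SNR is a package convention and is recorded in
    CSV exports of these stats.
    """
    arr = scalar.values if isinstance(scalar, ScalarMap) else np.asarray(scalar, float)
    if arr.shape != labels.labels.shape:
        raise ValueError("scalar grid does not match label grid")
    out = []
    for lab in labels.present_labels():
        vals = _masked_values(arr, labels.labels == lab)
        if len(vals) < 2:
            continue
        mean = float(vals.mean())
        sd = float(np.std(vals, ddof=1))
        snr = mean / sd if sd > 0 else None
        out.append(RegionStats(label=lab,
                               name=labels.names.get(lab, str(lab)),
                               mean=mean, sd=sd, n_voxels=len(vals), snr=snr))
    return out
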