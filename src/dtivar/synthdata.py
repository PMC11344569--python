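"""Synthetic data generation: DWI phantoms and longitudinal cohort tables.

Two generators drive every downstream module without any external data:

* :func:`generate_dwi` renders Stejskal–Tanner signals from a ground-truth
  tensor field (S = S0·exp(−b gᵀDg)) with Gaussian or Rician noise, at the
  scale of a 32-direction, b = 700 s/mm² clinical protocol.
* :func:`generate_cohort` draws long-format per-(subject, session, scan,
  ROI, scalar) variance records from a linear mixed model with known fixed
  effects, crossed subject and scanner random intercepts, and i.i.d.
  residual noise, returning the table together with a hidden-truth sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dti_core import DWIVolume, LabelMap

DEFAULT_B_VALUE = 700.0          # s/mm², max b-factor of the emulated protocol
WM_EIGENVALUES = (1.7e-3, 0.3e-3, 0.3e-3)   # mm²/s, white-matter-like tensor
DEFAULT_RESCAN_MOTION_SHIFT = 0.045          # mm per volume, added on rescan
DEFAULT_MOTION_MEDIAN = 0.26                 # mm, lognormal median


# ---------------------------------------------------------------------------
# Gradient tables
# ---------------------------------------------------------------------------

@dataclass
class GradientTable:
    """Diffusion gradient directions paired with b-values.

    Directions are unit vectors for every b > 0 entry; at least one b = 0
    entry (the baseline S0 acquisition) is required.
    """

    directions: np.ndarray      # (N, 3)
    b_values: np.ndarray        # (N,), s/mm²

    def __post_init__(self) -> None:
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.b_values = np.asarray(self.b_values, dtype=float).ravel()
        if self.directions.shape[0] != self.b_values.shape[0]:
            raise ValueError("directions and b_values length mismatch")
        if self.directions.shape[1] != 3:
            raise ValueError("directions must be 3-vectors")
        if not np.any(self.b_values == 0):
            raise ValueError("gradient table needs at least one b=0 entry")
        norms = np.linalg.norm(self.directions[self.b_values > 0], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("b>0 directions must be unit-norm (±1e-6)")

    def __len__(self) -> int:
        return len(self.b_values)


def spread_directions(n: int, seed: int = 0, n_iter: int = 2000) -> np.ndarray:
    """n unit vectors spread by electrostatic repulsion of antipodal pairs.

    Starts from a Fibonacci-sphere layout and descends the Coulomb energy
    Σ 1/|vi−vj| + 1/|vi+vj|; deterministic for fixed (n, seed, n_iter).
    """
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (i + 0.5) * 2.0 / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    v = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    rng = np.random.default_rng(seed)
    v += 1e-3 * rng.standard_normal(v.shape)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    step = 0.01
    for _ in range(n_iter):
        diff = v[:, None, :] - v[None, :, :]
        anti = v[:, None, :] + v[None, :, :]
        d1 = np.linalg.norm(diff, axis=-1)
        d2 = np.linalg.norm(anti, axis=-1)
        np.fill_diagonal(d1, np.inf)
        np.fill_diagonal(d2, np.inf)
        force = (diff / d1[..., None] ** 3).sum(axis=1) + (anti / d2[..., None] ** 3).sum(axis=1)
        v = v + step * force
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def default_gradient_table(n_directions: int = 32,
                           b_value: float = DEFAULT_B_VALUE,
                           n_b0: int = 1) -> GradientTable:
    """Protocol-style table: n_b0 baseline volumes plus n electrostatically
    spread directions at one shell.

    The protocol default is a single b0; pass ``n_b0 >= 2`` for acquisitions
    meant for model-based (wild-bootstrap) uncertainty estimation, which
    needs resampleable residual support on the b0 rows.
    """
    dirs = np.vstack([np.zeros((n_b0, 3)), spread_directions(n_directions)])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, b_value)])
    return GradientTable(directions=dirs, b_values=bvals)


def minimal_gradient_table(b_value: float = DEFAULT_B_VALUE) -> GradientTable:
    """One b0 + the classic 6-direction dual-gradient scheme (for closed-form
    tests: the design is exactly determined up to OLS)."""
    s = 1.0 / np.sqrt(2.0)
    dirs = np.array([
        [0.0, 0.0, 0.0],
        [s, s, 0.0], [s, -s, 0.0],
        [s, 0.0, s], [s, 0.0, -s],
        [0.0, s, s], [0.0, s, -s],
    ])
    bvals = np.array([0.0] + [b_value] * 6)
    return GradientTable(directions=dirs, b_values=bvals)


# ---------------------------------------------------------------------------
# Tensor-field phantoms
# ---------------------------------------------------------------------------

@dataclass
class TensorField:
    """Ground-truth per-voxel diffusion tensors (mm²/s) and baseline S0."""

    D: np.ndarray      # (x, y, z, 3, 3), symmetric PSD
    S0: np.ndarray     # (x, y, z), > 0 where tissue

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.S0.shape


def tensor_from_recipe(eigenvalues, principal_direction) -> np.ndarray:
    """Symmetric 3×3 tensor with given eigenvalues (sorted descending) whose
    leading eigenvector is the given direction."""
    lam = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    if np.any(lam < 0):
        raise ValueError("tensor recipe must be positive semidefinite "
                         f"(eigenvalues {lam})")
    e1 = np.asarray(principal_direction, dtype=float)
    nrm = np.linalg.norm(e1)
    if nrm == 0:
        raise ValueError("principal direction must be nonzero")
    e1 = e1 / nrm
    # complete an orthonormal frame
    helper = np.array([1.0, 0.0, 0.0])
    if abs(e1 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    R = np.column_stack([e1, e2, e3])
    return R @ np.diag(lam) @ R.T


@dataclass
class ROIRecipe:
    """A labeled box in the phantom grid with a homogeneous tensor recipe."""

    label: int
    name: str
    origin: tuple[int, int, int]
    size: tuple[int, int, int]
    eigenvalues: tuple[float, float, float] = WM_EIGENVALUES
    principal_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    s0: float = 1.0

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + s) for o, s in zip(self.origin, self.size))


@dataclass
class PhantomSpec:
    """Layout and noise model of a synthetic DWI phantom."""

    grid_shape: tuple[int, int, int]
    rois: list[ROIRecipe]
    noise_model: str = "gaussian"     # "gaussian" | "rician" | "none"
    sigma: float = 0.0                # signal units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        labels = [r.label for r in self.rois]
        if any(l <= 0 for l in labels):
            raise ValueError("ROI labels must be positive")
        if len(set(labels)) != len(labels):
            raise ValueError("ROI labels must be unique")
        occupied = np.zeros(self.grid_shape, dtype=int)
        for r in self.rois:
            sl = r.slices()
            if occupied[sl].any():
                raise ValueError(f"ROI {r.label} overlaps another ROI")
            occupied[sl] = 1


def two_roi_phantom(grid: tuple[int, int, int] = (12, 12, 6),
                    noise_model: str = "gaussian",
                    sigma: float = 0.0, seed: int = 0) -> PhantomSpec:
    """Convenience phantom: one anisotropic and one isotropic box ROI."""
    nx, ny, nz = grid
    half = nx // 2
    return PhantomSpec(
        grid_shape=grid,
        rois=[
            ROIRecipe(label=1, name="wm_box", origin=(1, 1, 1),
                      size=(half - 2, ny - 2, nz - 2),
                      eigenvalues=WM_EIGENVALUES,
                      principal_direction=(1.0, 0.0, 0.0)),
            ROIRecipe(label=2, name="gm_box", origin=(half + 1, 1, 1),
                      size=(nx - half - 2, ny - 2, nz - 2),
                      eigenvalues=(0.8e-3, 0.7e-3, 0.7e-3),
                      principal_direction=(0.0, 0.0, 1.0)),
        ],
        noise_model=noise_model, sigma=sigma, seed=seed,
    )


def add_noise(signal: np.ndarray, model: str, sigma: float,
              rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian or magnitude Rician noise on noiseless signals."""
    if sigma == 0 or model == "none":
        return signal.copy()
    if model == "gaussian":
        return signal + rng.normal(0.0, sigma, size=signal.shape)
    if model == "rician":
        n1 = rng.normal(0.0, sigma, size=signal.shape)
        n2 = rng.normal(0.0, sigma, size=signal.shape)
        return np.sqrt((signal + n1) ** 2 + n2 ** 2)
    raise ValueError(f"unknown noise model {model!r}")


def generate_dwi(spec: PhantomSpec, gradients: GradientTable
                 ) -> tuple[DWIVolume, LabelMap, TensorField]:
    """Render a DWI phantom: Stejskal–Tanner signals plus noise.

    Per voxel v and gradient q the noiseless signal is
    S = S0(v) · exp(−b_q · g_qᵀ D(v) g_q); noise is then applied per the
    spec's model.  Voxels outside every ROI have S0 = 0 (air).

    Returns the noisy DWI volume, the ROI label map and the ground-truth
    tensor field.  Reproducible for a fixed spec seed.
    """
    shape = spec.grid_shape
    D = np.zeros(shape + (3, 3))
    S0 = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int16)
    names: dict[int, str] = {}
    for roi in spec.rois:
        sl = roi.slices()
        D[sl] = tensor_from_recipe(roi.eigenvalues, roi.principal_direction)
        S0[sl] = roi.s0
        labels[sl] = roi.label
        names[roi.label] = roi.name

    b = np.asarray(gradients.b_values)
    g = np.asarray(gradients.directions)
    # quadratic form b_q · g_qᵀ D g_q for all voxels and gradients at once
    bgg = b[:, None, None] * (g[:, :, None] * g[:, None, :])   # (Q, 3, 3)
    atten = np.exp(-np.tensordot(D, bgg, axes=([3, 4], [1, 2])))
    signal = S0[..., None] * atten
    rng = np.random.default_rng(spec.seed)
    noisy = add_noise(signal, spec.noise_model, spec.sigma, rng)
    dwi = DWIVolume(data=noisy, gradients=gradients)
    return dwi, LabelMap(labels=labels, names=names), TensorField(D=D, S0=S0)


# ---------------------------------------------------------------------------
# Longitudinal cohort tables
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Design of a synthetic longitudinal variance cohort.

    The response for row (subject i, session j, scanner k, scan l) is

        sigma = β0 + β_baseline·Age_baseline + β_interval·Interval
                + β_motion·Motion + β_sex·Sex + β_rescan·Rescan
                + r1_i + r2_k + ε,

    with ages in decades, motion in mm, r1 ~ N(0, sd_subject²) per subject,
    r2 ~ N(0, sd_scanner²) per scanner and ε i.i.d. N(0, sd_resid²).
    Responses are generated directly on the standardized (z) scale;
    ``response_mode="positive"`` instead exponentiates a scaled response to
    produce strictly positive σ values for exercising the standardization
    step.
    """

    n_subjects: int = 50
    sessions_per_subject: int = 3          # max 12
    scans_per_session: int = 2             # 1 or 2
    n_scanners: int = 4
    beta: dict[str, float] = field(default_factory=lambda: {
        "intercept": 0.0, "baseline": 0.1, "interval": 0.5,
        "motion": 0.3, "sex": 0.2, "rescan": 0.1,
    })
    sd_subject: float = 0.5
    sd_scanner: float = 0.3
    sd_resid: float = 1.0
    baseline_age_range: tuple[float, float] = (22.4, 94.4)   # years
    session_gap_years: tuple[float, float] = (1.0, 3.0)      # uniform gap
    motion_median: float = DEFAULT_MOTION_MEDIAN             # mm, lognormal
    motion_log_sd: float = 0.5
    rescan_motion_shift: float = DEFAULT_RESCAN_MOTION_SHIFT  # mm, additive
    male_fraction: float = 0.473
    scanner_switch_prob: float = 0.06
    rois: tuple[str, ...] = ("roi_1",)
    scalars: tuple[str, ...] = ("FA",)
    response_mode: str = "z"               # "z" | "positive"
    positive_scale: float = 0.25
    positive_base: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.sessions_per_subject < 1:
            raise ValueError("need at least one subject and one session")
        if self.sessions_per_subject > 12:
            raise ValueError("at most 12 sessions per subject")
        if self.scans_per_session not in (1, 2):
            raise ValueError("scans per session must be 1 or 2")
        if min(self.sd_subject, self.sd_scanner, self.sd_resid) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.response_mode not in ("z", "positive"):
            raise ValueError("response_mode must be 'z' or 'positive'")


COHORT_COLUMNS = [
    "subject", "session", "scan", "scanner", "age_baseline_dec",
    "interval_dec", "motion_mm", "sex", "rescan", "roi", "scalar", "sigma",
]


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort table from the spec's mixed model.

    Returns ``(table, truth)`` where the table has the columns in
    :data:`COHORT_COLUMNS` (ages already in decades) and ``truth`` records
    the fixed effects, variance components and every per-subject/scanner
    random-intercept draw, per roi×scalar group.  Deterministic given the
    spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_sub, n_ses, n_scan = (spec.n_subjects, spec.sessions_per_subject,
                            spec.scans_per_session)

    lo, hi = spec.baseline_age_range
    age_baseline = rng.uniform(lo, hi, size=n_sub) / 10.0       # decades
    sex = (rng.uniform(size=n_sub) < spec.male_fraction).astype(int)
    gaps = rng.uniform(*spec.session_gap_years, size=(n_sub, n_ses))
    gaps[:, 0] = 0.0
    interval = np.cumsum(gaps, axis=1) / 10.0                   # decades

    home_scanner = rng.integers(0, spec.n_scanners, size=n_sub)
    scanner = np.empty((n_sub, n_ses), dtype=int)
    scanner[:, 0] = home_scanner
    for j in range(1, n_ses):
        switch = rng.uniform(size=n_sub) < spec.scanner_switch_prob
        scanner[:, j] = np.where(switch,
                                 rng.integers(0, spec.n_scanners, size=n_sub),
                                 scanner[:, j - 1])

    mu_log = np.log(spec.motion_median)
    motion = rng.lognormal(mu_log, spec.motion_log_sd,
                           size=(n_sub, n_ses, n_scan))
    if n_scan == 2:
        motion[:, :, 1] += spec.rescan_motion_shift

    subj_idx = np.repeat(np.arange(n_sub), n_ses * n_scan)
    ses_idx = np.tile(np.repeat(np.arange(n_ses), n_scan), n_sub)
    scan_idx = np.tile(np.arange(n_scan), n_sub * n_ses)
    rows = {
        "subject": subj_idx,
        "session": ses_idx,
        "scan": scan_idx,
        "scanner": scanner[subj_idx, ses_idx],
        "age_baseline_dec": age_baseline[subj_idx],
        "interval_dec": interval[subj_idx, ses_idx],
        "motion_mm": motion[subj_idx, ses_idx, scan_idx],
        "sex": sex[subj_idx],
        "rescan": scan_idx.astype(int),
    }
    base = pd.DataFrame(rows)

    b = spec.beta
    fixed = (b.get("intercept", 0.0)
             + b.get("baseline", 0.0) * base["age_baseline_dec"].to_numpy()
             + b.get("interval", 0.0) * base["interval_dec"].to_numpy()
             + b.get("motion", 0.0) * base["motion_mm"].to_numpy()
             + b.get("sex", 0.0) * base["sex"].to_numpy()
             + b.get("rescan", 0.0) * base["rescan"].to_numpy())

    tables = []
    truth: dict = {
        "beta": dict(b),
        "sd_subject": spec.sd_subject,
        "sd_scanner": spec.sd_scanner,
        "sd_resid": spec.sd_resid,
        "groups": {},
    }
    for roi in spec.rois:
        for scalar in spec.scalars:
            r1 = rng.normal(0.0, spec.sd_subject, size=n_sub)
            r2 = rng.normal(0.0, spec.sd_scanner, size=spec.n_scanners)
            eps = rng.normal(0.0, spec.sd_resid, size=len(base))
            z = (fixed + r1[base["subject"].to_numpy()]
                 + r2[base["scanner"].to_numpy()] + eps)
            if spec.response_mode == "positive":
                sigma = spec.positive_base * np.exp(spec.positive_scale * z)
            else:
                sigma = z
            grp = base.copy()
            grp["roi"] = roi
            grp["scalar"] = scalar
            grp["sigma"] = sigma
            tables.append(grp)
            truth["groups"][f"{roi}|{scalar}"] = {
                "subject_intercepts": r1.tolist(),
                "scanner_intercepts": r2.tolist(),
            }
    table = pd.concat(tables, ignore_index=True)[COHORT_COLUMNS]
    return table, truth


def write_cohort(table: pd.DataFrame, truth: dict | None,
                 csv_path: str | Path) -> None:
    """Write the cohort CSV and, if given, the truth sidecar JSON next to it."""
    csv_path = Path(csv_path)
    table.to_csv(csv_path, index=False)
    if truth is not None:
        sidecar = csv_path.with_suffix(".truth.json")
        sidecar.write_text(json.dumps(truth, indent=1))


def read_cohort(csv_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(csv_path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df
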