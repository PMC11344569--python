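"""Diffusion tensor fitting and scalar map computation.

Fits the single-tensor model to diffusion-weighted signals by log-linear
least squares and derives the four rotationally invariant scalars (FA, MD,
AD, RD) from the tensor eigenvalues.  The fit keeps its log-space residuals
so that model-based resampling (wild bootstrap) can reuse them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import nibabel as nib
import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .synthdata import GradientTable

SCALAR_NAMES = ("FA", "MD", "AD", "RD")


@dataclass
class DWIVolume:
    """4D diffusion-weighted signal with its gradient table.

    ``data`` is indexed (x, y, z, gradient) in arbitrary intensity units;
    ``gradients`` pairs each volume with a b-value (s/mm²) and a unit
    direction; ``voxel_size`` is millimetres per voxel edge.
    """

    data: np.ndarray
    gradients: "GradientTable"
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4D (x, y, z, gradient)")
        if self.data.shape[3] != len(self.gradients):
            raise ValueError(
                f"gradient axis length {self.data.shape[3]} != "
                f"gradient table length {len(self.gradients)}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("DWI intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class LabelMap:
    """Integer ROI labels on a 3D grid; 0 means background."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label map must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must be integer-typed")

    def mask(self, label: int | None = None) -> np.ndarray:
        """Binary mask of one label, or of all foreground if label is None."""
        if label is None:
            return self.labels > 0
        return self.labels == label

    def present_labels(self) -> list[int]:
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v > 0]


@dataclass
class ScalarMap:
    """One 3D DTI scalar (FA/MD/AD/RD); NaN marks voxels outside the fit."""

    values: np.ndarray
    name: str
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("scalar map must be 3D")
        if self.name not in SCALAR_NAMES:
            raise ValueError(f"scalar name must be one of {SCALAR_NAMES}")


@dataclass
class TensorFit:
    """Per-voxel tensor coefficients from the log-linear fit.

    ``coeffs`` holds (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, ln S0) per voxel inside
    ``mask``; ``residuals`` are ln S − ln Ŝ at every design row (b0 rows
    included), the raw material for the wild bootstrap.  ``dwi_residuals``
    restricts them to the b>0 gradients.

    With a single b0 volume the b0 row has leverage exactly 1 — on a single
    shell, ln S0 is confounded with the tensor trace among the b>0 rows, so
    the fit interpolates the b0 and its residual is identically zero.
    Residual resampling is then blind to b0 noise; acquisitions intended for
    model-based uncertainty estimation need several b0 rows.
    """

    coeffs: np.ndarray            # (n_voxels, 7)
    residuals: np.ndarray         # (n_voxels, n_rows), all design rows
    mask: np.ndarray              # 3D bool, True where fitted
    design: np.ndarray            # (n_rows, 7) log-linear design used
    dwi_rows: np.ndarray          # bool, rows of design with b > 0
    leverages: np.ndarray         # (n_rows,) hat-matrix diagonal
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def n_voxels(self) -> int:
        return self.coeffs.shape[0]

    @property
    def dwi_residuals(self) -> np.ndarray:
        """Residuals at the b>0 gradients only."""
        return self.residuals[:, self.dwi_rows]

    def tensors(self) -> np.ndarray:
        """Assemble (n_voxels, 3, 3) symmetric tensors from coefficients."""
        return tensors_from_coeffs(self.coeffs)


def design_matrix(bvals: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Log-linear tensor design: ln S = ln S0 − b gᵀ D g.

    Columns order the 6 unique tensor elements as
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) followed by the ln S0 column.
    """
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(directions, dtype=float)
    X = np.empty((len(b), 7))
    X[:, 0] = -b * g[:, 0] ** 2
    X[:, 1] = -b * g[:, 1] ** 2
    X[:, 2] = -b * g[:, 2] ** 2
    X[:, 3] = -2.0 * b * g[:, 0] * g[:, 1]
    X[:, 4] = -2.0 * b * g[:, 0] * g[:, 2]
    X[:, 5] = -2.0 * b * g[:, 1] * g[:, 2]
    X[:, 6] = 1.0
    return X


def tensors_from_coeffs(coeffs: np.ndarray) -> np.ndarray:
    c = np.atleast_2d(coeffs)
    D = np.empty((c.shape[0], 3, 3))
    D[:, 0, 0] = c[:, 0]
    D[:, 1, 1] = c[:, 1]
    D[:, 2, 2] = c[:, 2]
    D[:, 0, 1] = D[:, 1, 0] = c[:, 3]
    D[:, 0, 2] = D[:, 2, 0] = c[:, 4]
    D[:, 1, 2] = D[:, 2, 1] = c[:, 5]
    return D


def fit_tensor(dwi: DWIVolume, mask: np.ndarray | LabelMap) -> TensorFit:
    """Fit the diffusion tensor voxel-wise by ordinary least squares in
    log-signal space.

    Multiple b=0 volumes are averaged in log space before fitting, so the
    design always carries exactly one b0 row.  Voxels with any non-positive
    b>0 signal are dropped from the mask (logged via the returned mask).

    Parameters
    ----------
    dwi : DWIVolume
    mask : 3D boolean array or LabelMap (foreground = all labels > 0)

    Returns
    -------
    TensorFit with per-voxel coefficients and log-space residuals.
    """
    if isinstance(mask, LabelMap):
        mask = mask.mask()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.shape:
        raise ValueError("mask grid does not match DWI grid")

    gt = dwi.gradients
    bvals = np.asarray(gt.b_values, dtype=float)
    dirs = np.asarray(gt.directions, dtype=float)
    b0_idx = np.flatnonzero(bvals == 0)
    dwi_idx = np.flatnonzero(bvals > 0)
    if len(b0_idx) < 1:
        raise ValueError("need at least one b=0 volume")
    if len(dwi_idx) + 1 < 7:
        raise ValueError("need at least 7 gradients (1 b0 + 6 weighted)")

    signals = dwi.data[mask]                      # (n_vox, n_grad)
    positive = np.all(signals > 0, axis=1)
    fit_mask = mask.copy()
    fit_mask[mask] = positive
    signals = signals[positive]
    if signals.shape[0] == 0:
        raise ValueError("no voxel with all-positive signals inside mask")

    # every acquired volume is one design row; b0 rows (direction moot at
    # b = 0) anchor ln S0
    Y = np.log(signals)                           # (n_vox, n_grad)
    rows_g = dirs.copy()
    rows_g[b0_idx] = [0.0, 0.0, 1.0]
    X = design_matrix(bvals, rows_g)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("rank-deficient gradient design: directions do not "
                         "span the 6 tensor degrees of freedom")

    pinv = np.linalg.pinv(X)
    coeffs = Y @ pinv.T                           # (n_vox, 7)
    fitted = coeffs @ X.T
    resid = Y - fitted
    leverages = np.einsum("ij,ji->i", X, pinv)
    return TensorFit(
        coeffs=coeffs,
        residuals=resid,
        mask=fit_mask,
        design=X,
        dwi_rows=bvals > 0,
        leverages=leverages,
        voxel_size=dwi.voxel_size,
    )


def scalars_from_eigenvalues(evals: np.ndarray) -> dict[str, np.ndarray]:
    """FA/MD/AD/RD from eigenvalues sorted descending along the last axis.

    FA = sqrt(3/2)·sqrt(Σ(λ−MD)²) / sqrt(Σλ²), defined as 0 for the zero
    tensor and clipped into [0, 1] to guard against round-off; negative
    eigenvalues from noisy fits are used as-is.
    """
    lam = np.asarray(evals, dtype=float)
    md = lam.mean(axis=-1)
    ad = lam[..., 0]
    rd = lam[..., 1:].mean(axis=-1)
    num = np.sqrt(((lam - md[..., None]) ** 2).sum(axis=-1))
    den = np.sqrt((lam ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    # stick limit (λ2 = λ3 = 0, λ1 > 0) is analytically FA = 1; force it
    # past the round-off of the quotient form
    stick = (lam[..., 0] > 0) & (lam[..., 1] == 0) & (lam[..., 2] == 0)
    fa = np.where(stick, 1.0, fa)
    fa = np.clip(fa, 0.0, 1.0)
    return {"FA": fa, "MD": md, "AD": ad, "RD": rd}


def compute_scalars(fit: TensorFit) -> dict[str, ScalarMap]:
    """Eigen-decompose each fitted tensor and map out FA, MD, AD and RD.

    Returns a dict of ScalarMaps on the fit's grid with NaN outside the
    fitted mask.
    """
    D = fit.tensors()
    evals = np.linalg.eigvalsh(D)[:, ::-1]        # descending
    vals = scalars_from_eigenvalues(evals)
    out: dict[str, ScalarMap] = {}
    for name in SCALAR_NAMES:
        grid = np.full(fit.mask.shape, np.nan)
        grid[fit.mask] = vals[name]
        out[name] = ScalarMap(values=grid, name=name, voxel_size=fit.voxel_size)
    return out


# ---------------------------------------------------------------------------
# NIfTI / FSL-dialect I/O
# ---------------------------------------------------------------------------

def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_scalar_map(smap: ScalarMap, path: str | Path) -> None:
    img = nib.Nifti1Image(smap.values.astype(np.float32), _affine(smap.voxel_size))
    nib.save(img, str(path))


def read_scalar_map(path: str | Path, name: str) -> ScalarMap:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ScalarMap(values=np.asanyarray(img.dataobj, dtype=float),
                     name=name, voxel_size=zooms)


def write_dwi(dwi: DWIVolume, prefix: str | Path) -> None:
    """Write a 4D NIfTI plus FSL-dialect .bval/.bvec (3×N, row-major axes)."""
    prefix = Path(prefix)
    img = nib.Nifti1Image(dwi.data.astype(np.float32), _affine(dwi.voxel_size))
    nib.save(img, str(prefix) + ".nii.gz")
    bvals = np.asarray(dwi.gradients.b_values, dtype=float)
    bvecs = np.asarray(dwi.gradients.directions, dtype=float)
    np.savetxt(str(prefix) + ".bval", bvals[None, :], fmt="%.1f")
    np.savetxt(str(prefix) + ".bvec", bvecs.T, fmt="%.8f")


def read_dwi(prefix: str | Path) -> DWIVolume:
    from .synthdata import GradientTable  # avoid import cycle at module load

    prefix = Path(prefix)
    img = nib.load(str(prefix) + ".nii.gz")
    data = np.asanyarray(img.dataobj, dtype=float)
    bvals = np.loadtxt(str(prefix) + ".bval").ravel()
    bvecs = np.loadtxt(str(prefix) + ".bvec")
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DWIVolume(data=data,
                     gradients=GradientTable(directions=bvecs, b_values=bvals),
                     voxel_size=zooms)


def write_label_map(labels: LabelMap, path: str | Path,
                    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    import json

    img = nib.Nifti1Image(labels.labels.astype(np.int16), _affine(voxel_size))
    nib.save(img, str(path))
    lookup = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + "_names.json")
    lookup.write_text(json.dumps({str(k): v for k, v in labels.names.items()}))


def read_label_map(path: str | Path) -> LabelMap:
    import json

    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj).astype(np.int64)
    lookup = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + "_names.json")
    names = {}
    if lookup.exists():
        names = {int(k): v for k, v in json.loads(lookup.read_text()).items()}
    return LabelMap(labels=labels, names=names)
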