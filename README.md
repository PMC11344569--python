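# dtivar

Region-wise variance characterization for diffusion tensor imaging (DTI).

Large longitudinal neuroimaging studies pool scans across subjects, years
and scanners, and the *variance* of DTI scalars (FA, MD, AD, RD) within a
brain region is itself a quantity of scientific interest: it mixes imaging
noise with microstructural heterogeneity and changes with age, head motion
and hardware. `dtivar` is a toolkit for studying that variance end to end on
fully synthetic data:

* **Synthetic data** — Stejskal–Tanner DWI phantoms
  (S = S₀·exp(−b gᵀDg), Gaussian or Rician noise, 32 directions +
  b0 at b = 700 s/mm²) and longitudinal cohort tables drawn from a known
  mixed model, so every estimator can be checked against ground truth.
* **Tensor core** — log-linear least-squares tensor fits and the scalar
  maps FA, MD, AD, RD from the eigenvalues λ₁ ≥ λ₂ ≥ λ₃.
* **Noise estimation** — the four classic method families: repeated
  acquisitions (SD / bootstrap / jackknife), scan–rescan
  (SD of the difference image / √2), ROI-based (within-region SD), and the
  wild bootstrap (tensor-fit residuals flipped by Rademacher signs),
  plus per-ROI SNR reports.
* **Whitening** — for Y = Xβ + ε with ε ~ N(0, Σ), Σ diagonal but
  non-constant, OLS on the whitened system (WY, WX) with W = Σ^(−1/2) is
  exact GLS; a simulation quantifies the false-positive inflation and power
  loss of ignoring Σ.
* **Mixed models** — per ROI×scalar, the standardized within-ROI SD is
  modelled as

      σ ~ baseline + interval + motion + sex + rescan
          + (1 | subject) + (1 | scanner) + ε

  with crossed random intercepts fit by REML (own implementation, profiled
  likelihood + Woodbury identity), likelihood-ratio term tests, backward
  selection, and Benjamini–Hochberg FDR across regions.

## Worked example

```python
import numpy as np
from dtivar import (two_roi_phantom, default_gradient_table, generate_dwi,
                    fit_tensor, compute_scalars, estimate_roi,
                    CohortSpec, generate_cohort, LMMSpec, fit_lmm)

# phantom -> scalar maps -> per-ROI sigma
dwi, labels, truth = generate_dwi(
    two_roi_phantom(noise_model="gaussian", sigma=0.02, seed=1),
    default_gradient_table())
maps = compute_scalars(fit_tensor(dwi, labels))
est = estimate_roi(maps["FA"], labels.labels == 1)
print(f"ROI sigma(FA) = {est.sigma:.4f} over {est.n_samples} voxels")

# synthetic cohort -> crossed-intercepts REML fit
table, _ = generate_cohort(CohortSpec(n_subjects=60, seed=7))
fit = fit_lmm(table, LMMSpec())
print({k: round(v, 3) for k, v in fit.beta.items()})
print({k: round(v, 3) for k, v in fit.vcomp.items()})
```

Output:

```
ROI sigma(FA) = 0.0201 over 160 voxels
{'intercept': -0.318, 'baseline': 0.122, 'interval': 0.639, 'motion': 0.346, 'sex': 0.381, 'rescan': 0.301}
{'subject': 0.379, 'scanner': 0.0, 'residual': 0.878}
```

The phantom's anisotropic box has noise-free FA ≈ 0.80, so 0.020 is the
noise-driven spread of FA inside the region at this SNR. The cohort was
generated with β = (0, 0.1, 0.5, 0.3, 0.2, 0.1) and variance components
(0.25, 0.09, 1.0); at 60 subjects the fit recovers them up to sampling
error — note the scanner component, estimated from only 4 scanner levels,
lands on the boundary at 0 in this draw.

A command-line layer mirrors the pipeline stages:

```bash
dtivar simulate cohort --seed 3 --out cohort.csv
dtivar fit-regions --cohort cohort.csv --out results.csv
dtivar whiten-demo --scenario null --seed 1 --out sim.json
dtivar run --config run.yaml
```

## Layout

```
src/dtivar/
  synthdata.py   # phantoms, gradient tables, cohort generator
  dti_core.py    # tensor fit, scalar maps, NIfTI / bval / bvec I/O
  noise_est.py   # the four noise estimator families + SNR report
  hetreg.py      # whitening, OLS, FP/FN simulation
  lmm.py         # crossed-intercepts REML, selection, BH-FDR
  pipeline.py    # sigma-table extraction, motion comparison, full runs
  cli.py         # thin click layer over the above
docs/methods.md  # modelling and design notes
```
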