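# Methods and design notes

This note documents the models behind `dtivar`, the defaults and why they
were chosen, the numerical strategy of the mixed-model engine, and what the
synthetic generators do and do not emulate.

## Signal model and tensor fit

Diffusion-weighted signals follow the Stejskal–Tanner monoexponential
model: for gradient q with b-value b_q (s/mm²) and unit direction g_q,

    S_q = S0 · exp(−b_q · g_qᵀ D g_q),

with D the symmetric positive-semidefinite diffusion tensor (mm²/s). The
default phantom recipes use white-matter-like eigenvalues
(1.7, 0.3, 0.3)×10⁻³ mm²/s and the default acquisition is one shell of 32
electrostatically spread directions at b = 700 s/mm² plus one b0 volume,
matching a typical clinical aging-study protocol. Noise is additive
Gaussian or magnitude Rician (√((S+n₁)² + n₂²), n₁, n₂ ~ N(0, σ²)) at a
configurable σ in signal units; S0 defaults to 1, so σ = 0.02 means
b0 SNR 50.

The tensor is fit by unweighted ordinary least squares in log-signal space
over the 7-parameter design (6 tensor elements + ln S0). Reasons: it is
the simplest residual-generating model for the wild bootstrap, and weighting
or robust reweighting would change the residual structure that the variance
analysis studies. Voxels with any non-positive signal are excluded from the
fit mask rather than clamped. Negative eigenvalues of noisy fits are kept;
only FA is clipped into [0, 1], and the exact stick limit (λ₂ = λ₃ = 0) is
assigned FA = 1 analytically because the quotient form loses one ulp there.

**The single-b0 leverage pathology.** On a single shell, adding a constant
to ln S0 and α·I to D changes no b > 0 signal prediction, so ln S0 is
identified only by the b0 rows. With exactly one b0 row its hat-matrix
leverage is 1: the fit interpolates it and its residual is identically
zero. Consequently every b0 volume is kept as an ordinary design row (no
log-averaging into a pseudo-row), so that acquisitions with several b0
volumes have genuine, resampleable b0 residuals. This matters for the wild
bootstrap below.

## Noise estimation

Four estimator families, differing in data requirements and assumptions:

1. **Multiple acquisition** — per-voxel sample SD across aligned repeats
   (no assumptions), or bootstrap/jackknife of a per-ROI statistic.
2. **Scan–rescan** — SD of the voxelwise difference of two acquisitions
   over a region, divided by √2 (the difference carries both images'
   noise). Assumes spatially constant noise over the region.
3. **ROI-based** — sample SD of a single acquisition within a region.
   Assumes signal and noise both constant there; this is the σ fed to the
   region-wise models. On real anatomy it also captures microstructural
   heterogeneity — a known limitation of the proxy, not of the estimator.
4. **Wild bootstrap** — per voxel, flip each log-space residual by an
   independent Rademacher sign, add back to the fitted log-signals, refit,
   recompute the scalar; the replicate SD and percentile interval quantify
   fit uncertainty from one acquisition.

All sample SDs use denominator n − 1 (unbiased variance on small regions).
ROI statistics skip voxels excluded by the fit instead of imputing them.
SNR is defined as ROI mean / ROI sample SD; that definition is recorded in
every CSV the reporting code writes.

Wild-bootstrap flavors: `hc0` (raw residuals, the default) and `hc2`
(residuals scaled by 1/√(1−h)). OLS residuals have variance σ²(1−h), so
`hc0` understates the noise by the mean leverage (7 parameters over ~35
rows ≈ 10% in SD); `hc2` undoes this exactly in second moments. For
calibrated confidence intervals use an acquisition with ≥ 2 b0 volumes
(see the leverage pathology above) and `hc2`; the acceptance suite
demonstrates 92–93% empirical coverage of nominal 95% intervals on a 4-b0
protocol, and factor-of-~1.5 agreement between bootstrap SD and the
fresh-noise Monte-Carlo SD. With a single b0 the bootstrap is blind to b0
noise and materially understates FA uncertainty — measured ~0.010 vs a true
0.021 at b0 SNR 50 — which is why the default protocol table accepts an
`n_b0` argument.

## Whitening under heteroscedasticity

For Y = Xβ + ε, ε ~ N(0, Σ) with known diagonal Σ, the whitened system
(WY, WX) with W = Σ^(−1/2) has unit-variance errors, so OLS on it is exact
GLS and the slope's t test is exactly calibrated. The simulation compares
that arm against plain OLS with conventional homoscedastic standard errors.

Simulation defaults: M = 100 samples per experiment, x ~ U(0, 1), 10,000
experiments in batches of 100, α = 0.05, variance profile

    σ²(x) = 1 + 99·t⁴,  t = scaled x ∈ [0, 1].

The quartic profile concentrates variance where the slope's leverage is
high. That choice is deliberate: a linear ramp aligned with x leaves plain
OLS essentially calibrated (measured FP ≈ 4.8 vs 5.1 per 100 whitened)
because the symmetric leverage of the slope estimator averages the
miscalibration away, whereas the quartic profile produces the textbook
failure mode (FP ≈ 11.6 vs 5.3 per 100) while whitening also retains a
real efficiency advantage under the alternative (FN ≈ 18.5 vs 52 per 100
at slope 3.0). A symmetric U-shaped profile was rejected: it inflates FP
but hands plain OLS *spurious* power under the alternative, so neither
error direction can be shown on one profile. The alternative slope 3.0 was
fixed once so that plain-OLS power sits near one half, keeping both error
kinds visible; the profile degree, range and slope are all configurable.
The slope test uses the t distribution with M − 2 degrees of freedom, not
a normal approximation, so the 5-per-100 calibration is exact at M = 100.

## The region-wise mixed model

Per ROI×scalar pair, with the response z-scored within the pair (each
model sees a mean-0, SD-1 response; standardization of one group never
touches another):

    σ_ijkl = β₀ + β_b·baseline_i + β_i·interval_ij + β_m·motion_ijl
             + β_s·sex_i + β_r·rescan_ijl + r1_i + r2_k + ε_ijkl,

ages in decades, motion in mm, r1 ~ N(0, σ²_subject) per subject,
r2 ~ N(0, σ²_scanner) per scanner — crossed, since subjects change
scanners — and ε i.i.d.

**Estimation.** REML with β and the residual variance profiled out. Writing
V = σ²_ε(I + γ_s Z_sZ_sᵀ + γ_c Z_cZ_cᵀ), the criterion is optimized over
the log variance ratios log γ. The Woodbury identity reduces all n×n
algebra to the q×q capacitance matrix A = I_q + SᵀZᵀZS (q = subjects +
scanners), making a 1,200-row fit a few hundred sub-millisecond Cholesky
factorizations. Optimization: coarse grid over log γ ∈ {−6, −2, 0, 2}ᵈ,
Nelder–Mead polish from the best start(s) to 1e-9/1e-10 tolerances, and a
boundary snap that sets a ratio below 1e-4 exactly to zero when the
criterion does not object — so "no group structure" reproduces plain OLS
to machine-level agreement. Validation: the fit equals the balanced
one-way ANOVA closed form to ~1e-7 relative and matches statsmodels'
variance-components MixedLM on crossed data to 4+ digits.

**Term tests.** Fixed-term p-values come from likelihood-ratio comparisons
of ML refits with and without the term (REML likelihoods are not
comparable across fixed-effect structures). This replaces the
Satterthwaite-F machinery of the reference R workflow: for crossed designs
those denominators are a large, error-prone subsystem, and the LRT is
asymptotically equivalent; its finite-sample type-I error is verified by
simulation (measured 4.7–5.0% at 360-row cohorts, inside the 99% binomial
band). Random-intercept tests use the REML LRT with the boundary-corrected
½χ²₀ + ½χ²₁ reference, since σ² = 0 lies on the parameter boundary.

**Backward selection.** Phase 1 removes random intercepts (largest p
first) while p > α_random = 0.1; phase 2 removes fixed terms while
p > α_fixed = 0.05. The thresholds are the conventional defaults of
stepwise elimination and are config-exposed. Terms removed by selection
appear in outputs with a `retained = False` marker and NaN estimates —
never as β = 0. Factors whose grouping column is absent from the data skip
phase 1 entirely. Every candidate, statistic and decision is recorded in a
selection trace.

**FDR.** Benjamini–Hochberg step-up (monotone cumulative-minimum adjusted
values capped at 1) applied across ROI×scalar models separately per
covariate term; pooling all terms globally is a config switch. Per-term
pooling is the closer reading of "adjust across the scalar–region pairs"
and keeps each term's family homogeneous. NaN p-values (terms removed by
selection, failed refits) pass through without shrinking the family size.
Note the selection step conditions retained null terms on p < α_fixed, so
the empirical FDR among truly null regions is meaningful only when the
signal regions have real power; the FDR acceptance simulation therefore
uses conditions (3 sessions, interval effect 1.2 SD per decade) where
signal regions are detected essentially always, and measures mean FDR
≈ 0.02 at q = 0.05.

## The cohort generator

`generate_cohort` draws directly from the model above with known truth:
baseline ages uniform on 22.4–94.4 years (stored in decades — the
years-to-decades conversion happens inside the generator, or exactly once
in the extraction stage when starting from covariate CSVs); 1–12 sessions
with uniform 1–3-year gaps; 1 or 2 scans per session; motion lognormal
with median 0.26 mm and log-SD 0.5, with a +0.045 mm additive shift on
rescans so the motion-comparison operation has a known signal to recover
(the lognormal is a stand-in — the empirical distribution of real motion
values is not published — and every parameter of it is configurable); sex
a 0/1 indicator with male fraction 0.473; subjects keep a home scanner
with a 6% per-session switch probability, giving the crossed structure its
off-diagonal mass. Responses are generated on the z scale directly, since
the analysis models standardized σ; a positive-σ mode
(σ = 0.02·exp(0.25·z)) exists to exercise the standardization step itself.
Each ROI×scalar group draws independent random intercepts and residuals,
and the hidden-truth sidecar records every draw.

What the generator does **not** emulate: susceptibility or eddy
distortions, slice dropout, motion artifacts in the images themselves,
spatially correlated or parallel-imaging-weighted noise fields,
within-region signal heterogeneity, and any preprocessing pipeline.
Passing tests therefore demonstrate the statistical machinery — estimator
consistency, calibration, FDR control — under the stated models, not
robustness to real-scanner artifacts, and the published coefficients from
the access-restricted aging cohorts are out of reach by construction.

## Scales used in the validation suite

The acceptance tests run the whitening experiment at its full 10,000
experiments; estimator recovery on 10⁵-voxel phantoms; wild-bootstrap
coverage on 500 voxels × 500 replicates; coefficient coverage on 100
cohorts of 200 subjects × 3 sessions × 2 scans over 4 scanners; term-test
calibration on 1,000 refits of 360-row cohorts; and FDR control on 50
replicates of an 8-region half-null design. These sizes were chosen so
Monte-Carlo error is small against each tolerance while the whole suite
stays comfortably under typical CI time budgets.

## Known limitations

* The ROI-based σ is a noise proxy; on structured anatomy it conflates
  noise with heterogeneity (by design, the synthetic ROIs are homogeneous).
* LRT p-values are asymptotic; with very few subjects or scanner levels
  they drift anticonservative, and the scanner variance (4 levels in the
  default design) is estimated with large relative error even when β
  coverage is nominal.
* Backward selection is unstable in the well-known sense: near-threshold
  terms flip between neighboring datasets, and post-selection p-values of
  retained terms are conditioned on survival.
* The wild bootstrap assumes the tensor model captures the signal; under
  model misfit (crossing fibers, non-monoexponential decay) its σ reflects
  the misfit as well as the noise.
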