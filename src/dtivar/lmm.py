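"""Region-wise linear mixed-effects modelling of DTI scalar variance.

Each ROI×scalar pair gets a model of the form

    sigma ~ baseline + interval + motion + sex + rescan
            + (1 | subject) + (1 | scanner) + error

with the response standardized (z-scored) within the pair before fitting.
The two random intercepts are *crossed*: subjects move between scanners, so
neither factor nests the other.  The marginal covariance is

    V = σ²_subject Z_s Z_sᵀ + σ²_scanner Z_c Z_cᵀ + σ²_resid I,

and β̂ is the GLS estimate at the optimum — the mixed-model generalization
of whitening by V^(−1/2).  Variance components are estimated by restricted
maximum likelihood (REML), profiling out β and the residual variance and
optimizing the log variance ratios with multiple starts.

Fixed-term p-values come from likelihood-ratio comparisons of ML refits
with and without the term; random-intercept p-values from REML likelihood
ratios with the boundary-corrected ½χ²₀ + ½χ²₁ reference.  Backward
selection removes random terms first, then fixed terms; Benjamini–Hochberg
FDR is applied across ROI×scalar models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

FIXED_TERMS = ("baseline", "interval", "motion", "sex", "rescan")
TERM_COLUMNS = {
    "baseline": "age_baseline_dec",
    "interval": "interval_dec",
    "motion": "motion_mm",
    "sex": "sex",
    "rescan": "rescan",
}
FACTOR_COLUMNS = {"subject": "subject", "scanner": "scanner"}


@dataclass(frozen=True)
class LMMSpec:
    """Which fixed terms and random intercepts a model carries.

    The intercept is always present and never removable.
    """

    fixed_terms: tuple[str, ...] = FIXED_TERMS
    random_factors: tuple[str, ...] = ("subject", "scanner")
    criterion: str = "reml"              # "reml" | "ml"

    def __post_init__(self) -> None:
        for t in self.fixed_terms:
            if t not in TERM_COLUMNS:
                raise ValueError(f"unknown fixed term {t!r}")
        for f in self.random_factors:
            if f not in FACTOR_COLUMNS:
                raise ValueError(f"unknown random factor {f!r}")
        if self.criterion not in ("reml", "ml"):
            raise ValueError("criterion must be 'reml' or 'ml'")


@dataclass
class LMMFit:
    """One fitted mixed model: estimates, components, and the design it was
    fit to (kept so term tests can refit without the caller re-slicing)."""

    spec: LMMSpec
    beta: dict[str, float]
    se: dict[str, float]
    vcomp: dict[str, float]              # per-factor variances + "residual"
    loglik: float                        # restricted (or ML) log-likelihood
    reml: bool
    converged: bool
    n_obs: int
    p_wald: dict[str, float] = field(default_factory=dict)
    # design payload for refits
    _y: np.ndarray | None = None
    _X: np.ndarray | None = None
    _colnames: list[str] | None = None
    _factors: dict[str, np.ndarray] | None = None


class LMMError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Profiled (RE)ML machinery
# ---------------------------------------------------------------------------

class _Profile:
    """Precomputed cross-products for fast profiled likelihood evaluation.

    With U = [Z_1·√γ_1, …] the scaled random design, V0 = I + U Uᵀ and the
    Woodbury identity reduce every n×n operation to the q×q capacitance
    matrix A = I_q + S ZᵀZ S (S = diag of √γ per block), where q is the
    total number of random levels.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray,
                 factors: dict[str, np.ndarray]):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.names = list(factors)
        self.codes = [np.asarray(factors[f]) for f in self.names]
        self.q_sizes = [int(c.max()) + 1 if len(c) else 0 for c in self.codes]
        q = sum(self.q_sizes)
        self.q = q
        offs = np.cumsum([0] + self.q_sizes)
        self.block = [slice(offs[i], offs[i + 1]) for i in range(len(self.names))]

        ZtZ = np.zeros((q, q))
        ZtX = np.zeros((q, self.p))
        Zty = np.zeros(q)
        for i, ci in enumerate(self.codes):
            oi = offs[i]
            np.add.at(Zty, oi + ci, y)
            for j in range(self.p):
                np.add.at(ZtX[:, j], oi + ci, X[:, j])
            for jj, cj in enumerate(self.codes):
                oj = offs[jj]
                np.add.at(ZtZ, (oi + ci, oj + cj), 1.0)
        self.ZtZ, self.ZtX, self.Zty = ZtZ, ZtX, Zty
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _scale(self, gammas: np.ndarray) -> np.ndarray:
        s = np.empty(self.q)
        for i, sl in enumerate(self.block):
            s[sl] = np.sqrt(gammas[i])
        return s

    def core(self, gammas: np.ndarray):
        """Return (beta, quad, logdetV0, logdetXtV0X, XtV0X) at given ratios."""
        if self.q == 0 or len(gammas) == 0:
            XtVX = self.XtX
            beta = np.linalg.solve(XtVX, self.Xty)
            quad = self.yty - beta @ self.Xty
            sign, logdetX = np.linalg.slogdet(XtVX)
            return beta, max(quad, 1e-300), 0.0, logdetX, XtVX
        s = self._scale(np.asarray(gammas, float))
        A = np.eye(self.q) + (s[:, None] * self.ZtZ) * s[None, :]
        L = np.linalg.cholesky(A)
        logdetV0 = 2.0 * float(np.log(np.diag(L)).sum())
        SZtX = s[:, None] * self.ZtX
        SZty = s * self.Zty
        # A^{-1} applications via the Cholesky factor
        WX = solve_triangular(L, SZtX, lower=True)
        Wy = solve_triangular(L, SZty, lower=True)
        XtVX = self.XtX - WX.T @ WX
        XtVy = self.Xty - WX.T @ Wy
        ytVy = self.yty - Wy @ Wy
        beta = np.linalg.solve(XtVX, XtVy)
        quad = float(ytVy - beta @ XtVy)
        sign, logdetX = np.linalg.slogdet(XtVX)
        return beta, max(quad, 1e-300), logdetV0, logdetX, XtVX

    def neg2ll_g(self, gammas: np.ndarray, reml: bool) -> float:
        _, quad, logdetV0, logdetX, _ = self.core(gammas)
        n, p = self.n, self.p
        if reml:
            s2 = quad / (n - p)
            return (logdetV0 + logdetX
                    + (n - p) * (np.log(2.0 * np.pi * s2) + 1.0))
        s2 = quad / n
        return logdetV0 + n * (np.log(2.0 * np.pi * s2) + 1.0)

    def neg2ll(self, log_gammas: np.ndarray, reml: bool) -> float:
        return self.neg2ll_g(np.exp(np.clip(log_gammas, -30.0, 30.0)), reml)

    def finish(self, gammas: np.ndarray, reml: bool):
        """Assemble estimates at the optimum."""
        beta, quad, _, _, XtVX = self.core(gammas)
        dof = self.n - self.p if reml else self.n
        s2 = quad / dof
        cov_beta = s2 * np.linalg.inv(XtVX)
        se = np.sqrt(np.diag(cov_beta))
        vcomp = {name: float(s2 * g) for name, g in zip(self.names, gammas)}
        vcomp["residual"] = float(s2)
        return beta, se, vcomp


_LOG_GAMMA_BOUND = 12.0     # exp(±12): component ratio pinned ~0 or huge


def _optimize_profile(prof: _Profile, reml: bool) -> tuple[np.ndarray, float, bool]:
    """Return (gamma ratios, log-likelihood, converged)."""
    k = len(prof.names)
    if k == 0:
        return np.empty(0), -0.5 * prof.neg2ll_g(np.empty(0), reml), True
    # coarse multi-start grid on log ratios, then Nelder-Mead polish
    grid = [-6.0, -2.0, 0.0, 2.0]
    starts = np.array(np.meshgrid(*([grid] * k))).T.reshape(-1, k)
    vals = [prof.neg2ll(s, reml) for s in starts]
    order = np.argsort(vals)
    best_x, best_f, ok = None, np.inf, False
    n_polish = 2 if k >= 2 else 1
    for idx in order[:n_polish]:
        res = optimize.minimize(
            prof.neg2ll, starts[idx], args=(reml,), method="Nelder-Mead",
            options=dict(xatol=1e-9, fatol=1e-10, maxiter=4000, maxfev=6000))
        if res.fun < best_f:
            best_x, best_f, ok = res.x, res.fun, bool(res.success)
    gammas = np.exp(np.clip(best_x, -_LOG_GAMMA_BOUND, _LOG_GAMMA_BOUND))
    # boundary handling: a ratio wandering to the clip floor is a component
    # at zero; snap it there when the criterion does not object
    snapped = np.where(gammas < 1e-4, 0.0, gammas)
    if np.any(snapped != gammas):
        f_snap = prof.neg2ll_g(snapped, reml)
        if f_snap <= best_f + 1e-8:
            gammas, best_f = snapped, min(best_f, f_snap)
    return gammas, -0.5 * best_f, ok


# ---------------------------------------------------------------------------
# Public fitting API
# ---------------------------------------------------------------------------

def build_design(df: pd.DataFrame, spec: LMMSpec,
                 response: str = "sigma"):
    """Assemble (y, X, column names, factor level codes) from a table slice."""
    y = df[response].to_numpy(dtype=float)
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for t in spec.fixed_terms:
        cols.append(df[TERM_COLUMNS[t]].to_numpy(dtype=float))
        names.append(t)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise LMMError("fixed-effect design is rank-deficient")
    factors: dict[str, np.ndarray] = {}
    for f in spec.random_factors:
        col = FACTOR_COLUMNS[f]
        if col not in df.columns:
            continue   # no grouping column: factor cannot enter the model
        codes, levels = pd.factorize(df[col])
        if len(levels) < 2:
            continue   # a single level is indistinguishable from the intercept
        factors[f] = codes
    return y, X, names, factors


def fit_lmm(df: pd.DataFrame, spec: LMMSpec,
            fixed_components: dict[str, float] | None = None) -> LMMFit:
    """Fit the mixed model for one table slice.

    ``fixed_components`` pins the variance components (mapping factor name
    and "residual" to variances) instead of estimating them, in which case
    β̂ is the explicit GLS solution at those components.
    Deterministic given the data.
    """
    reml = spec.criterion == "reml"
    y, X, names, factors = build_design(df, spec)
    prof = _Profile(y, X, factors)

    if fixed_components is not None:
        s2 = fixed_components["residual"]
        gammas = np.array([fixed_components[f] / s2 for f in prof.names])
        beta, se, _ = prof.finish(gammas, reml)
        vcomp = {f: float(fixed_components[f]) for f in prof.names}
        vcomp["residual"] = float(s2)
        ll = -0.5 * prof.neg2ll_g(gammas, reml)
        converged = True
    else:
        gammas, ll, converged = _optimize_profile(prof, reml)
        beta, se, vcomp = prof.finish(gammas, reml)

    for f in spec.random_factors:
        vcomp.setdefault(f, 0.0)
    z = np.abs(beta) / np.where(se > 0, se, np.inf)
    p_wald = {nm: float(2.0 * stats.norm.sf(abs(zz)))
              for nm, zz in zip(names, z)}
    return LMMFit(
        spec=spec,
        beta={nm: float(b) for nm, b in zip(names, beta)},
        se={nm: float(s) for nm, s in zip(names, se)},
        vcomp=vcomp,
        loglik=float(ll),
        reml=reml,
        converged=converged,
        n_obs=len(y),
        p_wald=p_wald,
        _y=y, _X=X, _colnames=names, _factors=factors,
    )


def _loglik_arrays(y, X, factors, reml: bool) -> float:
    prof = _Profile(y, X, factors)
    _, ll, _ = _optimize_profile(prof, reml)
    return ll


def test_fixed_terms(fit: LMMFit, df: pd.DataFrame | None = None) -> dict[str, float]:
    """Likelihood-ratio p-value for each non-intercept fixed term.

    Both the full and the term-deleted model are refit by maximum
    likelihood (REML likelihoods are not comparable across fixed-effect
    structures); the statistic is referred to χ²₁.  The intercept is never
    tested.
    """
    if df is not None:
        fit = fit_lmm(df, fit.spec)
    if fit._y is None:
        raise LMMError("fit carries no design payload; pass the data slice")
    y, X, names, factors = fit._y, fit._X, fit._colnames, fit._factors
    ll_full = _loglik_arrays(y, X, factors, reml=False)
    out: dict[str, float] = {}
    for j, nm in enumerate(names):
        if nm == "intercept":
            continue
        X_red = np.delete(X, j, axis=1)
        try:
            ll_red = _loglik_arrays(y, X_red, factors, reml=False)
        except Exception:
            out[nm] = np.nan
            continue
        stat = max(0.0, 2.0 * (ll_full - ll_red))
        out[nm] = float(stats.chi2.sf(stat, df=1))
    return out


def test_random_factor(df: pd.DataFrame, spec: LMMSpec, factor: str) -> float:
    """Boundary-corrected REML likelihood-ratio p-value for one random
    intercept: the null σ²=0 sits on the parameter boundary, so the
    reference is the ½χ²₀ + ½χ²₁ mixture."""
    if factor not in spec.random_factors:
        raise ValueError(f"{factor!r} not in the model")
    full = fit_lmm(df, spec)
    reduced_spec = replace(
        spec, random_factors=tuple(f for f in spec.random_factors if f != factor))
    red = fit_lmm(df, reduced_spec)
    stat = max(0.0, 2.0 * (full.loglik - red.loglik))
    if stat == 0.0:
        return 1.0
    return float(0.5 * stats.chi2.sf(stat, df=1))


# these are model-testing operations, not pytest cases
test_fixed_terms.__test__ = False        # type: ignore[attr-defined]
test_random_factor.__test__ = False      # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# Backward selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionStep:
    phase: str          # "random" | "fixed"
    candidate: str
    p_value: float
    removed: bool


def backward_select(df: pd.DataFrame, full_spec: LMMSpec,
                    alpha_random: float = 0.1,
                    alpha_fixed: float = 0.05
                    ) -> tuple[LMMSpec, list[SelectionStep]]:
    """Backward elimination: random intercepts first, then fixed terms.

    In each phase the candidate with the largest p-value is dropped while
    that p-value exceeds the phase threshold; the trace records every
    candidate examined and the decision taken.
    """
    spec = full_spec
    trace: list[SelectionStep] = []

    # factors without a grouping column in the data skip phase 1 entirely
    present = tuple(f for f in spec.random_factors
                    if FACTOR_COLUMNS[f] in df.columns)
    spec = replace(spec, random_factors=present)

    while spec.random_factors:
        full = fit_lmm(df, spec)
        pvals = {}
        for f in spec.random_factors:
            try:
                red = fit_lmm(df, replace(spec, random_factors=tuple(
                    x for x in spec.random_factors if x != f)))
                stat = max(0.0, 2.0 * (full.loglik - red.loglik))
                pvals[f] = (1.0 if stat == 0.0
                            else float(0.5 * stats.chi2.sf(stat, df=1)))
            except Exception:
                pvals[f] = np.nan
        worst = max(pvals, key=lambda f: (-1 if np.isnan(pvals[f]) else pvals[f]))
        p = pvals[worst]
        if np.isnan(p) or p <= alpha_random:
            for f, pv in pvals.items():
                trace.append(SelectionStep("random", f, float(pv), False))
            break
        trace.append(SelectionStep("random", worst, float(p), True))
        spec = replace(spec, random_factors=tuple(
            f for f in spec.random_factors if f != worst))

    while spec.fixed_terms:
        y, X, names, factors = build_design(df, spec)
        ll_full = _loglik_arrays(y, X, factors, reml=False)
        pvals: dict[str, float] = {}
        for j, nm in enumerate(names):
            if nm == "intercept":
                continue
            try:
                ll_red = _loglik_arrays(y, np.delete(X, j, axis=1),
                                        factors, reml=False)
                stat = max(0.0, 2.0 * (ll_full - ll_red))
                pvals[nm] = float(stats.chi2.sf(stat, df=1))
            except Exception:
                pvals[nm] = np.nan
        worst = max(pvals, key=lambda t: (-1 if np.isnan(pvals[t]) else pvals[t]))
        p = pvals[worst]
        if np.isnan(p) or p <= alpha_fixed:
            for t, pv in pvals.items():
                trace.append(SelectionStep("fixed", t, float(pv), False))
            break
        trace.append(SelectionStep("fixed", worst, float(p), True))
        spec = replace(spec, fixed_terms=tuple(
            t for t in spec.fixed_terms if t != worst))

    return spec, trace


# ---------------------------------------------------------------------------
# Response standardization and FDR
# ---------------------------------------------------------------------------

def standardize_response(table: pd.DataFrame,
                         group_cols: tuple[str, ...] = ("roi", "scalar"),
                         response: str = "sigma") -> pd.DataFrame:
    """Z-score the response within each roi×scalar group.

    Each model then sees a mean-0, SD-1 (sample SD) response.  A group with
    zero spread cannot be standardized and raises with the group identity.
    """
    out = table.copy()
    for key, idx in table.groupby(list(group_cols)).groups.items():
        vals = table.loc[idx, response].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"group {key} has fewer than 2 rows")
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValueError(f"group {key} has zero response SD")
        out.loc[idx, response] = (vals - vals.mean()) / sd
    return out


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: adjusted p-values and rejection flags.

    Adjusted values use the monotone cumulative-minimum form capped at 1;
    rejection is adjusted ≤ q.  NaN entries pass through as NaN and are
    never counted in the family size.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full(p.shape, np.nan)
    rej = np.zeros(p.shape, dtype=bool)
    pf = p[finite]
    m = len(pf)
    if m:
        order = np.argsort(pf, kind="stable")
        ranked = pf[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        ranked = np.minimum(ranked, 1.0)
        a = np.empty(m)
        a[order] = ranked
        adj[finite] = a
        rej[finite] = a <= q
    return adj, rej


# ---------------------------------------------------------------------------
# Region-wise driver
# ---------------------------------------------------------------------------

@dataclass
class RegionwiseConfig:
    covariates: tuple[str, ...] = FIXED_TERMS
    random_factors: tuple[str, ...] = ("subject", "scanner")
    alpha_random: float = 0.1
    alpha_fixed: float = 0.05
    fdr_q: float = 0.05
    fdr_pooling: str = "per_term"        # "per_term" | "global"
    standardize: bool = True


@dataclass
class RegionwiseResult:
    """Long-format results plus per-group selection traces and failures.

    The table has one row per (roi, scalar, term); terms removed during
    selection keep their row with ``retained=False`` and NaN estimates (the
    "gray cells"), never a silently imputed zero.
    """

    table: pd.DataFrame
    traces: dict[tuple[str, str], list[SelectionStep]]
    failures: list[dict]


def run_region_wise(table: pd.DataFrame,
                    config: RegionwiseConfig | None = None) -> RegionwiseResult:
    """Standardize, select, fit and FDR-correct across all roi×scalar groups.

    Output row order is fixed by sorted group keys and the configured
    covariate order, so permuting input rows leaves results identical.
    """
    config = config or RegionwiseConfig()
    if config.standardize:
        table = standardize_response(table)
    full = LMMSpec(fixed_terms=tuple(config.covariates),
                   random_factors=tuple(config.random_factors))

    rows: list[dict] = []
    traces: dict[tuple[str, str], list[SelectionStep]] = {}
    failures: list[dict] = []
    keys = sorted(table.groupby(["roi", "scalar"]).groups)
    for roi, scalar in keys:
        df = table[(table["roi"] == roi) & (table["scalar"] == scalar)]
        df = df.sort_values(["subject", "session", "scan"]).reset_index(drop=True)
        try:
            spec, trace = backward_select(df, full,
                                          alpha_random=config.alpha_random,
                                          alpha_fixed=config.alpha_fixed)
            final = fit_lmm(df, spec)
            if not final.converged:
                raise LMMError("final fit did not converge")
            pvals = test_fixed_terms(final)
        except Exception as exc:   # logged, never silently dropped
            failures.append({"roi": roi, "scalar": scalar, "error": str(exc)})
            continue
        traces[(roi, scalar)] = trace
        for term in config.covariates:
            kept = term in spec.fixed_terms
            rows.append({
                "roi": roi, "scalar": scalar, "term": term,
                "beta": final.beta.get(term, np.nan) if kept else np.nan,
                "se": final.se.get(term, np.nan) if kept else np.nan,
                "p_raw": pvals.get(term, np.nan) if kept else np.nan,
                "retained": kept,
            })

    res = pd.DataFrame(rows)
    if len(res):
        res["p_adj"] = np.nan
        res["reject"] = False
        if config.fdr_pooling == "per_term":
            for term in config.covariates:
                sel = res["term"] == term
                adj, rej = bh_fdr(res.loc[sel, "p_raw"].to_numpy(), config.fdr_q)
                res.loc[sel, "p_adj"] = adj
                res.loc[sel, "reject"] = rej
        else:
            adj, rej = bh_fdr(res["p_raw"].to_numpy(), config.fdr_q)
            res["p_adj"] = adj
            res["reject"] = rej
    return RegionwiseResult(table=res, traces=traces, failures=failures)
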