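"""Mixed-model engine: REML components, GLS link, selection, FDR."""

import numpy as np
import pandas as pd
import pytest

from dtivar.lmm import (LMMSpec, RegionwiseConfig, backward_select, bh_fdr,
                        fit_lmm, run_region_wise, standardize_response,
                        test_fixed_terms, test_random_factor)
from dtivar.synthdata import CohortSpec, generate_cohort


def one_way_table(n_groups=20, n_per=5, sd_b=0.7, sd_w=1.0, seed=1):
    rng = np.random.default_rng(seed)
    r = rng.normal(0, sd_b, n_groups)
    y = (r[:, None] + rng.normal(0, sd_w, (n_groups, n_per))).ravel()
    return pd.DataFrame({
        "sigma": y,
        "subject": np.repeat(np.arange(n_groups), n_per),
        "scanner": 0, "age_baseline_dec": 0.0, "interval_dec": 0.0,
        "motion_mm": 0.0, "sex": 0, "rescan": 0,
    })


class TestStandardize:
    def test_zscore_example(self):
        df = pd.DataFrame({"sigma": [1.0, 2.0, 3.0], "roi": "r",
                           "scalar": "FA"})
        out = standardize_response(df)
        assert np.allclose(out["sigma"], [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        df = pd.DataFrame({"sigma": [-1.0, 0.0, 1.0], "roi": "r",
                           "scalar": "FA"})
        out = standardize_response(standardize_response(df))
        assert np.allclose(out["sigma"], [-1.0, 0.0, 1.0])

    def test_groups_are_local(self):
        df = pd.DataFrame({"sigma": [1.0, 2.0, 3.0, 10.0, 20.0, 30.0],
                           "roi": ["a"] * 3 + ["b"] * 3, "scalar": "FA"})
        out = standardize_response(df)
        assert np.allclose(out.loc[df["roi"] == "a", "sigma"], [-1, 0, 1])
        assert np.allclose(out.loc[df["roi"] == "b", "sigma"], [-1, 0, 1])

    def test_zero_sd_group_rejected_with_identity(self):
        df = pd.DataFrame({"sigma": [2.0, 2.0], "roi": "flat", "scalar": "FA"})
        with pytest.raises(ValueError, match="flat"):
            standardize_response(df)


class TestFitLmm:
    def test_no_grouping_matches_ols(self):
        """When the generating process has no group structure the REML fit
        collapses to plain OLS."""
        spec = CohortSpec(n_subjects=60, sd_subject=0.0, sd_scanner=0.0,
                          sd_resid=1.0, seed=2)
        tab, _ = generate_cohort(spec)
        fit = fit_lmm(tab, LMMSpec())
        assert fit.vcomp["subject"] < 1e-3
        assert fit.vcomp["scanner"] < 1e-3
        X = np.column_stack([np.ones(len(tab)),
                             tab["age_baseline_dec"], tab["interval_dec"],
                             tab["motion_mm"], tab["sex"], tab["rescan"]])
        beta_ols = np.linalg.lstsq(X, tab["sigma"].to_numpy(), rcond=None)[0]
        got = [fit.beta[t] for t in ("intercept", "baseline", "interval",
                                     "motion", "sex", "rescan")]
        assert np.allclose(got, beta_ols, atol=1e-6)

    def test_balanced_one_way_closed_form(self):
        """REML on balanced one-factor data has the ANOVA closed form:
        σ̂²_b = (MSB − MSW)/n_per, σ̂²_w = MSW."""
        n_g, n_per = 20, 5
        df = one_way_table(n_g, n_per)
        y = df["sigma"].to_numpy().reshape(n_g, n_per)
        msb = n_per * ((y.mean(1) - y.mean()) ** 2).sum() / (n_g - 1)
        msw = ((y - y.mean(1, keepdims=True)) ** 2).sum() / (n_g * (n_per - 1))
        fit = fit_lmm(df, LMMSpec(fixed_terms=(), random_factors=("subject",)))
        assert fit.vcomp["subject"] == pytest.approx((msb - msw) / n_per,
                                                     rel=1e-6)
        assert fit.vcomp["residual"] == pytest.approx(msw, rel=1e-6)

    def test_fixed_components_give_explicit_gls(self):
        """With variance components pinned at truth, β̂ must equal the
        explicit whitening (GLS) solution computed from V^{-1/2}."""
        spec = CohortSpec(n_subjects=25, sessions_per_subject=2,
                          n_scanners=3, seed=5)
        tab, _ = generate_cohort(spec)
        comp = {"subject": 0.25, "scanner": 0.09, "residual": 1.0}
        fit = fit_lmm(tab, LMMSpec(), fixed_components=comp)

        # oracle: dense V, eigendecomposition whitening, plain OLS
        subj = pd.factorize(tab["subject"])[0]
        scan = pd.factorize(tab["scanner"])[0]
        n = len(tab)
        Zs = np.eye(subj.max() + 1)[subj]
        Zc = np.eye(scan.max() + 1)[scan]
        V = (comp["subject"] * Zs @ Zs.T + comp["scanner"] * Zc @ Zc.T
             + comp["residual"] * np.eye(n))
        w, U = np.linalg.eigh(V)
        W = U @ np.diag(w ** -0.5) @ U.T
        X = np.column_stack([np.ones(n), tab["age_baseline_dec"],
                             tab["interval_dec"], tab["motion_mm"],
                             tab["sex"], tab["rescan"]])
        beta_gls = np.linalg.lstsq(W @ X, W @ tab["sigma"].to_numpy(),
                                   rcond=None)[0]
        got = [fit.beta[t] for t in ("intercept", "baseline", "interval",
                                     "motion", "sex", "rescan")]
        assert np.allclose(got, beta_gls, atol=1e-8)

    def test_crossed_fit_matches_statsmodels(self):
        """Independent cross-check of the crossed-intercepts REML optimum
        against statsmodels' variance-components MixedLM."""
        smf = pytest.importorskip("statsmodels.formula.api")
        spec = CohortSpec(n_subjects=40, sessions_per_subject=3,
                          scans_per_session=2, n_scanners=4, seed=7)
        tab, _ = generate_cohort(spec)
        fit = fit_lmm(tab, LMMSpec())

        tab2 = tab.copy()
        tab2["grp"] = 1
        md = smf.mixedlm(
            "sigma ~ age_baseline_dec + interval_dec + motion_mm + sex + rescan",
            tab2, groups="grp",
            vc_formula={"subject": "0 + C(subject)",
                        "scanner": "0 + C(scanner)"})
        mf = md.fit(reml=True)
        assert fit.beta["interval"] == pytest.approx(
            mf.params["interval_dec"], abs=1e-4)
        assert fit.beta["motion"] == pytest.approx(mf.params["motion_mm"],
                                                   abs=1e-4)
        assert fit.vcomp["residual"] == pytest.approx(mf.scale, rel=1e-3)
        sm_vc = dict(zip(sorted(md.exog_vc.names), mf.vcomp))
        assert fit.vcomp["subject"] == pytest.approx(sm_vc["subject"],
                                                     rel=1e-3)
        assert fit.vcomp["scanner"] == pytest.approx(sm_vc["scanner"],
                                                     rel=1e-3)

    def test_rank_deficient_design_rejected(self):
        tab = one_way_table()
        tab["motion_mm"] = tab["sex"]    # perfectly collinear constants
        with pytest.raises(Exception, match="rank"):
            fit_lmm(tab, LMMSpec(fixed_terms=("motion", "sex")))


class TestTermTests:
    def test_intercept_never_tested(self):
        tab, _ = generate_cohort(CohortSpec(n_subjects=20, seed=1))
        fit = fit_lmm(tab, LMMSpec(fixed_terms=("interval",)))
        assert "intercept" not in test_fixed_terms(fit)

    def test_duplicating_rows_increases_evidence(self):
        spec = CohortSpec(n_subjects=25,
                          beta={"intercept": 0.0, "interval": 0.4},
                          sd_subject=0.3, sd_scanner=0.0, sd_resid=1.0,
                          seed=3)
        tab, _ = generate_cohort(spec)
        mspec = LMMSpec(fixed_terms=("interval",),
                        random_factors=("subject",))
        p1 = test_fixed_terms(fit_lmm(tab, mspec))["interval"]
        doubled = pd.concat([tab, tab], ignore_index=True)
        p2 = test_fixed_terms(fit_lmm(doubled, mspec))["interval"]
        assert p2 < p1

    def test_random_factor_boundary_p_is_one_without_structure(self):
        tab = one_way_table(sd_b=0.0, seed=4)
        p = test_random_factor(tab, LMMSpec(fixed_terms=(),
                                            random_factors=("subject",)),
                               "subject")
        assert p > 0.4    # boundary mixture can never be tiny here


class TestBackwardSelect:
    def test_strong_effects_all_retained(self):
        spec = CohortSpec(n_subjects=150, sessions_per_subject=3,
                          scans_per_session=2, n_scanners=4,
                          beta={"intercept": 0.0, "baseline": 0.5,
                                "interval": 1.0, "motion": 1.0, "sex": 0.8,
                                "rescan": 0.5},
                          sd_subject=0.4, sd_scanner=0.3, sd_resid=0.5,
                          seed=6)
        tab, _ = generate_cohort(spec)
        sel, trace = backward_select(tab, LMMSpec())
        assert set(sel.fixed_terms) == set(LMMSpec().fixed_terms)
        assert set(sel.random_factors) == {"subject", "scanner"}
        assert all(not s.removed for s in trace)

    def test_pure_noise_covariate_usually_removed(self):
        """Backward elimination drops a null covariate in the vast majority
        of replicates at alpha_fixed = 0.05."""
        removed = 0
        n_sim = 60
        for i in range(n_sim):
            spec = CohortSpec(n_subjects=20, sessions_per_subject=2,
                              scans_per_session=2, n_scanners=2,
                              beta={"intercept": 0.0, "interval": 1.0,
                                    "motion": 0.0},
                              sd_subject=0.3, sd_scanner=0.2, sd_resid=0.6,
                              seed=1000 + i)
            tab, _ = generate_cohort(spec)
            sel, _ = backward_select(
                tab, LMMSpec(fixed_terms=("interval", "motion")))
            removed += "motion" not in sel.fixed_terms
        assert removed / n_sim >= 0.85

    def test_no_grouping_columns_skips_random_phase(self):
        tab = one_way_table().drop(columns=["subject", "scanner"])
        sel, trace = backward_select(
            tab, LMMSpec(fixed_terms=(),
                         random_factors=("subject", "scanner")))
        assert sel.random_factors == ()
        assert all(s.phase != "random" for s in trace)


class TestBhFdr:
    def test_hand_examples(self):
        adj, rej = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05], q=0.05)
        assert np.allclose(adj, 0.05)
        assert rej.all()
        adj, rej = bh_fdr([0.005, 0.049, 0.5], q=0.05)
        assert np.allclose(adj, [0.015, 0.0735, 0.5])
        assert list(rej) == [True, False, False]

    def test_single_p_unchanged(self):
        adj, _ = bh_fdr([0.123])
        assert adj[0] == pytest.approx(0.123)

    def test_matches_statsmodels(self):
        multipletests = pytest.importorskip(
            "statsmodels.stats.multitest").multipletests
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 20))
            adj, rej = bh_fdr(p, q=0.05)
            sm_rej, sm_adj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert np.allclose(adj, sm_adj)
            assert np.array_equal(rej, sm_rej)

    def test_adjusted_at_least_raw_and_bounded(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        adj, _ = bh_fdr(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestRegionWise:
    def _cohort(self, rois=("a", "b"), seed=0, **kw):
        spec = CohortSpec(n_subjects=25, sessions_per_subject=2,
                          scans_per_session=2, n_scanners=2, rois=rois,
                          seed=seed, **kw)
        return generate_cohort(spec)[0]

    def test_single_group_reduces_to_one_fit(self):
        tab = self._cohort(rois=("only",))
        res = run_region_wise(tab)
        assert set(res.table["roi"]) == {"only"}
        assert len(res.table) == len(RegionwiseConfig().covariates)

    def test_row_permutation_invariant(self):
        tab = self._cohort()
        res1 = run_region_wise(tab)
        shuffled = tab.sample(frac=1.0, random_state=9).reset_index(drop=True)
        res2 = run_region_wise(shuffled)
        pd.testing.assert_frame_equal(res1.table, res2.table)

    def test_removed_terms_marked_not_zeroed(self):
        tab = self._cohort(beta={"intercept": 0.0, "interval": 1.5},
                           sd_subject=0.2, sd_scanner=0.1, sd_resid=0.5,
                           seed=3)
        res = run_region_wise(tab)
        dropped = res.table[~res.table["retained"]]
        assert len(dropped) > 0
        assert dropped["beta"].isna().all()
        assert dropped["p_adj"].isna().all()

    def test_failures_reported_not_dropped(self):
        tab = self._cohort()
        flat = tab[tab["roi"] == "a"].copy()
        flat["roi"] = "flat"
        flat["sigma"] = 1.0
        combined = pd.concat([tab, flat], ignore_index=True)
        cfg = RegionwiseConfig(standardize=False)
        res = run_region_wise(combined, cfg)
        assert any(f["roi"] == "flat" for f in res.failures) or \
            "flat" in set(res.table["roi"])
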