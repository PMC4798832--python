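import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ncii.lmm import (
    MixedLMM,
    ModelSpec,
    anova_ncii_oracle,
    fit_lmm,
    lrt,
    pairwise_contrasts,
    single_step_adjust,
)
from ncii.simulate import simulate_phenotypes

from conftest import balanced_allocation, quiet_params


def brute_force_mean_squares(y, si, di):
    """Independent mean-square computation by direct summation."""
    ns, nd = si.max() + 1, di.max() + 1
    r = len(y) // (ns * nd)
    grand = y.mean()
    ss_s = ss_d = ss_sd = ss_e = 0.0
    cell = {}
    for s in range(ns):
        for d in range(nd):
            cell[(s, d)] = y[(si == s) & (di == d)].mean()
    for s in range(ns):
        m = y[si == s].mean()
        ss_s += r * nd * (m - grand) ** 2
    for d in range(nd):
        m = y[di == d].mean()
        ss_d += r * ns * (m - grand) ** 2
    for s in range(ns):
        for d in range(nd):
            ss_sd += r * (cell[(s, d)] - y[si == s].mean() - y[di == d].mean() + grand) ** 2
    for i, v in enumerate(y):
        ss_e += (v - cell[(si[i], di[i])]) ** 2
    return (
        ss_s / (ns - 1),
        ss_d / (nd - 1),
        ss_sd / ((ns - 1) * (nd - 1)),
        ss_e / (ns * nd * (r - 1)),
    )


class TestOracle:
    def test_against_brute_force_on_toy_table(self):
        rng = np.random.default_rng(0)
        ns, nd, r = 2, 2, 2
        y = rng.normal(10, 2, ns * nd * r)
        si = np.repeat(np.arange(ns), nd * r)
        di = np.tile(np.repeat(np.arange(nd), r), ns)
        rec = pd.DataFrame({"sire_id": si.astype(str), "dam_id": di.astype(str), "hatch_dd": y})
        ms_s, ms_d, ms_sd, ms_e = brute_force_mean_squares(y, si, di)
        out = anova_ncii_oracle(rec, "hatch_dd")
        assert out["resid"] == pytest.approx(ms_e, rel=1e-10)
        assert out["sire:dam"] == pytest.approx((ms_sd - ms_e) / r, rel=1e-10)
        assert out["sire"] == pytest.approx((ms_s - ms_sd) / (r * nd), rel=1e-10)
        assert out["dam"] == pytest.approx((ms_d - ms_sd) / (r * ns), rel=1e-10)

    def test_residual_only_data(self):
        alloc = balanced_allocation(4, 12, reps=6)
        rec = simulate_phenotypes(alloc, quiet_params(0, 0, 0, 1.0), seed=3)
        out = anova_ncii_oracle(rec, "hatch_dd")
        for term in ("sire", "dam", "sire:dam"):
            # zero-truth estimates fluctuate around 0 (possibly negative);
            # the loosest term (sire:dam) has sampling SD ~ 0.04 here
            assert abs(out[term]) < 0.2
        assert out["resid"] == pytest.approx(1.0, abs=0.1)

    def test_parameter_recovery_large(self):
        alloc = balanced_allocation(8, 40, reps=6)
        rec = simulate_phenotypes(alloc, quiet_params(0.25, 0.25, 0.1, 0.4), seed=4)
        out = anova_ncii_oracle(rec, "hatch_dd")
        assert out["sire"] == pytest.approx(0.25, abs=0.12)
        assert out["dam"] == pytest.approx(0.25, abs=0.3)  # few dam levels
        assert out["sire:dam"] == pytest.approx(0.1, abs=0.05)
        assert out["resid"] == pytest.approx(0.4, abs=0.03)

    def test_unbalanced_rejected(self, study_records):
        with pytest.raises(ValueError, match="balanced"):
            anova_ncii_oracle(study_records, "hatch_dd")


class TestMixedLMM:
    def test_zero_variance_data_hits_boundary_and_matches_ols(self):
        alloc = balanced_allocation(4, 12, reps=6)
        rec = simulate_phenotypes(alloc, quiet_params(0, 0, 0, 1.0), seed=0)
        fit = fit_lmm(rec, ModelSpec("hatch_dd", fixed=()))
        # components collapse to (or near) the zero boundary; the
        # intercept then coincides with the OLS sample mean
        total = sum(fit.sigma2.values())
        assert total < 0.1 * fit.sigma2_resid
        assert len(fit.boundary_terms) >= 1
        assert fit.beta["(Intercept)"] == pytest.approx(rec["hatch_dd"].mean(), abs=0.05)

    def test_matches_oracle_on_balanced_data(self, balanced_records):
        oracle = anova_ncii_oracle(balanced_records, "hatch_dd")
        assert min(oracle.values()) > 0  # interior case
        fit = fit_lmm(balanced_records, ModelSpec("hatch_dd", fixed=()))
        for term in ("sire", "dam", "sire:dam"):
            assert fit.sigma2[term] == pytest.approx(oracle[term], rel=1e-4)
        assert fit.sigma2_resid == pytest.approx(oracle["resid"], rel=1e-4)

    def test_one_way_closed_form(self):
        # balanced one-way layout: REML sigma2_between = (MSB - MSW) / n
        rng = np.random.default_rng(6)
        k, n = 30, 8
        eff = rng.normal(0, 1.0, k)
        y = np.repeat(eff, n) + rng.normal(0, 0.5, k * n)
        rec = pd.DataFrame({
            "sire_id": np.repeat([f"S{i}" for i in range(k)], n),
            "dam_id": "D1", "analysis_group": "control", "hatch_dd": y + 400,
        })
        grp = rec.groupby("sire_id")["hatch_dd"].mean()
        msb = n * grp.var(ddof=1)
        msw = rec.groupby("sire_id")["hatch_dd"].var(ddof=1).mean()
        fit = fit_lmm(rec, ModelSpec("hatch_dd", fixed=(), random=("sire",)))
        assert fit.sigma2["sire"] == pytest.approx((msb - msw) / n, rel=1e-5)
        assert fit.sigma2_resid == pytest.approx(msw, rel=1e-5)

    def test_scale_equivariance(self, balanced_records):
        spec = ModelSpec("hatch_dd", fixed=())
        f1 = fit_lmm(balanced_records, spec)
        scaled = balanced_records.copy()
        c = 3.7
        scaled["hatch_dd"] = scaled["hatch_dd"] * c
        f2 = fit_lmm(scaled, spec)
        for term in f1.sigma2:
            assert f2.sigma2[term] == pytest.approx(c**2 * f1.sigma2[term], rel=1e-3, abs=1e-8)
        assert f2.sigma2_resid == pytest.approx(c**2 * f1.sigma2_resid, rel=1e-4)

    def test_scale_leaves_lrt_unchanged(self, balanced_records):
        spec = ModelSpec("hatch_dd", fixed=())
        c = 5.0
        scaled = balanced_records.copy()
        scaled["hatch_dd"] *= c
        chi = []
        for rec in (balanced_records, scaled):
            full = fit_lmm(rec, spec)
            red = fit_lmm(rec, spec.drop_random("sire:dam"))
            chi.append(lrt(full, red).chi2)
        assert abs(chi[0] - chi[1]) < 1e-6

    def test_loglik_monotone_in_model_size(self, balanced_records):
        spec = ModelSpec("hatch_dd", fixed=())
        full = fit_lmm(balanced_records, spec)
        for drop in ("sire", "dam", "sire:dam"):
            red = fit_lmm(balanced_records, spec.drop_random(drop))
            assert full.loglik >= red.loglik - 1e-6

    def test_optimum_beats_surrounding_grid(self, balanced_records):
        fit = fit_lmm(balanced_records, ModelSpec("hatch_dd", fixed=()))
        g_opt = np.array([fit.sigma2[t] / fit.sigma2_resid for t in fit.spec.random])
        ll_opt = fit._core.profiled(g_opt, "REML")[0]
        for f in (0.7, 0.9, 1.1, 1.4):
            for k in range(3):
                g = g_opt.copy()
                g[k] *= f
                assert fit._core.profiled(g, "REML")[0] <= ll_opt + 1e-8

    def test_sklearn_param_interface(self):
        m = MixedLMM(response="length_mm", method="ML")
        assert m.get_params()["response"] == "length_mm"
        m.set_params(method="REML")
        assert m._spec().method == "REML"

    def test_collinear_fixed_design_named(self, balanced_records):
        # single-group data: treatment dummies are undefined
        with pytest.raises(ValueError, match="analysis groups"):
            fit_lmm(balanced_records, ModelSpec("hatch_dd", fixed=("treatment",)))

    def test_recovery_at_design_scale(self):
        # mean REML estimates over replicates approach the truth
        truth = dict(sire=0.25, dam=0.25, **{"sire:dam": 0.10})
        ests = {t: [] for t in truth}
        resid = []
        n_rep = 30
        for seed in range(n_rep):
            rec = simulate_phenotypes(balanced_allocation(), quiet_params(), seed=1000 + seed)
            fit = fit_lmm(rec, ModelSpec("hatch_dd", fixed=()))
            for t in truth:
                ests[t].append(fit.sigma2[t])
            resid.append(fit.sigma2_resid)
        for t, v in truth.items():
            mean = np.mean(ests[t])
            se = np.std(ests[t], ddof=1) / math.sqrt(n_rep)
            assert abs(mean - v) < max(0.10 * v, 2 * se)
        assert np.mean(resid) == pytest.approx(0.40, rel=0.05)


class TestLRT:
    def _fake_fit(self, loglik, random=("sire", "dam"), fixed=(), method="REML", n_obs=100):
        from ncii.lmm import MixedModelFit

        spec = ModelSpec("hatch_dd", fixed=fixed, random=random, method=method)
        return MixedModelFit(
            spec=spec, beta=pd.Series(dtype=float), se=pd.Series(dtype=float),
            cov_beta=np.empty((0, 0)), sigma2={t: 1.0 for t in random},
            sigma2_resid=1.0, loglik=loglik, n_obs=n_obs, p_fixed=1, converged=True,
        )

    def test_identical_models(self):
        a = self._fake_fit(-50.0)
        res = lrt(a, self._fake_fit(-50.0))
        assert res.chi2 == 0.0 and res.p_value == 1.0 and res.df == 0

    def test_chi2_to_p_mapping(self):
        full = self._fake_fit(-50.0, random=("sire", "dam"))
        red = self._fake_fit(-50.0 - 3.8415 / 2, random=("dam",))
        res = lrt(full, red)
        assert res.df == 1
        assert res.p_value == pytest.approx(0.05, abs=2e-4)
        assert res.p_boundary == pytest.approx(0.025, abs=1e-4)

    def test_non_nested_rejected(self):
        a = self._fake_fit(-50.0, random=("sire",))
        b = self._fake_fit(-51.0, random=("dam",))
        with pytest.raises(ValueError, match="nested"):
            lrt(a, b)

    def test_different_rows_rejected(self):
        a = self._fake_fit(-50.0, n_obs=100)
        b = self._fake_fit(-51.0, random=("dam",), n_obs=90)
        with pytest.raises(ValueError, match="row counts"):
            lrt(a, b)

    def test_null_calibration_small(self):
        # true sire variance 0: naive df=1 test is conservative
        rejections = 0
        n_sim = 60
        for seed in range(n_sim):
            rec = simulate_phenotypes(
                balanced_allocation(4, 12, reps=3),
                quiet_params(0.0, 0.25, 0.1, 0.4), seed=5000 + seed,
            )
            spec = ModelSpec("hatch_dd", fixed=())
            full = fit_lmm(rec, spec)
            red = fit_lmm(rec, spec.drop_random("sire"))
            if lrt(full, red).p_value < 0.05:
                rejections += 1
        # binomial(60, 0.05) upper tail: 8 rejections is p < 1e-2
        assert rejections <= 7


class TestContrasts:
    def test_independence_closed_form(self):
        # two independent contrasts at raw p = 0.05: adjusted ~ 1 - 0.95^2
        z = np.array([stats.norm.isf(0.025), 0.5])
        adj = single_step_adjust(z, np.eye(2), seed=1, n_draws=400_000)
        assert adj[0] == pytest.approx(1 - 0.95**2, abs=0.003)

    def test_pair_count_and_ordering(self, study_records):
        fit = fit_lmm(study_records, ModelSpec("hatch_dd", fixed=("treatment",)))
        res = pairwise_contrasts(fit, n_draws=20_000)
        assert len(res.table) == 21
        assert res.table.loc[0, "group_a"] == "control"
        # antisymmetry: estimate of (a, b) is mean(b) - mean(a)
        gm = res.table.set_index(["group_a", "group_b"])["estimate"]
        assert gm[("control", "agno3_high")] < 0  # earlier hatching under silver

    def test_adjusted_at_least_raw(self, study_records):
        fit = fit_lmm(study_records, ModelSpec("hatch_dd", fixed=("treatment",)))
        res = pairwise_contrasts(fit, n_draws=20_000)
        assert (res.table["p_adjusted"] >= res.table["p_raw"] - 1e-12).all()
        assert res.table["p_adjusted"].between(0, 1).all()

    def test_single_contrast_adjustment_is_identity(self, two_group_records):
        fit = fit_lmm(two_group_records, ModelSpec("hatch_dd", fixed=("treatment",)))
        res = pairwise_contrasts(fit, n_draws=200_000)
        assert len(res.table) == 1
        assert res.table.loc[0, "p_adjusted"] == pytest.approx(
            res.table.loc[0, "p_raw"], abs=0.01
        )

    def test_missing_factor_rejected(self, balanced_records):
        fit = fit_lmm(balanced_records, ModelSpec("hatch_dd", fixed=()))
        with pytest.raises(ValueError, match="treatment"):
            pairwise_contrasts(fit)
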