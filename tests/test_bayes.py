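import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ncii.bayes import (
    ChainSettings,
    GibbsVarianceSampler,
    PriorSpec,
    dic,
    dic_significant,
    gibbs_sample,
    heidelberger_welch,
    hpd_interval,
    posterior_mode,
    _cvm_sf,
)
from ncii.lmm import ModelSpec, fit_lmm
from ncii.simulate import simulate_phenotypes

from conftest import balanced_allocation, quiet_params


def brute_force_hpd(x, prob):
    """Shortest window by exhaustive search over all candidate windows."""
    x = np.sort(np.asarray(x, float))
    n = x.size
    m = int(math.ceil(prob * n))
    best = (np.inf, None)
    for j in range(n - m + 1):
        w = x[j + m - 1] - x[j]
        if w < best[0]:
            best = (w, (x[j], x[j + m - 1]))
    return best[1]


class TestHPD:
    def test_uniform_sequence_tie_break(self):
        iv = hpd_interval(np.arange(1, 101), 0.95)
        assert (iv.lower, iv.upper) == (1, 95)  # first minimal window

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for dist in (rng.gamma(2, 1, 500), rng.normal(0, 1, 301), rng.exponential(1, 123)):
            iv = hpd_interval(dist, 0.9)
            lo, hi = brute_force_hpd(dist, 0.9)
            assert iv.lower == lo and iv.upper == hi

    def test_skewed_hpd_narrower_than_equal_tail(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(0, 1, 2000)
        iv = hpd_interval(x, 0.95)
        lo, hi = np.quantile(x, [0.025, 0.975])
        assert iv.upper - iv.lower <= hi - lo

    def test_point_mass(self):
        iv = hpd_interval(np.full(50, 3.3), 0.95)
        assert iv.lower == iv.upper == 3.3

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(10), 0.95)

    @given(
        a=st.floats(0.1, 5), b=st.floats(-10, 10),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=30, deadline=None)
    def test_affine_equivariance(self, a, b, seed):
        x = np.random.default_rng(seed).gamma(2, 1, 200)
        iv = hpd_interval(x, 0.9)
        iv2 = hpd_interval(a * x + b, 0.9)
        assert iv2.lower == pytest.approx(a * iv.lower + b, rel=1e-9, abs=1e-9)
        assert iv2.upper == pytest.approx(a * iv.upper + b, rel=1e-9, abs=1e-9)


class TestPosteriorMode:
    def test_constant_draws(self):
        assert posterior_mode(np.full(30, 2.5)) == 2.5

    def test_symmetric_sample_mode_near_mean(self):
        x = np.random.default_rng(4).normal(5, 1, 20_000)
        assert posterior_mode(x) == pytest.approx(5.0, abs=0.15)

    def test_unequal_mixture_picks_heavier_component(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 0.5, 7000), rng.normal(5, 0.5, 3000)])
        assert abs(posterior_mode(x) - 0.0) < 0.5


class TestGibbs:
    def _records_for_conjugate(self, n=300, sigma=1.3, seed=6):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "sire_id": "S1", "dam_id": "D1", "analysis_group": "control",
            "hatch_dd": rng.normal(0.0, sigma, n),
        })

    def test_conjugate_residual_posterior(self):
        # known mean 0 (beta pinned by a tiny prior variance): the residual
        # variance posterior is inverse-gamma in closed form
        rec = self._records_for_conjugate()
        y = rec["hatch_dd"].to_numpy()
        nu, V = 0.002, 1.0
        shape = nu / 2 + y.size / 2
        scale = nu * V / 2 + float(y @ y) / 2
        est = GibbsVarianceSampler(
            response="hatch_dd", fixed=(), random=(),
            prior=PriorSpec(nu, V),
            settings=ChainSettings(12_000, 2_000, 1, seed=1),
            beta_prior_var=1e-12,
        ).fit(rec)
        draws = est.chain_.draws["sigma2_resid"].to_numpy()
        analytic_mean = scale / (shape - 1)
        se = draws.std(ddof=1) / math.sqrt(draws.size)  # draws ~ iid here
        assert abs(draws.mean() - analytic_mean) < 3 * se
        # full-distribution agreement
        ks = stats.kstest(draws, stats.invgamma(shape, scale=scale).cdf).statistic
        assert ks < 0.03

    def test_same_seed_identical_chains(self, balanced_records):
        spec = ModelSpec("hatch_dd", fixed=())
        st_ = ChainSettings(2000, 200, 2, seed=9)
        a = gibbs_sample(balanced_records, spec, settings=st_)
        b = gibbs_sample(balanced_records, spec, settings=st_)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_retained_row_count(self, balanced_records):
        st_ = ChainSettings(5000, 500, 3, seed=0)
        ch = gibbs_sample(balanced_records, ModelSpec("hatch_dd", fixed=()), settings=st_)
        assert len(ch.draws) == (5000 - 500) // 3
        assert (ch.draws.filter(like="sigma2") > 0).all().all()

    def test_posterior_means_track_reml_on_large_data(self):
        # big design: enough levels for the posterior to concentrate
        alloc = balanced_allocation(n_dams=10, n_sires=30, reps=6)
        rec = simulate_phenotypes(alloc, quiet_params(), seed=7)
        spec = ModelSpec("hatch_dd", fixed=())
        reml = fit_lmm(rec, spec)
        ch = gibbs_sample(rec, spec, settings=ChainSettings(12_000, 2_000, 5, seed=2))
        for term, col in [("sire", "sigma2_sire"), ("dam", "sigma2_dam"),
                          ("sire:dam", "sigma2_sire:dam")]:
            post = ch.draws[col].mean()
            sd = ch.draws[col].std()
            assert abs(post - reml.sigma2[term]) < max(0.2 * reml.sigma2[term], 2 * sd)
        assert ch.draws["sigma2_resid"].mean() == pytest.approx(reml.sigma2_resid, rel=0.1)

    def test_binary_response_rejected(self, study_records):
        with pytest.raises(ValueError, match="Gaussian"):
            gibbs_sample(study_records, ModelSpec("survived", fixed=()))


class TestDIC:
    def test_identical_chains_not_significant(self, balanced_records):
        spec = ModelSpec("hatch_dd", fixed=())
        ch = gibbs_sample(balanced_records, spec, settings=ChainSettings(3000, 500, 2, seed=3))
        d = dic(ch, balanced_records)
        assert not dic_significant(d, d)
        assert d.dic == pytest.approx(d.mean_deviance + d.effective_params)
        assert d.effective_params > 0

    def test_rule_boundary_inclusive(self):
        assert dic_significant(110.0, 100.0)       # difference exactly 10
        assert not dic_significant(109.9, 100.0)

    def test_smaller_model_preferred_under_its_own_truth(self):
        # data with no sire:dam variance: adding it should not improve DIC by >= 10
        deltas = []
        for seed in range(3):
            rec = simulate_phenotypes(
                balanced_allocation(4, 12, reps=3),
                quiet_params(0.25, 0.25, 0.0, 0.4), seed=800 + seed,
            )
            full_spec = ModelSpec("hatch_dd", fixed=())
            red_spec = full_spec.drop_random("sire:dam")
            st_ = ChainSettings(4000, 800, 2, seed=seed)
            d_full = dic(gibbs_sample(rec, full_spec, settings=st_), rec)
            d_red = dic(gibbs_sample(rec, red_spec, settings=st_), rec)
            deltas.append(d_red.dic - d_full.dic)
        assert sum(1 for d in deltas if d < 10) >= 2

    def test_mismatched_spec_rejected(self, balanced_records):
        spec = ModelSpec("hatch_dd", fixed=())
        ch = gibbs_sample(balanced_records, spec, settings=ChainSettings(1000, 100, 2, seed=4))
        with pytest.raises(ValueError, match="match"):
            dic(ch, balanced_records, spec.drop_random("sire:dam"))


class TestHeidelbergerWelch:
    def test_cvm_tail_critical_values(self):
        # classical asymptotic critical points of the one-sample statistic
        assert _cvm_sf(0.46136) == pytest.approx(0.05, abs=2e-3)
        assert _cvm_sf(0.34730) == pytest.approx(0.10, abs=2e-3)
        assert _cvm_sf(0.74346) == pytest.approx(0.01, abs=1e-3)

    def test_white_noise_passes(self):
        passed = 0
        for seed in range(10):
            x = np.random.default_rng(seed).normal(0, 1, 2000)
            h = heidelberger_welch(x)
            passed += h.stationarity_passed and h.fraction_discarded == 0.0
        assert passed >= 8  # level-0.05 test: occasional false alarms expected

    def test_linear_trend_fails(self):
        # drift of 4 posterior SDs across the chain, clearly nonstationary
        x = np.linspace(0, 4, 2000) + np.random.default_rng(0).normal(0, 1, 2000)
        h = heidelberger_welch(x)
        assert not h.stationarity_passed

    def test_mean_shift_fails(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 1000), rng.normal(2, 1, 1000)])
        assert not heidelberger_welch(x).stationarity_passed

    def test_constant_chain_passes_halfwidth(self):
        h = heidelberger_welch(np.full(500, 7.0))
        assert h.stationarity_passed and h.halfwidth_passed
        assert h.fraction_discarded == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            heidelberger_welch(np.arange(50))
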