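"""Bayesian variance components: Gibbs sampling, HPD, DIC, convergence.

The sampler is the blocked Gibbs scheme for a Gaussian mixed model with
conjugate priors. Location effects (fixed coefficients with a vague normal
prior, random effects with their component variances) are drawn jointly
from their multivariate-normal full conditional; each variance then has a
scaled-inverse-gamma full conditional. The prior on every variance is
"inverse-gamma(nu, V)" in the convention of the animal-model literature,
i.e. inverse-gamma with shape nu/2 and scale nu*V/2 — at the default
(nu = 0.002, V = 1) this is a near-flat prior on the variance. This
parameterization choice matters: the same (nu, V) under a (shape, rate)
reading would be a different prior.

Posterior summaries follow the conventions of the variance-component
literature: highest-posterior-density intervals (shortest window over the
sorted draws), kernel-density posterior modes, conditional-deviance DIC
(deviance evaluated given the location effects, with the effective parameter
count pD = mean deviance minus deviance at the posterior means), and the
Heidelberger-Welch stationarity/halfwidth diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .lmm import ModelSpec, build_design

__all__ = [
    "PriorSpec",
    "ChainSettings",
    "PosteriorChain",
    "HPDInterval",
    "DICResult",
    "HWDiagnostic",
    "GibbsVarianceSampler",
    "gibbs_sample",
    "hpd_interval",
    "posterior_mode",
    "dic",
    "dic_significant",
    "heidelberger_welch",
]

#: DIC differences at or above this value are called significant
DIC_RULE = 10.0


@dataclass(frozen=True)
class PriorSpec:
    """Inverse-gamma (nu, V) prior, applied to every variance component."""

    nu: float = 0.002
    V: float = 1.0

    def __post_init__(self):
        if self.nu <= 0 or self.V <= 0:
            raise ValueError("prior nu and V must be positive")

    @property
    def shape(self) -> float:
        return self.nu / 2.0

    @property
    def scale(self) -> float:
        return self.nu * self.V / 2.0


@dataclass(frozen=True)
class ChainSettings:
    """MCMC run length. Defaults are desk-scale; the source analysis ran
    6-7 million iterations with 100,000 burn-in and thinning 1000, which
    these settings emulate at a fraction of the cost (run length changes
    Monte Carlo error only)."""

    n_iter: int = 50_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorChain:
    """Thinned draws of variance components and fixed effects.

    ``draws`` holds one column per monitored scalar (sigma2_<term>,
    sigma2_resid, fixed-effect names); ``u_draws`` keeps the random-effect
    draws (retained iterations x q) for conditional-deviance DIC.
    """

    draws: pd.DataFrame
    u_draws: np.ndarray
    settings: ChainSettings
    prior: PriorSpec
    spec: ModelSpec
    term_slices: dict[str, slice] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.draws)


def hpd_interval(draws, prob: float = 0.95) -> "HPDInterval":
    """Shortest contiguous interval over the sorted draws holding >= prob mass.

    With n draws the window holds ceil(prob * n) of them; among equal-width
    windows the one with the lowest lower bound is returned.
    """
    x = np.sort(np.asarray(draws, float))
    n = x.size
    if n < 20:
        raise ValueError(f"need >= 20 draws for an HPD interval, got {n}")
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must be in (0, 1)")
    m = int(math.ceil(prob * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    j = int(np.argmin(widths))  # argmin takes the first minimum: lowest lower bound
    return HPDInterval(lower=float(x[j]), upper=float(x[j + m - 1]), prob=prob)


@dataclass(frozen=True)
class HPDInterval:
    lower: float
    upper: float
    prob: float = 0.95


def posterior_mode(draws) -> float:
    """Mode of a Gaussian kernel density (Silverman bandwidth, 512-point grid)."""
    x = np.asarray(draws, float)
    if x.size < 20:
        raise ValueError(f"need >= 20 draws for a posterior mode, got {x.size}")
    if np.ptp(x) == 0.0:
        return float(x[0])
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


class GibbsVarianceSampler(BaseEstimator):
    """Blocked Gibbs sampler for the Gaussian NC II mixed model.

    ``fit`` runs the chain on an embryo-record table and stores the thinned
    draws as ``chain_``. Every draw is strictly positive (the inverse-gamma
    full conditionals are supported on (0, inf)).
    """

    def __init__(
        self,
        response: str = "hatch_dd",
        transform: str = "none",
        fixed: tuple[str, ...] = (),
        random: tuple[str, ...] = ("sire", "dam", "sire:dam"),
        prior: PriorSpec = PriorSpec(),
        settings: ChainSettings = ChainSettings(),
        beta_prior_var: float = 1e8,
    ):
        self.response = response
        self.transform = transform
        self.fixed = fixed
        self.random = random
        self.prior = prior
        self.settings = settings
        self.beta_prior_var = beta_prior_var

    def fit(self, records: pd.DataFrame, y=None) -> "GibbsVarianceSampler":
        spec = ModelSpec(
            response=self.response,
            transform=self.transform,
            fixed=tuple(self.fixed),
            random=tuple(self.random),
            method="ML",
        )
        design = build_design(records, spec)
        st, pr = self.settings, self.prior
        rng = np.random.default_rng(st.seed)
        y = design.y
        n, p, q = design.n, design.p, design.q
        K = len(spec.random)
        sizes = design.block_sizes
        C = np.hstack([design.X, design.Z])
        CtC = C.T @ C
        Cty = C.T @ y
        level_term = np.repeat(np.arange(K), sizes) if K else np.empty(0, int)

        var_y = float(np.var(y)) or 1.0
        s2 = np.full(K, var_y / (K + 1))
        s2_e = var_y / (K + 1)

        n_keep = st.n_retained
        names = [f"sigma2_{t}" for t in spec.random] + ["sigma2_resid"] + design.x_names
        out = np.empty((n_keep, K + 1 + p))
        u_out = np.empty((n_keep, q))
        kept = 0
        prior_prec_beta = 1.0 / self.beta_prior_var

        for it in range(st.n_iter):
            # --- location block: theta | s2, s2_e ~ N(A^-1 b, A^-1) -----
            prec = np.concatenate([np.full(p, prior_prec_beta), np.repeat(1.0 / s2, sizes)])
            A = CtC / s2_e
            A[np.diag_indices_from(A)] += prec
            L = np.linalg.cholesky(A)
            mean = _chol_solve(L, Cty / s2_e)
            z = rng.standard_normal(p + q)
            theta = mean + np.linalg.solve(L.T, z)
            u = theta[p:]
            # --- variances: scaled inverse gamma full conditionals ------
            for k in range(K):
                uk = u[level_term == k]
                shape = pr.shape + uk.size / 2.0
                scale = pr.scale + float(uk @ uk) / 2.0
                s2[k] = scale / rng.gamma(shape)
            r = y - C @ theta
            shape_e = pr.shape + n / 2.0
            scale_e = pr.scale + float(r @ r) / 2.0
            s2_e = scale_e / rng.gamma(shape_e)
            if it >= st.burn_in and (it - st.burn_in) % st.thin == 0:
                out[kept, :K] = s2
                out[kept, K] = s2_e
                out[kept, K + 1 :] = theta[:p]
                u_out[kept] = u
                kept += 1

        draws = pd.DataFrame(out[:kept], columns=names)
        self.chain_ = PosteriorChain(
            draws=draws,
            u_draws=u_out[:kept],
            settings=st,
            prior=pr,
            spec=spec,
            term_slices=design.term_slices,
        )
        self.design_ = design
        return self

    def summary(self, prob: float = 0.95) -> pd.DataFrame:
        """Posterior mode and HPD bounds per variance component."""
        rows = []
        for col in self.chain_.draws.columns:
            if not col.startswith("sigma2"):
                continue
            d = self.chain_.draws[col].to_numpy()
            iv = hpd_interval(d, prob)
            rows.append((col, posterior_mode(d), float(d.mean()), iv.lower, iv.upper))
        return pd.DataFrame(rows, columns=["parameter", "mode", "mean", "lower95", "upper95"])


def gibbs_sample(
    records: pd.DataFrame,
    spec: ModelSpec,
    prior: PriorSpec = PriorSpec(),
    settings: ChainSettings = ChainSettings(),
) -> PosteriorChain:
    """Functional wrapper over :class:`GibbsVarianceSampler`."""
    if spec.response == "survived":
        raise ValueError("Gibbs sampler supports Gaussian responses only")
    est = GibbsVarianceSampler(
        response=spec.response,
        transform=spec.transform,
        fixed=spec.fixed,
        random=spec.random,
        prior=prior,
        settings=settings,
    )
    return est.fit(records).chain_


@dataclass(frozen=True)
class DICResult:
    dic: float
    mean_deviance: float
    effective_params: float


def dic(chain: PosteriorChain, records: pd.DataFrame, spec: ModelSpec | None = None) -> DICResult:
    """Conditional-deviance DIC for a sampled model.

    The deviance of each draw is -2 log N(y | X beta + Z u, s2_e I) at that
    draw's location effects; pD is the mean deviance minus the deviance at
    the posterior means of (beta, u, s2_e). DIC = mean deviance + pD.
    """
    spec = spec or chain.spec
    if tuple(spec.random) != tuple(chain.spec.random) or spec.response != chain.spec.response:
        raise ValueError("spec does not match the sampled chain")
    design = build_design(records, chain.spec)
    y = design.y
    n = y.size
    K = len(chain.spec.random)
    beta = chain.draws[design.x_names].to_numpy()
    s2_e = chain.draws["sigma2_resid"].to_numpy()
    resid = y[:, None] - design.X @ beta.T - design.Z @ chain.u_draws.T
    rss = np.einsum("ij,ij->j", resid, resid)
    devs = n * np.log(2 * math.pi * s2_e) + rss / s2_e
    mean_dev = float(devs.mean())
    r_bar = y - design.X @ beta.mean(axis=0) - design.Z @ chain.u_draws.mean(axis=0)
    s2_bar = float(s2_e.mean())
    dev_bar = n * math.log(2 * math.pi * s2_bar) + float(r_bar @ r_bar) / s2_bar
    pd_eff = mean_dev - dev_bar
    return DICResult(dic=mean_dev + pd_eff, mean_deviance=mean_dev, effective_params=pd_eff)


def dic_significant(dic_a: float | DICResult, dic_b: float | DICResult) -> bool:
    """Model-comparison rule: a DIC difference of >= 10 is significant."""
    a = dic_a.dic if isinstance(dic_a, DICResult) else dic_a
    b = dic_b.dic if isinstance(dic_b, DICResult) else dic_b
    return abs(a - b) >= DIC_RULE


# ---------------------------------------------------------------------------
# Heidelberger-Welch convergence diagnostic


@dataclass(frozen=True)
class HWDiagnostic:
    stationarity_passed: bool
    fraction_discarded: float
    halfwidth_passed: bool
    cvm_statistic: float
    cvm_p: float
    mean: float
    halfwidth: float


def _spectrum0_ar(x: np.ndarray) -> float:
    """Spectral density of the chain at frequency zero, via an AR fit with
    AIC order selection (the classic approach of the coda diagnostics)."""
    n = x.size
    if np.ptp(x) == 0.0:
        return 0.0
    from statsmodels.tsa.ar_model import AutoReg, ar_select_order

    maxlag = min(int(10 * math.log10(n)), n // 2 - 2)
    if maxlag < 1:
        return float(np.var(x, ddof=1))
    try:
        sel = ar_select_order(x, maxlag=maxlag, ic="aic", old_names=False)
        order = len(sel.ar_lags) if sel.ar_lags is not None else 0
        if order == 0:
            return float(np.var(x, ddof=1))
        fit = AutoReg(x, lags=order, old_names=False).fit()
        arc = fit.params[1 : order + 1]
        return float(fit.sigma2 / (1.0 - np.sum(arc)) ** 2)
    except Exception:
        return float(np.var(x, ddof=1))


def _cvm_sf(x: float) -> float:
    """Upper tail of the limiting Cramer-von Mises distribution.

    Bessel-K series for x <= 1.2; beyond that the truncated series loses
    accuracy, so the principal-eigenvalue exponential tail (decay rate
    pi^2/2 per unit statistic) is spliced on continuously.
    """
    if x <= 0:
        return 1.0
    if x > 1.2:
        return 8.426e-4 * math.exp(-(math.pi**2 / 2.0) * (x - 1.2))
    tot = 0.0
    for j in range(6):
        a = (4 * j + 1) ** 2 / (16.0 * x)
        coef = special.gamma(j + 0.5) / (special.gamma(0.5) * special.factorial(j))
        tot += coef * math.sqrt(4 * j + 1) * math.exp(-a) * special.kv(0.25, a)
    cdf = tot / (math.pi * math.sqrt(x))
    return float(min(max(1.0 - cdf, 0.0), 1.0))


def heidelberger_welch(draws, alpha: float = 0.05, eps: float = 0.1) -> HWDiagnostic:
    """Stationarity (Cramer-von Mises on the cumulative-sum process) and
    halfwidth test for a single monitored parameter.

    The initial 10% of the chain is discarded repeatedly (up to 50%) until
    the standardized Brownian-bridge statistic stops rejecting at level
    ``alpha``; the variance normalisation uses the spectral density at zero
    estimated from the second half of the chain. The halfwidth test passes
    when half the 95% interval of the mean is at most ``eps`` times the
    absolute mean (a constant chain passes trivially).
    """
    x = np.asarray(draws, float)
    n = x.size
    if n < 100:
        raise ValueError(f"need >= 100 draws for the diagnostic, got {n}")
    s0 = _spectrum0_ar(x[n // 2 :])
    if s0 == 0.0:  # constant (or second-half-constant degenerate) chain
        return HWDiagnostic(True, 0.0, True, 0.0, 1.0, float(x.mean()), 0.0)

    stat = math.nan
    pval = math.nan
    passed = False
    frac = 0.0
    for i in range(5):  # discard 0%, 10%, ..., 40%; test the remainder
        frac = round(0.1 * i, 1)
        sub = x[int(frac * n) :]
        m = sub.size
        csum = np.cumsum(sub)
        t = np.arange(1, m + 1)
        b = (csum - t * sub.mean()) / math.sqrt(m * s0)
        stat = float(np.sum(b**2) / m)
        pval = _cvm_sf(stat)
        if pval > alpha:
            passed = True
            break
    if not passed:
        frac = 0.5
    keep = x[int(frac * n) :] if passed else x[n // 2 :]
    s0_keep = _spectrum0_ar(keep)
    mean = float(keep.mean())
    hw = 1.96 * math.sqrt(s0_keep / keep.size)
    hw_pass = bool(hw <= eps * abs(mean)) if mean != 0 else bool(hw == 0.0)
    return HWDiagnostic(passed, frac, hw_pass, stat, pval, mean, hw)


def _chol_solve(L: np.ndarray, b: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    return solve_triangular(L.T, solve_triangular(L, b, lower=True), lower=False)
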