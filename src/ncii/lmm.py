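"""Gaussian linear mixed models with crossed random effects.

The variance structure is the NC II workhorse: independent scalar variance
components for each random term (sire, dam, sire x dam, and their crossings
with treatment), so

    y = X beta + sum_k Z_k u_k + e,    u_k ~ N(0, s2_k I),  e ~ N(0, s2_e I).

Estimation maximises the restricted (or full) likelihood profiled over beta
and the residual variance: writing s2_k = gamma_k * s2_e and
H = I + sum_k gamma_k Z_k Z_k', both beta and s2_e have closed forms given
the ratios gamma, leaving a K-dimensional search over log gamma. All the
linear algebra runs through the Woodbury identity on the q x q inner matrix
I + G^{1/2} Z'Z G^{1/2} (q = total number of random levels), which stays
well-conditioned as components approach the zero boundary.

For balanced designs the classical expected-mean-squares estimator is
provided as an independent oracle (`anova_ncii_oracle`); on balanced data
with interior estimates REML coincides with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .design import ANALYSIS_GROUPS

__all__ = [
    "ModelSpec",
    "MixedModelFit",
    "LRTResult",
    "ContrastResult",
    "MixedLMM",
    "fit_lmm",
    "anova_ncii_oracle",
    "lrt",
    "pairwise_contrasts",
]

RANDOM_TERMS = ("sire", "dam", "sire:dam", "sire:treatment", "dam:treatment", "sire:dam:treatment")
FIXED_TERMS = ("treatment", "hatch_dd")

#: components below 1e-8 x var(response) are reported as exact zeros
BOUNDARY_REL_TOL = 1e-8
_LOG_GAMMA_LO, _LOG_GAMMA_HI = -30.0, 10.0


@dataclass(frozen=True)
class ModelSpec:
    """Declarative mixed-model description.

    ``fixed`` lists terms beyond the always-present intercept; ``random``
    draws from the sire/dam vocabulary. ``transform="log"`` is used for
    yolk volume. ``method`` selects REML (default, for variance-component
    inference) or ML (for fixed-effect likelihood-ratio tests).
    """

    response: str
    transform: str = "none"
    fixed: tuple[str, ...] = ("treatment",)
    random: tuple[str, ...] = ("sire", "dam", "sire:dam")
    method: str = "REML"

    def __post_init__(self):
        if self.transform not in ("none", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.method not in ("REML", "ML"):
            raise ValueError(f"method must be REML or ML, got {self.method!r}")
        for t in self.fixed:
            if t not in FIXED_TERMS:
                raise ValueError(f"unknown fixed term {t!r}")
        for t in self.random:
            if t not in RANDOM_TERMS:
                raise ValueError(f"unknown random term {t!r}")
        if len(set(self.random)) != len(self.random):
            raise ValueError("duplicate random terms")
        if len(set(self.fixed)) != len(self.fixed):
            raise ValueError("duplicate fixed terms")

    def drop_random(self, term: str) -> "ModelSpec":
        return replace(self, random=tuple(t for t in self.random if t != term))

    def add_random(self, term: str) -> "ModelSpec":
        return replace(self, random=self.random + (term,))

    def with_method(self, method: str) -> "ModelSpec":
        return replace(self, method=method)


@dataclass
class Design:
    """Numeric design matrices for one model on one record subset."""

    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    Z: np.ndarray  # n x q, columns grouped by term
    term_slices: dict[str, slice]
    term_levels: dict[str, list]
    treatment_levels: list[str]
    hatch_center: float | None
    row_index: pd.Index

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    @property
    def block_sizes(self) -> list[int]:
        return [sl.stop - sl.start for sl in self.term_slices.values()]


def build_design(records: pd.DataFrame, spec: ModelSpec) -> Design:
    """Assemble y, X and Z from an embryo-record table.

    Rows with a missing response (or missing hatching-time covariate, when
    used) are dropped. Treatment is dummy-coded against the control (first
    analysis group present); the hatching-time covariate is centred at its
    sample mean. Random terms become indicator blocks over the observed
    factor levels.
    """
    df = records
    if spec.response not in df.columns:
        raise ValueError(f"response {spec.response!r} not in records")
    keep = df[spec.response].notna()
    if "hatch_dd" in spec.fixed and spec.response != "hatch_dd":
        keep &= df["hatch_dd"].notna()
    df = df.loc[keep]
    if df.empty:
        raise ValueError("no usable rows for this model")
    y = df[spec.response].to_numpy(float)
    if spec.transform == "log":
        if np.any(y <= 0):
            raise ValueError("log transform requires positive response values")
        y = np.log(y)

    cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    present = list(dict.fromkeys(df["analysis_group"]))
    trt_levels = [g for g in ANALYSIS_GROUPS if g in present]
    trt_levels += sorted(g for g in present if g not in trt_levels)
    if "treatment" in spec.fixed:
        if len(trt_levels) < 2:
            raise ValueError("treatment fixed effect needs >= 2 analysis groups")
        for g in trt_levels[1:]:
            cols.append((df["analysis_group"] == g).to_numpy(float))
            names.append(f"treatment[{g}]")
    center = None
    if "hatch_dd" in spec.fixed:
        h = df["hatch_dd"].to_numpy(float)
        center = float(h.mean())
        cols.append(h - center)
        names.append("hatch_dd_c")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the collinearity via QR pivoting
        _, r, piv = _qr_pivot(X)
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"singular fixed-effects design; collinear columns: {bad}")

    z_blocks, slices, levels = [], {}, {}
    start = 0
    for term in spec.random:
        labels = _term_labels(df, term)
        levs, codes = np.unique(labels, return_inverse=True)
        block = np.zeros((len(df), levs.size))
        block[np.arange(len(df)), codes] = 1.0
        z_blocks.append(block)
        slices[term] = slice(start, start + levs.size)
        levels[term] = list(levs)
        start += levs.size
        if levs.size < 2:
            raise ValueError(f"random term {term!r} has fewer than 2 levels")
    Z = np.column_stack(z_blocks) if z_blocks else np.zeros((len(df), 0))
    return Design(y, X, names, Z, slices, levels, trt_levels, center, df.index)


def _term_labels(df: pd.DataFrame, term: str) -> np.ndarray:
    parts = term.split(":")
    colmap = {"sire": "sire_id", "dam": "dam_id", "treatment": "analysis_group"}
    lab = df[colmap[parts[0]]].astype(str)
    for p in parts[1:]:
        lab = lab + "|" + df[colmap[p]].astype(str)
    return lab.to_numpy()


def _qr_pivot(X):
    from scipy.linalg import qr

    q, r, piv = qr(X, pivoting=True, mode="economic")
    return q, r, piv


class _GaussianCore:
    """Profiled (restricted) likelihood for the variance-ratio search.

    Precomputes the cross-product matrices once; each evaluation at a ratio
    vector gamma costs one Cholesky of the q x q inner matrix.
    """

    def __init__(self, design: Design):
        d = design
        self.n, self.p = d.n, d.p
        self.block_sizes = d.block_sizes
        # centre the response: the (restricted) likelihood is invariant
        # because X contains the intercept, and working near zero avoids
        # catastrophic cancellation in the residual quadratic form
        self.ybar = float(d.y.mean())
        y = d.y - self.ybar
        self.ZtZ = d.Z.T @ d.Z
        self.ZtX = d.Z.T @ d.X
        self.Zty = d.Z.T @ y
        self.XtX = d.X.T @ d.X
        self.Xty = d.X.T @ y
        self.yty = float(y @ y)

    def _expand(self, gamma: np.ndarray) -> np.ndarray:
        return np.repeat(np.sqrt(gamma), self.block_sizes)

    def profiled(self, gamma: np.ndarray, method: str):
        """Return (loglik, beta, s2_e, XtHiX_inv) profiled at gamma."""
        g = self._expand(np.asarray(gamma, float))
        q = g.size
        if q:
            M = np.eye(q) + (g[:, None] * self.ZtZ) * g[None, :]
            L = np.linalg.cholesky(M)
            logdetH = 2.0 * float(np.log(np.diag(L)).sum())
            from scipy.linalg import solve_triangular

            W = solve_triangular(L, g[:, None] * self.ZtX, lower=True)
            wy = solve_triangular(L, g * self.Zty, lower=True)
            XtHiX = self.XtX - W.T @ W
            XtHiy = self.Xty - W.T @ wy
            ytHiy = self.yty - float(wy @ wy)
        else:
            logdetH = 0.0
            XtHiX, XtHiy, ytHiy = self.XtX, self.Xty, self.yty
        XtHiX = 0.5 * (XtHiX + XtHiX.T)
        try:
            cf = np.linalg.cholesky(XtHiX)
        except np.linalg.LinAlgError:
            return -np.inf, None, None, None
        beta = np.linalg.solve(XtHiX, XtHiy)
        rHir = max(ytHiy - float(beta @ XtHiy), 1e-300)
        n, p = self.n, self.p
        if method == "REML":
            df = n - p
            s2 = rHir / df
            logdet_xtx = 2.0 * float(np.log(np.diag(cf)).sum())
            ll = -0.5 * (df * math.log(2 * math.pi * s2) + df + logdetH + logdet_xtx)
        else:
            s2 = rHir / n
            ll = -0.5 * (n * math.log(2 * math.pi * s2) + n + logdetH)
        return ll, beta, s2, np.linalg.inv(XtHiX)


@dataclass
class MixedModelFit:
    """A fitted mixed model: estimates plus everything LRTs and contrasts need."""

    spec: ModelSpec
    beta: pd.Series
    se: pd.Series
    cov_beta: np.ndarray
    sigma2: dict[str, float]
    sigma2_resid: float | None
    loglik: float
    n_obs: int
    p_fixed: int
    converged: bool
    boundary_terms: set[str] = field(default_factory=set)
    family: str = "gaussian"
    design: Design | None = None
    _core: object | None = None

    @property
    def n_params(self) -> int:
        """Fixed coefficients + variance parameters (for LRT df bookkeeping)."""
        extra = 1 if self.family == "gaussian" else 0
        return self.p_fixed + len(self.sigma2) + extra

    def profiled_loglik(self, sigma2: dict[str, float], sigma2_resid: float | None = None) -> float:
        """(Restricted) log-likelihood at given variance components.

        If ``sigma2_resid`` is None the residual variance is profiled out
        along with beta, i.e. the value is the profile likelihood at the
        implied variance ratios.
        """
        if self.family != "gaussian" or self._core is None:
            raise ValueError("profiled_loglik is only available for Gaussian fits")
        base = sigma2_resid if sigma2_resid is not None else self.sigma2_resid or 1.0
        gamma = np.array([max(sigma2[t], 0.0) / base for t in self.spec.random])
        ll = self._core.profiled(gamma, self.spec.method)[0]
        if sigma2_resid is None:
            return ll
        # un-profile the residual variance: evaluate at fixed s2_e
        llp, beta, s2_hat, _ = self._core.profiled(gamma, self.spec.method)
        n, p = self._core.n, self._core.p
        df = n - p if self.spec.method == "REML" else n
        # ll(s2) = llp - 0.5*df*(log(s2/s2_hat) + s2_hat/s2 - 1)
        return llp - 0.5 * df * (math.log(base / s2_hat) + s2_hat / base - 1.0)


class MixedLMM(BaseEstimator):
    """Crossed-random-effects Gaussian mixed model (REML or ML).

    Parameters mirror :class:`ModelSpec`; ``fit`` takes an embryo-record
    DataFrame. Fitted attributes carry a trailing underscore; ``result_``
    bundles them as a :class:`MixedModelFit`.

    Examples
    --------
    >>> from ncii import simulate_dataset, MixedLMM
    >>> rec = simulate_dataset(seed=1)
    >>> m = MixedLMM(response="hatch_dd").fit(rec)
    >>> sorted(m.sigma2_)
    ['dam', 'sire', 'sire:dam']
    """

    def __init__(
        self,
        response: str = "hatch_dd",
        transform: str = "none",
        fixed: tuple[str, ...] = ("treatment",),
        random: tuple[str, ...] = ("sire", "dam", "sire:dam"),
        method: str = "REML",
        tol: float = 1e-8,
        max_iter: int = 5000,
    ):
        self.response = response
        self.transform = transform
        self.fixed = fixed
        self.random = random
        self.method = method
        self.tol = tol
        self.max_iter = max_iter

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            response=self.response,
            transform=self.transform,
            fixed=tuple(self.fixed),
            random=tuple(self.random),
            method=self.method,
        )

    def fit(self, records: pd.DataFrame, y=None) -> "MixedLMM":
        spec = self._spec()
        design = build_design(records, spec)
        if design.n < design.p + 2:
            raise ValueError(f"only {design.n} usable rows for {design.p} fixed parameters")
        core = _GaussianCore(design)
        K = len(spec.random)
        var_y = float(np.var(design.y)) or 1.0

        if K == 0:
            ll, beta, s2, xtx_inv = core.profiled(np.empty(0), spec.method)
            converged = True
            gamma_hat = np.empty(0)
        else:
            # deterministic start: equal partition of the response variance
            x0 = np.zeros(K)

            def neg(theta):
                ll = core.profiled(np.exp(theta), spec.method)[0]
                return -ll if np.isfinite(ll) else 1e12

            opts = {
                "xatol": self.tol,
                "fatol": self.tol * 1e-2,
                "maxiter": self.max_iter,
                "maxfev": self.max_iter,
            }
            res = optimize.minimize(
                neg, x0, method="Nelder-Mead",
                bounds=[(_LOG_GAMMA_LO, _LOG_GAMMA_HI)] * K, options=opts,
            )
            # polish with line searches: NM stalls with a collapsed simplex
            # short of the optimum on very flat profiles
            res2 = optimize.minimize(
                neg, res.x, method="Powell",
                bounds=[(_LOG_GAMMA_LO, _LOG_GAMMA_HI)] * K,
                options={"xtol": 1e-10, "ftol": 1e-13, "maxiter": self.max_iter},
            )
            if res2.fun <= res.fun:
                res = res2
            converged = bool(res.success)
            gamma_hat = np.exp(res.x)
            ll, beta, s2, xtx_inv = core.profiled(gamma_hat, spec.method)

        beta = beta.copy()
        beta[design.x_names.index("(Intercept)")] += core.ybar
        cov_beta = s2 * xtx_inv
        sigma2 = {}
        boundary = set()
        floor = BOUNDARY_REL_TOL * var_y
        for k, term in enumerate(spec.random):
            v = float(gamma_hat[k] * s2)
            if v < floor:
                v = 0.0
                boundary.add(term)
            sigma2[term] = v
        beta_s = pd.Series(beta, index=design.x_names)
        se_s = pd.Series(np.sqrt(np.diag(cov_beta)), index=design.x_names)

        self.result_ = MixedModelFit(
            spec=spec,
            beta=beta_s,
            se=se_s,
            cov_beta=cov_beta,
            sigma2=sigma2,
            sigma2_resid=float(s2),
            loglik=float(ll),
            n_obs=design.n,
            p_fixed=design.p,
            converged=converged,
            boundary_terms=boundary,
            design=design,
            _core=core,
        )
        self.beta_ = beta_s
        self.se_ = se_s
        self.sigma2_ = sigma2
        self.sigma2_resid_ = float(s2)
        self.loglik_ = float(ll)
        self.converged_ = converged
        self.boundary_terms_ = boundary
        self.n_obs_ = design.n
        return self

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        """Population-level (fixed-effects-only) predictions on the model scale."""
        fit = self.result_
        d = build_design(records, self.result_.spec.with_method(self.method))
        return d.X @ fit.beta.to_numpy()


def fit_lmm(records: pd.DataFrame, spec: ModelSpec, **kw) -> MixedModelFit:
    """Functional wrapper over :class:`MixedLMM`."""
    est = MixedLMM(
        response=spec.response,
        transform=spec.transform,
        fixed=spec.fixed,
        random=spec.random,
        method=spec.method,
        **kw,
    )
    return est.fit(records).result_


def anova_ncii_oracle(records: pd.DataFrame, trait: str, transform: str = "none") -> dict[str, float]:
    """Expected-mean-squares estimator for a balanced NC II table.

    Requires every sire x dam cell to hold the same number r of non-missing
    responses. Equates observed mean squares to their expectations:

        s2_e  = MS_E
        s2_sd = (MS_SD - MS_E) / r
        s2_s  = (MS_S - MS_SD) / (r * n_dams)
        s2_d  = (MS_D - MS_SD) / (r * n_sires)

    Negative solutions are reported as-is; the oracle never truncates.
    """
    df = records.loc[records[trait].notna(), ["sire_id", "dam_id", trait]]
    y = df[trait].to_numpy(float)
    if transform == "log":
        y = np.log(y)
    sires, si = np.unique(df["sire_id"], return_inverse=True)
    dams, di = np.unique(df["dam_id"], return_inverse=True)
    ns, nd = sires.size, dams.size
    cell = si * nd + di
    counts = np.bincount(cell, minlength=ns * nd)
    if counts.min() != counts.max() or counts.min() == 0:
        raise ValueError("oracle requires a balanced table: equal replicates in every sire x dam cell")
    r = int(counts[0])
    if r < 2:
        raise ValueError("oracle requires >= 2 replicates per cell for a residual mean square")

    grand = y.mean()
    cell_means = np.bincount(cell, weights=y) / r
    cm = cell_means.reshape(ns, nd)
    sire_means = cm.mean(axis=1)
    dam_means = cm.mean(axis=0)

    ss_s = r * nd * np.sum((sire_means - grand) ** 2)
    ss_d = r * ns * np.sum((dam_means - grand) ** 2)
    ss_sd = r * np.sum((cm - sire_means[:, None] - dam_means[None, :] + grand) ** 2)
    ss_e = np.sum((y - cell_means[cell]) ** 2)

    ms_s = ss_s / (ns - 1)
    ms_d = ss_d / (nd - 1)
    ms_sd = ss_sd / ((ns - 1) * (nd - 1))
    ms_e = ss_e / (ns * nd * (r - 1))

    s2_e = ms_e
    s2_sd = (ms_sd - ms_e) / r
    s2_s = (ms_s - ms_sd) / (r * nd)
    s2_d = (ms_d - ms_sd) / (r * ns)
    return {"sire": s2_s, "dam": s2_d, "sire:dam": s2_sd, "resid": s2_e}


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of nested mixed models."""

    chi2: float
    df: int
    p_value: float
    full_loglik: float
    reduced_loglik: float
    method: str
    tested: tuple[str, ...]
    #: 50:50 chi-bar mixture p-value, reported alongside for single
    #: boundary (variance = 0) tests
    p_boundary: float | None = None


def lrt(full: MixedModelFit, reduced: MixedModelFit) -> LRTResult:
    """Compare nested fits; chi2 referenced to a chi-squared distribution.

    Random-term tests must share the fixed structure and estimation flavour;
    the degrees of freedom are the number of dropped parameters (one per
    scalar variance term, one per fixed coefficient). For a single dropped
    variance the conservative naive p is accompanied by the 50:50
    point-mass/chi2(1) boundary mixture.
    """
    fs, rs = full.spec, reduced.spec
    if full.n_obs != reduced.n_obs:
        raise ValueError(f"fits use different row counts ({full.n_obs} vs {reduced.n_obs})")
    if fs.method != rs.method:
        raise ValueError("fits use different estimation flavours")
    if not set(rs.random) <= set(fs.random):
        raise ValueError("reduced random terms are not nested in the full model")
    if not set(rs.fixed) <= set(fs.fixed):
        raise ValueError("reduced fixed terms are not nested in the full model")
    dropped_random = tuple(t for t in fs.random if t not in rs.random)
    dropped_fixed = tuple(t for t in fs.fixed if t not in rs.fixed)
    if dropped_random and dropped_fixed:
        raise ValueError("test either random or fixed terms, not both at once")
    if dropped_random and fs.method == "REML" and fs.fixed != rs.fixed:
        raise ValueError("REML random-term tests require identical fixed effects")
    df = (full.n_params - reduced.n_params) if dropped_fixed else len(dropped_random)
    if df <= 0:
        # identical models
        return LRTResult(0.0, 0, 1.0, full.loglik, reduced.loglik, fs.method, ())
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    p_b = None
    if len(dropped_random) == 1 and not dropped_fixed:
        p_b = 0.5 * float(stats.chi2.sf(chi2, 1)) if chi2 > 0 else 1.0
    return LRTResult(chi2, df, p, full.loglik, reduced.loglik, fs.method, dropped_random or dropped_fixed, p_b)


@dataclass
class ContrastResult:
    """All-pairs treatment contrasts with single-step familywise adjustment."""

    table: pd.DataFrame  # group_a, group_b, estimate, se, z, p_raw, p_adjusted
    seed: int
    n_draws: int

    @property
    def pairs(self):
        return list(zip(self.table["group_a"], self.table["group_b"]))


def single_step_adjust(
    z: np.ndarray, corr: np.ndarray, seed: int = 20260921, n_draws: int = 100_000
) -> np.ndarray:
    """Single-step familywise adjustment of |z| statistics.

    adjusted p_i = P(max_j |Z_j| >= |z_i|) under Z ~ N(0, corr), estimated
    by seeded Monte Carlo. For k independent contrasts this reduces to
    1 - (1 - p_raw)^k.
    """
    z = np.asarray(z, float)
    corr = np.asarray(corr, float)
    rng = np.random.default_rng(seed)
    w, v = np.linalg.eigh(0.5 * (corr + corr.T))
    root = v * np.sqrt(np.clip(w, 0.0, None))
    draws = rng.standard_normal((n_draws, corr.shape[0])) @ root.T
    maxabs = np.abs(draws).max(axis=1)
    return np.array([(maxabs >= abs(zi)).mean() for zi in z])


def pairwise_contrasts(
    fit: MixedModelFit,
    factor: str = "treatment",
    seed: int = 20260921,
    n_draws: int = 100_000,
) -> ContrastResult:
    """All C(g,2) pairwise treatment-mean contrasts from a fitted model.

    Adjusted p-values use the single-step max-|Z| method: under the joint
    normal with the contrast estimators' correlation, the familywise
    adjusted p for contrast i is P(max_j |Z_j| >= |z_i|), estimated by
    seeded Monte Carlo. Pairs are ordered control-first under the declared
    factor ordering.
    """
    if factor != "treatment":
        raise ValueError("only the treatment factor is supported")
    if "treatment" not in fit.spec.fixed:
        raise ValueError("fit has no treatment fixed effect")
    if not fit.converged:
        raise ValueError("fit did not converge; contrasts unavailable")
    levels = fit.design.treatment_levels
    names = fit.beta.index.to_list()
    p = len(names)
    # group-mean coefficient rows: control (reference) has all-zero dummies
    rows = {}
    for g in levels:
        v = np.zeros(p)
        nm = f"treatment[{g}]"
        if nm in names:
            v[names.index(nm)] = 1.0
        rows[g] = v
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    L = np.array([rows[b] - rows[a] for a, b in pairs])
    est = L @ fit.beta.to_numpy()
    cov = L @ fit.cov_beta @ L.T
    se = np.sqrt(np.diag(cov))
    z = est / se
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    corr = cov / np.outer(se, se)
    p_adj = single_step_adjust(z, corr, seed=seed, n_draws=n_draws)
    p_adj = np.maximum(p_adj, p_raw)  # familywise >= per-comparison by construction
    table = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "estimate": est,
            "se": se,
            "z": z,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
        }
    )
    return ContrastResult(table=table, seed=seed, n_draws=n_draws)
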