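"""Binomial-logit mixed models for embryo mortality.

Estimation is a Laplace approximation to the marginal likelihood: for given
variance components the joint mode of (beta, u) is found by penalized
iteratively reweighted least squares (PIRLS), and the marginal log-likelihood
is approximated by the integrand at the mode corrected by the log-determinant
of the conditional curvature. Random effects are reparameterized as
u = sqrt(s2) v with a unit-normal penalty on v, which keeps the algebra
well-behaved as variances reach the zero boundary. The outer search over
log variances reuses the same derivative-free strategy as the Gaussian
engine.

Mortality in the source system is rare (~0.5%) and the data may be degenerate
(all embryos surviving in a subset); such fits are flagged as boundary cases
with finite, clipped estimates rather than raised as errors. The same applies
to complete separation by a fixed effect.
"""

from __future__ import annotations

import math
import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .lmm import MixedModelFit, ModelSpec, build_design

__all__ = ["BinaryLogitGLMM", "fit_glmm_binary"]

#: |eta| cap: logit-scale linear predictors beyond this are numerically
#: saturated probabilities; hitting the cap marks a boundary/separation fit
ETA_CAP = 30.0


def _pirls(y, X, Z, sqrt_s2_levels, max_iter=200, tol=1e-11):
    """Joint penalized Newton for (beta, v) at fixed variance components.

    Returns (beta, v, eta, loglik_at_mode, logdet_curvature, saturated).
    """
    n, p = X.shape
    q = Z.shape[1]
    Zs = Z * sqrt_s2_levels[None, :]
    C = np.hstack([X, Zs])
    theta = np.zeros(p + q)
    pen = np.concatenate([np.zeros(p), np.ones(q)])
    obj_old = -np.inf
    for _ in range(max_iter):
        eta = np.clip(C @ theta, -ETA_CAP, ETA_CAP)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = C.T @ (y - mu) - pen * theta
        H = (C.T * w) @ C + np.diag(pen) + 1e-10 * np.eye(p + q)
        step = np.linalg.solve(H, grad)
        # backtracking on the penalized log-likelihood
        ll = _bernoulli_ll(y, eta) - 0.5 * float(theta[p:] @ theta[p:])
        t = 1.0
        for _ in range(40):
            cand = theta + t * step
            eta_c = np.clip(C @ cand, -ETA_CAP, ETA_CAP)
            ll_c = _bernoulli_ll(y, eta_c) - 0.5 * float(cand[p:] @ cand[p:])
            if ll_c >= ll - 1e-14:
                break
            t *= 0.5
        theta = theta + t * step
        if abs(ll_c - obj_old) < tol * (1.0 + abs(ll_c)):
            obj_old = ll_c
            break
        obj_old = ll_c
    eta = np.clip(C @ theta, -ETA_CAP, ETA_CAP)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    beta, v = theta[:p], theta[p:]
    # Laplace curvature over v only (beta is profiled at the joint mode)
    if q:
        Hv = (Zs.T * w) @ Zs + np.eye(q)
        sign, logdet = np.linalg.slogdet(Hv)
        logdet = float(logdet)
    else:
        logdet = 0.0
    saturated = bool(np.any(np.abs(C @ theta) >= ETA_CAP - 1e-6))
    ll_mode = _bernoulli_ll(y, eta) - 0.5 * float(v @ v)
    return beta, v, eta, ll_mode, logdet, saturated


def _bernoulli_ll(y, eta):
    # log p(y|eta) = y*eta - log(1 + e^eta), stable form
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


class BinaryLogitGLMM(BaseEstimator):
    """Crossed-random-effects logistic mixed model (Laplace approximation).

    The response column must be binary (the survival indicator). Fitted
    attributes mirror :class:`ncii.lmm.MixedLMM`; ``sigma2_resid_`` is None
    (the binomial variance is mean-determined).
    """

    def __init__(
        self,
        response: str = "survived",
        fixed: tuple[str, ...] = ("treatment",),
        random: tuple[str, ...] = ("sire", "dam", "sire:dam"),
        tol: float = 1e-7,
        max_iter: int = 2000,
    ):
        self.response = response
        self.fixed = fixed
        self.random = random
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, records: pd.DataFrame, y=None) -> "BinaryLogitGLMM":
        df = records.copy()
        df[self.response] = df[self.response].astype(float)
        spec = ModelSpec(
            response=self.response,
            fixed=tuple(self.fixed),
            random=tuple(self.random),
            method="ML",
        )
        design = build_design(df, spec)
        yv = design.y
        if not np.isin(yv, (0.0, 1.0)).all():
            raise ValueError("response must be binary (0/1)")
        K = len(spec.random)
        sizes = design.block_sizes

        def laplace_ll(log_s2):
            s2 = np.exp(log_s2)
            sq = np.repeat(np.sqrt(s2), sizes) if K else np.empty(0)
            beta, v, eta, ll_mode, logdet, sat = _pirls(yv, design.X, design.Z, sq)
            return ll_mode - 0.5 * logdet, (beta, v, sat)

        if K == 0:
            ll, (beta, v, sat) = laplace_ll(np.empty(0))
            s2_hat = np.empty(0)
            converged = True
        else:
            def neg(theta):
                val = laplace_ll(theta)[0]
                return -val if np.isfinite(val) else 1e12

            res = optimize.minimize(
                neg,
                np.full(K, math.log(0.1)),
                method="Nelder-Mead",
                bounds=[(-23.0, 6.0)] * K,
                options={"xatol": self.tol, "fatol": self.tol * 1e-2, "maxfev": self.max_iter},
            )
            converged = bool(res.success)
            s2_hat = np.exp(res.x)
            ll, (beta, v, sat) = laplace_ll(res.x)

        boundary = set()
        sigma2 = {}
        for k, term in enumerate(spec.random):
            val = float(s2_hat[k]) if K else 0.0
            if val < 1e-8:
                val = 0.0
                boundary.add(term)
            sigma2[term] = val
        degenerate = yv.min() == yv.max()
        if sat or degenerate:
            boundary.add("(Intercept)")
        # observed-information SEs for beta at the mode (approximate)
        eta = np.clip(
            design.X @ beta
            + (design.Z * (np.repeat(np.sqrt(np.maximum(list(sigma2.values()), 0)), sizes) if K else 0)) @ v,
            -ETA_CAP,
            ETA_CAP,
        )
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-12, None)
        XtWX = (design.X.T * w) @ design.X + 1e-10 * np.eye(design.p)
        cov_beta = np.linalg.inv(XtWX)
        beta_s = pd.Series(beta, index=design.x_names)
        se_s = pd.Series(np.sqrt(np.diag(cov_beta)), index=design.x_names)

        self.result_ = MixedModelFit(
            spec=spec,
            beta=beta_s,
            se=se_s,
            cov_beta=cov_beta,
            sigma2=sigma2,
            sigma2_resid=None,
            loglik=float(ll),
            n_obs=design.n,
            p_fixed=design.p,
            converged=converged,
            boundary_terms=boundary,
            family="binomial",
            design=design,
        )
        self.beta_ = beta_s
        self.se_ = se_s
        self.sigma2_ = sigma2
        self.loglik_ = float(ll)
        self.converged_ = converged
        self.boundary_terms_ = boundary
        self.n_obs_ = design.n
        self.separation_ = sat or degenerate
        return self

    def predict_proba(self, records: pd.DataFrame) -> np.ndarray:
        """Population-level survival probabilities from the fixed effects."""
        d = build_design(records.assign(**{self.response: 0.0}), self.result_.spec)
        eta = np.clip(d.X @ self.beta_.to_numpy(), -ETA_CAP, ETA_CAP)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_glmm_binary(records: pd.DataFrame, spec: ModelSpec, **kw) -> MixedModelFit:
    """Functional wrapper over :class:`BinaryLogitGLMM`."""
    est = BinaryLogitGLMM(response=spec.response, fixed=spec.fixed, random=spec.random, **kw)
    return est.fit(records).result_
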