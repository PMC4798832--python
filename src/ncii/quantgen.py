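"""NC II variance decomposition and narrow-sense heritability.

Under the paternal half-sib covariance structure of a full-factorial NC II
design (and assuming negligible epistasis), the sire variance component
estimates a quarter of the additive genetic variance, so V_A = 4 * s2_sire;
likewise the sire x dam component estimates a quarter of the dominance
variance, V_NA = 4 * s2_sire_dam. The dam component (V_Dam) confounds
maternal environmental and genetic effects and is taken as-is, as is the
residual. Total phenotypic variance is the sum of the four raw components:

    V_P = s2_sire + s2_dam + s2_sire_dam + s2_e,
    h2  = V_A / V_P = 4 * s2_sire / V_P.

Because the numerator inflates a raw component by 4 while the denominator
does not, sampling noise can push h2 above 1 (bounded by 4); that is a
property of the estimator, not an error. The residual component itself
still contains 1/2 V_A and 3/4 of the dominance variance, which is why the
decomposition carries an annotation rather than subtracting them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["VarianceDecomposition", "decompose", "decompose_posterior", "RESIDUAL_NOTE"]

RESIDUAL_NOTE = (
    "V_Res includes environmental variance plus 1/2 V_A and 3/4 of the "
    "dominance variance; it is reported as the raw residual component."
)

_REQUIRED = ("sire", "dam", "sire:dam")


@dataclass(frozen=True)
class VarianceDecomposition:
    """Genetic variance components derived from one mixed-model fit."""

    V_A: float
    V_Dam: float
    V_NA: float
    V_Res: float
    V_P: float
    h2: float
    note: str = RESIDUAL_NOTE

    def as_series(self) -> pd.Series:
        return pd.Series(
            {"V_A": self.V_A, "V_Dam": self.V_Dam, "V_NA": self.V_NA,
             "V_Res": self.V_Res, "V_P": self.V_P, "h2": self.h2}
        )


def decompose(fit_or_components, sigma2_resid: float | None = None) -> VarianceDecomposition:
    """Convert sire/dam/sire:dam/residual components into V_A, V_Dam, V_NA, h2.

    Accepts either a :class:`ncii.lmm.MixedModelFit` or a mapping with keys
    ``sire``, ``dam``, ``sire:dam`` and ``resid`` (or a separate
    ``sigma2_resid``).
    """
    if hasattr(fit_or_components, "sigma2"):
        comp = dict(fit_or_components.sigma2)
        resid = fit_or_components.sigma2_resid
    else:
        comp = dict(fit_or_components)
        resid = comp.pop("resid", sigma2_resid)
    if resid is None:
        raise ValueError("missing residual variance component 'resid'")
    for term in _REQUIRED:
        if term not in comp:
            raise ValueError(f"missing variance component {term!r}")
    s2_s, s2_d, s2_sd = comp["sire"], comp["dam"], comp["sire:dam"]
    for name, v in (("sire", s2_s), ("dam", s2_d), ("sire:dam", s2_sd), ("resid", resid)):
        if v < 0:
            raise ValueError(f"negative variance component {name!r}: {v}")
    v_p = s2_s + s2_d + s2_sd + resid
    v_a = 4.0 * s2_s
    h2 = v_a / v_p if v_p > 0 else 0.0
    return VarianceDecomposition(
        V_A=v_a, V_Dam=s2_d, V_NA=4.0 * s2_sd, V_Res=resid, V_P=v_p, h2=h2
    )


def decompose_posterior(chain) -> pd.DataFrame:
    """Apply the decomposition draw-wise to a posterior chain.

    Parameters
    ----------
    chain : PosteriorChain or DataFrame
        Must carry columns ``sigma2_sire``, ``sigma2_dam``,
        ``sigma2_sire:dam`` and ``sigma2_resid``.

    Returns
    -------
    DataFrame
        One row per retained draw with columns V_A, V_Dam, V_NA, V_Res,
        V_P, h2 — the basis for HPD intervals on V_A and h2.
    """
    draws = chain.draws if hasattr(chain, "draws") else chain
    if len(draws) == 0:
        raise ValueError("empty posterior chain")
    need = ["sigma2_sire", "sigma2_dam", "sigma2_sire:dam", "sigma2_resid"]
    for c in need:
        if c not in draws.columns:
            raise ValueError(f"chain lacks column {c!r}")
    s2s = draws["sigma2_sire"].to_numpy()
    s2d = draws["sigma2_dam"].to_numpy()
    s2sd = draws["sigma2_sire:dam"].to_numpy()
    s2e = draws["sigma2_resid"].to_numpy()
    v_p = s2s + s2d + s2sd + s2e
    out = pd.DataFrame(
        {
            "V_A": 4.0 * s2s,
            "V_Dam": s2d,
            "V_NA": 4.0 * s2sd,
            "V_Res": s2e,
            "V_P": v_p,
            "h2": np.where(v_p > 0, 4.0 * s2s / v_p, 0.0),
        },
        index=draws.index,
    )
    return out
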