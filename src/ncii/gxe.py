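"""Genotype-by-environment analysis.

Two complementary views of G x E across the pollutant treatments:

* random slope-intercept likelihood-ratio tests — does adding a
  sire x treatment (or dam x treatment, or sire x dam x treatment)
  variance component improve the two-group model of control vs one
  treatment? A significant sire x treatment term is additive genetic
  variance for the reaction norm itself.
* cross-environment genetic correlations — Pearson correlations of
  paternal sibgroup means between treatments. The family-mean estimator is
  conservative (attenuated toward zero by within-family sampling noise)
  but bounded in [-1, 1]. Significance is Bonferroni-corrected over all
  treatment pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .design import ANALYSIS_GROUPS
from .lmm import ModelSpec, fit_lmm, lrt

__all__ = [
    "SireMeanMatrix",
    "GeneticCorrelationResult",
    "sire_means",
    "cross_env_correlation",
    "interaction_lrt_suite",
    "INTERACTION_TERMS",
]

INTERACTION_TERMS = ("sire:treatment", "dam:treatment", "sire:dam:treatment")


@dataclass
class SireMeanMatrix:
    """Paternal sibgroup means: sires x analysis groups for one trait."""

    values: pd.DataFrame  # index: sire_id, columns: analysis groups
    counts: pd.DataFrame
    trait: str


def sire_means(records: pd.DataFrame, trait: str) -> SireMeanMatrix:
    """Mean trait value per sire per analysis group.

    Means are taken over surviving, measured offspring only (missing trait
    values are excluded); a sire with no measured offspring in a group
    yields a missing cell. Offspring of all dams are pooled within a sire.
    """
    if trait not in records.columns:
        raise ValueError(f"trait {trait!r} not in records")
    df = records.loc[records[trait].notna()]
    piv = df.pivot_table(index="sire_id", columns="analysis_group", values=trait, aggfunc="mean")
    cnt = df.pivot_table(index="sire_id", columns="analysis_group", values=trait, aggfunc="count")
    order = [g for g in ANALYSIS_GROUPS if g in piv.columns] + [
        g for g in piv.columns if g not in ANALYSIS_GROUPS
    ]
    return SireMeanMatrix(values=piv[order], counts=cnt.reindex(columns=order), trait=trait)


@dataclass
class GeneticCorrelationResult:
    """Cross-environment correlation matrix of paternal sibgroup means."""

    corr: pd.DataFrame
    raw_p: pd.DataFrame
    n: pd.DataFrame  # pairwise-complete sire counts
    n_pairs: int
    bonferroni_alpha: float
    significant: pd.DataFrame
    trait: str

    def pair_table(self) -> pd.DataFrame:
        """Tidy upper-triangle listing (group_a, group_b, r, p, n, significant)."""
        rows = []
        groups = list(self.corr.columns)
        for a, b in combinations(groups, 2):
            rows.append(
                (a, b, self.corr.loc[a, b], self.raw_p.loc[a, b], self.n.loc[a, b],
                 bool(self.significant.loc[a, b]))
            )
        return pd.DataFrame(rows, columns=["group_a", "group_b", "r", "p", "n", "significant"])


def cross_env_correlation(means: SireMeanMatrix, alpha: float = 0.05) -> GeneticCorrelationResult:
    """Pairwise-complete Pearson correlations between treatment columns.

    Each pair uses the sires with observed means in both groups; two-sided
    p-values come from the t transform with n - 2 df. The familywise level
    ``alpha`` is Bonferroni-split over all C(g, 2) pairs (seven groups give
    21 pairs and a threshold of 0.05/21 ~ 0.002); pairs with fewer than 3
    complete sires yield a missing cell with a warning, not an error.
    """
    v = means.values
    groups = list(v.columns)
    g = len(groups)
    n_pairs = g * (g - 1) // 2
    bonf = alpha / n_pairs if n_pairs else alpha
    corr = pd.DataFrame(np.eye(g), index=groups, columns=groups)
    raw_p = pd.DataFrame(np.nan, index=groups, columns=groups)
    nmat = pd.DataFrame(0, index=groups, columns=groups)
    for a, b in combinations(groups, 2):
        ok = v[a].notna() & v[b].notna()
        n = int(ok.sum())
        nmat.loc[a, b] = nmat.loc[b, a] = n
        if n < 3:
            warnings.warn(
                f"fewer than 3 complete sire pairs for ({a}, {b}); correlation left missing"
            )
            corr.loc[a, b] = corr.loc[b, a] = np.nan
            continue
        r, p = stats.pearsonr(v.loc[ok, a], v.loc[ok, b])
        corr.loc[a, b] = corr.loc[b, a] = float(r)
        raw_p.loc[a, b] = raw_p.loc[b, a] = float(p)
    sig = raw_p < bonf
    return GeneticCorrelationResult(
        corr=corr, raw_p=raw_p, n=nmat, n_pairs=n_pairs,
        bonferroni_alpha=bonf, significant=sig, trait=means.trait,
    )


def interaction_lrt_suite(
    records: pd.DataFrame,
    trait: str,
    control_group: str = "control",
    test_group: str | None = None,
    transform: str = "none",
    extra_fixed: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Random slope-intercept LRTs on a control-vs-one-treatment subset.

    The base REML model holds sire, dam and sire x dam intercepts with
    treatment (and any ``extra_fixed``, e.g. the hatching-time covariate)
    as fixed effects. Each interaction term — sire x treatment,
    dam x treatment, sire x dam x treatment — is added in turn and tested
    against the base by a likelihood-ratio test (one scalar variance
    parameter per term, so df = 1).

    Returns a tidy table: trait, comparison, term, chi2, df, p, p_boundary.
    """
    groups = set(records["analysis_group"])
    if test_group is None:
        present = [g for g in groups if g != control_group]
        if len(present) != 1:
            raise ValueError("subset must contain exactly two analysis groups, or pass test_group")
        test_group = present[0]
    sub = records[records["analysis_group"].isin([control_group, test_group])]
    if sub["analysis_group"].nunique() != 2:
        raise ValueError(
            f"need both {control_group!r} and {test_group!r} present in the records"
        )
    base_spec = ModelSpec(
        response=trait,
        transform=transform,
        fixed=("treatment",) + tuple(extra_fixed),
        random=("sire", "dam", "sire:dam"),
        method="REML",
    )
    base = fit_lmm(sub, base_spec)
    rows = []
    for term in INTERACTION_TERMS:
        full = fit_lmm(sub, base_spec.add_random(term))
        res = lrt(full, base)
        rows.append(
            {
                "trait": trait,
                "comparison": f"{control_group} vs {test_group}",
                "term": term,
                "chi2": res.chi2,
                "df": res.df,
                "p": res.p_value,
                "p_boundary": res.p_boundary,
            }
        )
    return pd.DataFrame(rows)
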