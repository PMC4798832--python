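"""End-to-end orchestration of the NC II stress-tolerance analysis.

A single call reproduces the full analysis chain on simulated or loaded
records: control pooling, the mortality GLMM, treatment effects on hatching
time and the size traits (with multiplicity-adjusted contrasts), the
per-treatment variance decompositions with Bayesian HPD intervals, posterior
modes, DIC model comparisons and convergence diagnostics, the random
slope-intercept interaction tests of control against each silver treatment,
and the cross-environment sire-mean correlations. Every stage logs to
standard error and lands in the :class:`ResultBundle`; numeric tables are
emitted even when estimates sit on the zero boundary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .bayes import (
    ChainSettings,
    PriorSpec,
    dic,
    dic_significant,
    gibbs_sample,
    heidelberger_welch,
    hpd_interval,
    posterior_mode,
)
from .design import ANALYSIS_GROUPS, TreatmentScheme
from .glmm import fit_glmm_binary
from .gxe import cross_env_correlation, interaction_lrt_suite, sire_means
from .lmm import ModelSpec, fit_lmm, lrt, pairwise_contrasts
from .quantgen import decompose, decompose_posterior
from .simulate import SimulationParams, params_to_dict, read_records, simulate_dataset, validate_records

__all__ = [
    "AnalysisConfig",
    "ResultBundle",
    "run_full_analysis",
    "summarize_treatment_means",
    "mortality_summary",
    "TRAIT_MODELS",
]

log = logging.getLogger("ncii")

#: trait -> (transform, uses hatching-time covariate)
TRAIT_MODELS = {
    "hatch_dd": ("none", False),
    "length_mm": ("none", True),
    "yolk_vol_mm3": ("log", True),
}


@dataclass
class AnalysisConfig:
    """Run configuration; exactly one input mode (simulate or load)."""

    mode: str = "simulate"
    input_path: str | None = None
    n_dams: int = 4
    n_sires: int = 12
    reps_min: int = 5
    reps_max: int = 7
    sim_params: SimulationParams = field(default_factory=SimulationParams)
    chain: ChainSettings = field(default_factory=lambda: ChainSettings(20_000, 2_000, 10))
    prior: PriorSpec = field(default_factory=PriorSpec)
    run_bayes: bool = True
    run_dic_ladder: bool = True
    contrast_draws: int = 100_000
    seed: int = 0
    out_dir: str | None = None
    verbosity: str = "INFO"

    def __post_init__(self):
        if self.mode not in ("simulate", "load"):
            raise ValueError("mode must be 'simulate' or 'load'")
        if self.mode == "load" and not self.input_path:
            raise ValueError("mode 'load' requires input_path")
        if self.mode == "simulate" and self.input_path:
            raise ValueError("input_path is only valid with mode 'load'")
        if self.reps_min < 1:
            raise ValueError("reps_min must be >= 1 (every family needs replicates)")

    def digest(self) -> str:
        d = asdict(self)
        d["sim_params"] = params_to_dict(self.sim_params)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    """Everything the analysis produces, plus run metadata."""

    records: pd.DataFrame
    mortality: dict
    treatment_means: dict[str, pd.DataFrame]
    fixed_effect_lrts: pd.DataFrame
    contrasts: dict[str, pd.DataFrame]
    random_effect_lrts: pd.DataFrame
    decompositions: pd.DataFrame
    posterior_summaries: pd.DataFrame
    hw_diagnostics: pd.DataFrame
    dic_table: pd.DataFrame
    interaction_lrts: pd.DataFrame
    correlations: dict[str, pd.DataFrame]
    metadata: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "fixed_effect_lrts": self.fixed_effect_lrts,
            "random_effect_lrts": self.random_effect_lrts,
            "decompositions": self.decompositions,
            "posterior_summaries": self.posterior_summaries,
            "hw_diagnostics": self.hw_diagnostics,
            "dic_table": self.dic_table,
            "interaction_lrts": self.interaction_lrts,
        }
        for trait, df in self.treatment_means.items():
            out[f"means_{trait}"] = df
        for trait, df in self.contrasts.items():
            out[f"contrasts_{trait}"] = df
        for trait, df in self.correlations.items():
            out[f"correlations_{trait}"] = df
        return out

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", index=False)
        for name, df in self.tables().items():
            df.to_csv(out / f"{name}.csv", index=name.startswith("correlations"))
        meta = dict(self.metadata)
        meta["mortality"] = self.mortality
        (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str))


def summarize_treatment_means(records: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Per analysis group: mean, standard error and count of non-missing values."""
    if trait not in records.columns:
        raise ValueError(f"trait {trait!r} not in records")
    df = records.loc[records[trait].notna()]
    rows = []
    present = set(df["analysis_group"])
    for g in [g for g in ANALYSIS_GROUPS if g in set(records["analysis_group"])]:
        if g not in present:
            log.warning("no measured %s values in group %s; row left missing", trait, g)
            rows.append((g, np.nan, np.nan, 0))
            continue
        vals = df.loc[df["analysis_group"] == g, trait].to_numpy()
        se = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
        rows.append((g, float(vals.mean()), float(se), int(vals.size)))
    return pd.DataFrame(rows, columns=["analysis_group", "mean", "se", "n"])


def mortality_summary(records: pd.DataFrame) -> dict:
    """Deaths, total and percent mortality (one decimal)."""
    if len(records) == 0:
        raise ValueError("no records")
    total = int(len(records))
    deaths = int((~records["survived"].astype(bool)).sum())
    return {"deaths": deaths, "total": total, "percent": round(100.0 * deaths / total, 1)}


def _stage(name):
    log.info("stage: %s", name)
    return time.time()


def run_full_analysis(config: AnalysisConfig) -> ResultBundle:
    """Run the complete pipeline; deterministic given ``config.seed``."""
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    t0 = time.time()
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(8)]
    stage = "setup"
    try:
        # ---- data ------------------------------------------------------
        stage = "data"
        _stage(stage)
        if config.mode == "simulate":
            records = simulate_dataset(
                n_dams=config.n_dams,
                n_sires=config.n_sires,
                reps_min=config.reps_min,
                reps_max=config.reps_max,
                params=config.sim_params,
                seed=seeds[0],
            )
        else:
            records = read_records(config.input_path)
            scheme = TreatmentScheme()
            records["analysis_group"] = records["raw_group"].map(scheme.pooling_map)
        validate_records(records)
        mort = mortality_summary(records)
        log.info("records: %d embryos, %d families, mortality %.1f%%",
                 len(records), records.groupby(["sire_id", "dam_id"]).ngroups, mort["percent"])

        # ---- mortality GLMM ---------------------------------------------
        stage = "mortality_glmm"
        _stage(stage)
        g_full = fit_glmm_binary(records, ModelSpec(response="survived", fixed=("treatment",)))
        g_red = fit_glmm_binary(records, ModelSpec(response="survived", fixed=()))
        g_lrt = lrt(g_full, g_red)
        mort.update({"lrt_chi2": g_lrt.chi2, "lrt_df": g_lrt.df, "lrt_p": g_lrt.p_value,
                     "glmm_boundary": sorted(g_full.boundary_terms)})

        # ---- treatment effects per trait --------------------------------
        stage = "treatment_effects"
        _stage(stage)
        means = {}
        contrasts = {}
        fixed_rows = [{"trait": "survived", "term": "treatment", "chi2": g_lrt.chi2,
                       "df": g_lrt.df, "p": g_lrt.p_value}]
        for trait, (transform, with_cov) in TRAIT_MODELS.items():
            means[trait] = summarize_treatment_means(records, trait)
            fixed = ("treatment", "hatch_dd") if with_cov else ("treatment",)
            ml_spec = ModelSpec(trait, transform, fixed, method="ML")
            full_ml = fit_lmm(records, ml_spec)
            red_ml = fit_lmm(records, ModelSpec(trait, transform,
                                                tuple(t for t in fixed if t != "treatment"),
                                                method="ML"))
            res = lrt(full_ml, red_ml)
            fixed_rows.append({"trait": trait, "term": "treatment", "chi2": res.chi2,
                               "df": res.df, "p": res.p_value})
            if with_cov:
                red_cov = fit_lmm(records, ModelSpec(trait, transform, ("treatment",), method="ML"))
                res_c = lrt(full_ml, red_cov)
                fixed_rows.append({"trait": trait, "term": "hatch_dd", "chi2": res_c.chi2,
                                   "df": res_c.df, "p": res_c.p_value})
            reml_fit = fit_lmm(records, ModelSpec(trait, transform, fixed, method="REML"))
            contrasts[trait] = pairwise_contrasts(
                reml_fit, seed=seeds[1], n_draws=config.contrast_draws
            ).table
        fixed_lrts = pd.DataFrame(fixed_rows)

        # ---- per-treatment variance models ------------------------------
        stage = "variance_models"
        _stage(stage)
        rand_rows, dec_rows = [], []
        group_fits = {}
        groups = [g for g in ANALYSIS_GROUPS if g in set(records["analysis_group"])]
        for trait, (transform, with_cov) in TRAIT_MODELS.items():
            fixed = ("hatch_dd",) if with_cov else ()
            for g in groups:
                sub = records[records["analysis_group"] == g]
                spec = ModelSpec(trait, transform, fixed, ("sire", "dam", "sire:dam"), "REML")
                full = fit_lmm(sub, spec)
                ref = fit_lmm(sub, spec.drop_random("sire:dam"))
                no_sire = fit_lmm(sub, ModelSpec(trait, transform, fixed, ("dam",), "REML"))
                no_dam = fit_lmm(sub, ModelSpec(trait, transform, fixed, ("sire",), "REML"))
                for term, a, b in (("sire:dam", full, ref), ("sire", ref, no_sire), ("dam", ref, no_dam)):
                    r = lrt(a, b)
                    rand_rows.append({"trait": trait, "group": g, "term": term, "chi2": r.chi2,
                                      "df": r.df, "p": r.p_value, "p_boundary": r.p_boundary})
                dec = decompose(full)
                row = {"trait": trait, "group": g, **dec.as_series().to_dict(),
                       "boundary_terms": ";".join(sorted(full.boundary_terms))}
                dec_rows.append(row)
                group_fits[(trait, g)] = (sub, spec, full)
        random_lrts = pd.DataFrame(rand_rows)
        decomps = pd.DataFrame(dec_rows)

        # ---- Bayesian summaries -----------------------------------------
        stage = "bayesian"
        _stage(stage)
        post_rows, hw_rows, dic_rows = [], [], []
        if config.run_bayes:
            chain_seed = seeds[2]
            for idx, ((trait, g), (sub, spec, _)) in enumerate(group_fits.items()):
                st = ChainSettings(config.chain.n_iter, config.chain.burn_in,
                                   config.chain.thin, (chain_seed + idx) % 2**31)
                chain = gibbs_sample(sub, spec, prior=config.prior, settings=st)
                post = decompose_posterior(chain)
                for par in post.columns:
                    d = post[par].to_numpy()
                    iv = hpd_interval(d, 0.95)
                    post_rows.append({"trait": trait, "group": g, "parameter": par,
                                      "mode": posterior_mode(d), "mean": float(d.mean()),
                                      "lower95": iv.lower, "upper95": iv.upper})
                for par in ("sigma2_sire", "sigma2_dam", "sigma2_sire:dam", "sigma2_resid"):
                    h = heidelberger_welch(chain.draws[par].to_numpy())
                    hw_rows.append({"trait": trait, "group": g, "parameter": par,
                                    "stationarity_passed": h.stationarity_passed,
                                    "fraction_discarded": h.fraction_discarded,
                                    "halfwidth_passed": h.halfwidth_passed,
                                    "cvm_statistic": h.cvm_statistic})
                if config.run_dic_ladder:
                    full_dic = dic(chain, sub)
                    dic_rows.append({"trait": trait, "group": g, "model": "full",
                                     "dic": full_dic.dic, "pD": full_dic.effective_params,
                                     "delta_vs_full": 0.0, "significant": False})
                    for drop in ("sire", "dam", "sire:dam"):
                        sp = spec.drop_random(drop)
                        st_d = ChainSettings(st.n_iter, st.burn_in, st.thin, (st.seed + 7919) % 2**31)
                        ch_d = gibbs_sample(sub, sp, prior=config.prior, settings=st_d)
                        d_d = dic(ch_d, sub)
                        dic_rows.append({"trait": trait, "group": g, "model": f"no_{drop}",
                                         "dic": d_d.dic, "pD": d_d.effective_params,
                                         "delta_vs_full": d_d.dic - full_dic.dic,
                                         "significant": dic_significant(d_d, full_dic)})
        post_df = pd.DataFrame(post_rows)
        hw_df = pd.DataFrame(hw_rows)
        dic_df = pd.DataFrame(dic_rows)

        # ---- interaction (G x E) suites ---------------------------------
        stage = "interaction_lrts"
        _stage(stage)
        inter = []
        for trait, (transform, with_cov) in TRAIT_MODELS.items():
            extra = ("hatch_dd",) if with_cov else ()
            for g in groups:
                if g == "control":
                    continue
                inter.append(interaction_lrt_suite(records, trait, "control", g,
                                                   transform=transform, extra_fixed=extra))
        inter_df = pd.concat(inter, ignore_index=True) if inter else pd.DataFrame()

        # ---- cross-environment correlations -----------------------------
        stage = "correlations"
        _stage(stage)
        corrs = {}
        corr_results = {}
        for trait in TRAIT_MODELS:
            res = cross_env_correlation(sire_means(records, trait))
            corr_results[trait] = res
            corrs[trait] = res.corr
        stage = "finalize"
        meta = {
            "seed": config.seed,
            "config_hash": config.digest(),
            "ncii_version": __version__,
            "python": platform.python_version(),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "runtime_s": round(time.time() - t0, 2),
            "n_records": len(records),
            "analysis_groups": groups,
            "bonferroni_alpha": {t: r.bonferroni_alpha for t, r in corr_results.items()},
        }
        bundle = ResultBundle(
            records=records,
            mortality=mort,
            treatment_means=means,
            fixed_effect_lrts=fixed_lrts,
            contrasts=contrasts,
            random_effect_lrts=random_lrts,
            decompositions=decomps,
            posterior_summaries=post_df,
            hw_diagnostics=hw_df,
            dic_table=dic_df,
            interaction_lrts=inter_df,
            correlations=corrs,
            metadata=meta,
        )
        bundle.correlation_results = corr_results
        if config.out_dir:
            bundle.save(config.out_dir)
        log.info("done in %.1f s", time.time() - t0)
        return bundle
    except Exception as exc:
        if config.out_dir:
            from pathlib import Path

            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "INCOMPLETE").write_text(f"failed at stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
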