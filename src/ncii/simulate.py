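"""Synthetic phenotypes for the NC II factorial under pollutant stress.

The generator mirrors the statistical structure the downstream mixed models
assume: for each Gaussian trait

    y = mu + tau[group] + s_i + d_j + (sd)_ij + e,

with independent zero-mean normal sire, dam, sire x dam and residual effects.
Sire effects are drawn jointly across analysis groups with a cross-environment
correlation matrix R_G, so the strength of genotype-by-environment interaction
is a single dial: R_G of all ones means every sire reacts identically to every
treatment (no G x E); R_G = I means sire rankings reshuffle freely between
environments. Larval length and log yolk volume additionally depend linearly
on centred hatching time (earlier-hatching larvae are smaller but carry more
yolk). Survival is Bernoulli on the logit scale; dead embryos carry no trait
values; size traits are observed only on a random measurement subset per
analysis group, as in the source experiment.

Hatching time is kept on the degree-day (DD) scale throughout: constant
6.5 degC incubation means DD = 6.5 x days post-fertilization, and treatments
started at 240.5 DD, so any observed hatch must exceed that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import ANALYSIS_GROUPS, TreatmentScheme, allocate_embryos, make_design

__all__ = [
    "TraitParams",
    "SimulationParams",
    "compute_yolk_volume",
    "simulate_phenotypes",
    "simulate_dataset",
    "validate_records",
    "write_records",
    "read_records",
    "TREATMENT_START_DD",
    "TRAIT_COLUMNS",
]

TREATMENT_START_DD = 240.5
DEGREES_PER_DAY = 6.5

#: trait columns of the record table, in canonical order
TRAIT_COLUMNS = ("hatch_dd", "length_mm", "yolk_len_mm", "yolk_width_mm", "yolk_vol_mm3")

RECORD_COLUMNS = (
    "sire_id",
    "dam_id",
    "raw_group",
    "analysis_group",
    "replicate",
    "survived",
) + TRAIT_COLUMNS

#: default prolate-spheroid coefficient, V = (pi/6) L W^2
SPHEROID_COEFF = math.pi / 6.0


@dataclass
class TraitParams:
    """Generative parameters for one Gaussian trait.

    ``treatment_effects`` maps analysis-group label -> fixed effect relative
    to the grand mean (control = 0); variance components are in squared trait
    units. ``rho_g`` is the cross-environment correlation of a sire's effects
    (scalar compound symmetry, or a full g x g matrix via ``r_g``).
    """

    mean: float
    s2_sire: float
    s2_dam: float
    s2_sire_dam: float
    s2_resid: float
    treatment_effects: dict[str, float] = field(default_factory=dict)
    rho_g: float = 1.0
    r_g: np.ndarray | None = None

    def variance_components(self) -> dict[str, float]:
        return {
            "sire": self.s2_sire,
            "dam": self.s2_dam,
            "sire:dam": self.s2_sire_dam,
            "resid": self.s2_resid,
        }

    def validate(self, groups: tuple[str, ...]) -> None:
        # effects for groups absent from the allocation are simply unused
        for name, v in self.variance_components().items():
            if v < 0:
                raise ValueError(f"negative variance component {name}: {v}")

    def correlation_matrix(self, n_groups: int) -> np.ndarray:
        """Cross-environment sire-effect correlation, validated PSD."""
        if self.r_g is not None:
            r = np.asarray(self.r_g, float)
        else:
            r = np.full((n_groups, n_groups), self.rho_g)
            np.fill_diagonal(r, 1.0)
        if r.shape != (n_groups, n_groups):
            raise ValueError(f"R_G must be {n_groups}x{n_groups}, got {r.shape}")
        if not np.allclose(r, r.T):
            raise ValueError("R_G must be symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("R_G must have unit diagonal")
        w = np.linalg.eigvalsh(r)
        if w.min() < -1e-8:
            raise ValueError(f"R_G is not positive semidefinite (min eigenvalue {w.min():.3g})")
        return r


def _default_hatch() -> TraitParams:
    # h2 = 4*20/(20+25+5+50) = 0.8; high-dose ionic silver accelerates
    # hatching most, high-dose nanoparticles less, low doses hardly at all.
    return TraitParams(
        mean=360.0,
        s2_sire=20.0,
        s2_dam=25.0,
        s2_sire_dam=5.0,
        s2_resid=50.0,
        treatment_effects={
            "agno3_low": -0.5,
            "agno3_high": -25.0,
            "agnp20_low": -4.0,
            "agnp20_high": -10.0,
            "agnp100_low": -4.0,
            "agnp100_high": -8.0,
        },
        rho_g=0.95,
    )


def _default_length() -> TraitParams:
    # dam-dominated, little additive variance; treatment effects ~ 0
    return TraitParams(
        mean=12.0,
        s2_sire=0.005,
        s2_dam=0.08,
        s2_sire_dam=0.005,
        s2_resid=0.15,
        treatment_effects={},
        rho_g=0.95,
    )


def _default_log_yolk() -> TraitParams:
    # log mm^3 scale; high-dose ionic silver leaves larger yolk sacs
    return TraitParams(
        mean=0.47,
        s2_sire=0.002,
        s2_dam=0.03,
        s2_sire_dam=0.002,
        s2_resid=0.06,
        treatment_effects={"agno3_high": 0.08},
        rho_g=0.95,
    )


@dataclass
class SimulationParams:
    """Full generative configuration; defaults are synthetic.

    The defaults reproduce the qualitative pattern of the study system —
    heritability near 0.8 for hatching time, dam-dominated variance for the
    size traits, earlier hatching and larger yolk under high-dose AgNO3,
    near-unity cross-environment genetic correlation, rare (0.5%) mortality —
    but are not estimates from any real data set.
    """

    hatch: TraitParams = field(default_factory=_default_hatch)
    length: TraitParams = field(default_factory=_default_length)
    log_yolk: TraitParams = field(default_factory=_default_log_yolk)
    #: mm of larval length per degree-day of hatching delay (positive:
    #: later hatchers are longer)
    slope_length: float = 0.010
    #: log yolk volume per degree-day (negative: later hatchers have
    #: consumed more yolk)
    slope_log_yolk: float = -0.004
    p_mort: float = 0.005
    #: logit-scale mortality random-effect variances (default 0: observed
    #: mortality was rare and treatment-independent)
    mort_s2_sire: float = 0.0
    mort_s2_dam: float = 0.0
    mort_s2_sire_dam: float = 0.0
    #: fraction of survivors per analysis group measured for size traits
    measure_fraction: float = 0.12
    #: yolk sac length/width aspect ratio (prolate spheroid, L >= W)
    yolk_aspect: float = 1.35
    yolk_coeff: float = SPHEROID_COEFF
    rng_seed: int = 0

    def validate(self, groups: tuple[str, ...] = ANALYSIS_GROUPS) -> None:
        if not 0.0 <= self.p_mort <= 1.0:
            raise ValueError(f"p_mort must be in [0, 1], got {self.p_mort}")
        if not 0.0 <= self.measure_fraction <= 1.0:
            raise ValueError("measure_fraction must be in [0, 1]")
        for v in (self.mort_s2_sire, self.mort_s2_dam, self.mort_s2_sire_dam):
            if v < 0:
                raise ValueError("mortality random-effect variances must be >= 0")
        if self.yolk_aspect <= 0 or self.yolk_coeff <= 0:
            raise ValueError("yolk_aspect and yolk_coeff must be positive")
        for t in (self.hatch, self.length, self.log_yolk):
            t.validate(groups)


def compute_yolk_volume(
    yolk_len_mm: float | np.ndarray,
    yolk_width_mm: float | np.ndarray,
    coeff: float = SPHEROID_COEFF,
) -> float | np.ndarray:
    """Yolk sac volume from its two measured axes.

    Models the yolk sac as a prolate spheroid: V = (pi/6) * L * W^2, the
    standard formula for salmonid yolk sacs. The coefficient is configurable
    to accommodate alternative conventions. Arguments are not symmetric: the
    width enters squared.
    """
    L = np.asarray(yolk_len_mm, float)
    W = np.asarray(yolk_width_mm, float)
    if np.any(L <= 0) or np.any(W <= 0):
        raise ValueError("yolk dimensions must be positive")
    out = coeff * L * W**2
    return float(out) if out.ndim == 0 else out


def _correlated_sire_effects(
    rng: np.random.Generator, n_sires: int, s2: float, r: np.ndarray
) -> np.ndarray:
    """n_sires x n_groups matrix of sire effects with Cov = s2 * R."""
    if s2 == 0.0:
        return np.zeros((n_sires, r.shape[0]))
    # eigen square root: R may be singular (e.g. all-ones, perfect correlation)
    w, v = np.linalg.eigh(r)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    z = rng.standard_normal((n_sires, r.shape[0]))
    return math.sqrt(s2) * z @ root.T


def simulate_phenotypes(
    allocation: pd.DataFrame,
    params: SimulationParams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate survival and trait values for an embryo allocation table.

    Parameters
    ----------
    allocation : DataFrame
        Output of :func:`ncii.design.allocate_embryos` (columns sire_id,
        dam_id, raw_group, analysis_group, replicate).
    params : SimulationParams
        Generative configuration; defaults are the synthetic study
        conditions.
    seed : int, optional
        Overrides ``params.rng_seed``. All randomness flows from one
        seeded generator.

    Returns
    -------
    DataFrame
        One validated embryo record per allocation row.
    """
    if params is None:
        params = SimulationParams()
    groups = tuple(dict.fromkeys(allocation["analysis_group"]))
    params.validate(groups)
    rng = np.random.default_rng(params.rng_seed if seed is None else seed)

    sires = sorted(allocation["sire_id"].unique())
    dams = sorted(allocation["dam_id"].unique())
    si = allocation["sire_id"].map({s: i for i, s in enumerate(sires)}).to_numpy()
    di = allocation["dam_id"].map({d: i for i, d in enumerate(dams)}).to_numpy()
    gi = allocation["analysis_group"].map({g: i for i, g in enumerate(groups)}).to_numpy()
    n = len(allocation)
    ns, nd, ng = len(sires), len(dams), len(groups)

    # ---- survival -------------------------------------------------------
    eta = np.full(n, _logit(1.0 - params.p_mort))
    for s2, idx, nlev in (
        (params.mort_s2_sire, si, ns),
        (params.mort_s2_dam, di, nd),
        (params.mort_s2_sire_dam, si * nd + di, ns * nd),
    ):
        if s2 > 0:
            eta += rng.normal(0.0, math.sqrt(s2), nlev)[idx]
    survived = rng.random(n) < _expit(eta)

    def draw_trait(tp: TraitParams) -> np.ndarray:
        r = tp.correlation_matrix(ng)
        s_eff = _correlated_sire_effects(rng, ns, tp.s2_sire, r)
        d_eff = rng.normal(0.0, math.sqrt(tp.s2_dam), nd) if tp.s2_dam > 0 else np.zeros(nd)
        sd_eff = (
            rng.normal(0.0, math.sqrt(tp.s2_sire_dam), (ns, nd))
            if tp.s2_sire_dam > 0
            else np.zeros((ns, nd))
        )
        e = rng.normal(0.0, math.sqrt(tp.s2_resid), n) if tp.s2_resid > 0 else np.zeros(n)
        tau = np.array([tp.treatment_effects.get(g, 0.0) for g in groups])
        return tp.mean + tau[gi] + s_eff[si, gi] + d_eff[di] + sd_eff[si, di] + e

    hatch = draw_trait(params.hatch)
    hatch[~survived] = np.nan
    hatch_c = hatch - np.nanmean(hatch)

    length = draw_trait(params.length) + params.slope_length * np.where(np.isnan(hatch_c), 0.0, hatch_c)
    log_yolk = draw_trait(params.log_yolk) + params.slope_log_yolk * np.where(
        np.isnan(hatch_c), 0.0, hatch_c
    )

    # measurement subset: a random fraction of survivors per analysis group
    measured = np.zeros(n, bool)
    for g in range(ng):
        pool = np.flatnonzero(survived & (gi == g))
        k = int(round(params.measure_fraction * pool.size))
        if k > 0:
            measured[rng.choice(pool, size=k, replace=False)] = True

    length = np.where(measured, length, np.nan)
    log_yolk = np.where(measured, log_yolk, np.nan)
    yolk_vol = np.exp(log_yolk)
    # back out the two measured axes from volume and a noisy aspect ratio,
    # so records stay exactly consistent with the declared volume formula
    aspect = params.yolk_aspect * np.exp(rng.normal(0.0, 0.05, n))
    width = np.cbrt(yolk_vol / (params.yolk_coeff * aspect))
    ylen = aspect * width

    records = allocation.copy()
    records["survived"] = survived
    records["hatch_dd"] = hatch
    records["length_mm"] = length
    records["yolk_len_mm"] = ylen
    records["yolk_width_mm"] = width
    records["yolk_vol_mm3"] = yolk_vol
    validate_records(records, yolk_coeff=params.yolk_coeff)
    return records


def simulate_dataset(
    n_dams: int = 4,
    n_sires: int = 12,
    reps_min: int = 5,
    reps_max: int = 7,
    params: SimulationParams | None = None,
    seed: int = 0,
    scheme: TreatmentScheme | None = None,
) -> pd.DataFrame:
    """Design + allocation + phenotypes in one call (study scale by default)."""
    design = make_design(n_dams, n_sires)
    scheme = scheme or TreatmentScheme()
    rng = np.random.default_rng(seed)
    alloc = allocate_embryos(design, scheme, reps_min, reps_max, seed=rng)
    return simulate_phenotypes(alloc, params=params, seed=int(rng.integers(2**31)))


def validate_records(records: pd.DataFrame, yolk_coeff: float = SPHEROID_COEFF) -> None:
    """Check the embryo-record invariants; raise ValueError naming rows.

    Invariants: required columns present; dead embryos carry no trait
    values; observed hatch_dd exceeds the 240.5 DD treatment start;
    yolk volume is positive and consistent with its axes under the
    declared spheroid formula.
    """
    missing_cols = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing_cols:
        raise ValueError(f"records missing columns: {missing_cols}")
    dead = ~records["survived"].astype(bool)
    for col in TRAIT_COLUMNS:
        bad = records.index[dead & records[col].notna()]
        if len(bad):
            raise ValueError(f"dead embryos with non-missing {col} at rows {list(bad[:5])}")
    h = records["hatch_dd"]
    bad = records.index[h.notna() & (h <= TREATMENT_START_DD)]
    if len(bad):
        raise ValueError(
            f"hatch_dd <= {TREATMENT_START_DD} DD (treatment start) at rows {list(bad[:5])}"
        )
    v = records["yolk_vol_mm3"]
    bad = records.index[v.notna() & (v <= 0)]
    if len(bad):
        raise ValueError(f"non-positive yolk volume at rows {list(bad[:5])}")
    both = v.notna() & records["yolk_len_mm"].notna() & records["yolk_width_mm"].notna()
    if both.any():
        expect = yolk_coeff * records.loc[both, "yolk_len_mm"] * records.loc[both, "yolk_width_mm"] ** 2
        rel = np.abs(expect - records.loc[both, "yolk_vol_mm3"]) / expect
        bad = rel.index[rel > 1e-6]
        if len(bad):
            raise ValueError(f"yolk volume inconsistent with axes at rows {list(bad[:5])}")


def write_records(records: pd.DataFrame, path) -> None:
    """Write records as UTF-8 CSV with a header row; empty cell = missing."""
    validate_records(records)
    records.to_csv(path, index=False)


def read_records(path, validate: bool = True) -> pd.DataFrame:
    """Read an embryo-record CSV, restoring missing values and dtypes."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"cannot parse record file {path}: {exc}") from exc
    missing_cols = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"record file {path} missing columns: {missing_cols}")
    if df["survived"].dtype == object:
        df["survived"] = df["survived"].map({"True": True, "False": False})
        if df["survived"].isna().any():
            row = int(df.index[df["survived"].isna()][0])
            raise ValueError(f"unparseable 'survived' value at row {row}")
    df["survived"] = df["survived"].astype(bool)
    for col in TRAIT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="raise")
    if validate:
        validate_records(df)
    return df


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p)) if 0.0 < p < 1.0 else (math.inf if p >= 1 else -math.inf)


def _expit(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def params_to_dict(params: SimulationParams) -> dict:
    """JSON/YAML-serialisable view of SimulationParams."""
    d = asdict(params)
    for t in ("hatch", "length", "log_yolk"):
        if d[t]["r_g"] is not None:
            d[t]["r_g"] = np.asarray(d[t]["r_g"]).tolist()
    return d


def params_from_dict(d: dict) -> SimulationParams:
    """Inverse of :func:`params_to_dict`; unknown keys rejected."""
    d = dict(d)
    traits = {}
    for t in ("hatch", "length", "log_yolk"):
        if t in d:
            td = dict(d.pop(t))
            if td.get("r_g") is not None:
                td["r_g"] = np.asarray(td["r_g"], float)
            traits[t] = TraitParams(**td)
    return SimulationParams(**traits, **d)
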