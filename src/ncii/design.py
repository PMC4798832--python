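"""North Carolina II crossing design and treatment allocation.

A North Carolina II (NC II) design crosses every sire with every dam in a
full factorial, so that phenotypic variance can later be split into sire
(additive), dam (maternal + genetic), and sire x dam (dominance) components.
This module builds the family list, the treatment scheme (an untreated
control, two dispersant controls, and six silver exposures that are pooled
to seven analysis groups), and the per-family replicate allocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CrossDesign",
    "TreatmentScheme",
    "make_design",
    "allocate_embryos",
]

#: raw experimental groups: untreated control, two sodium-citrate dispersant
#: controls, and ionic / nanoparticulate silver at low (0.5 ug/L) and high
#: (100 ug/L) dose.
RAW_GROUPS = (
    "control",
    "citrate_low",
    "citrate_high",
    "agno3_low",
    "agno3_high",
    "agnp20_low",
    "agnp20_high",
    "agnp100_low",
    "agnp100_high",
)

#: analysis groups after pooling the three controls, control first.
ANALYSIS_GROUPS = (
    "control",
    "agno3_low",
    "agno3_high",
    "agnp20_low",
    "agnp20_high",
    "agnp100_low",
    "agnp100_high",
)

DOSE_LOW_UG_L = 0.5
DOSE_HIGH_UG_L = 100.0


@dataclass(frozen=True)
class CrossDesign:
    """Full-factorial sire x dam crossing design.

    ``families`` enumerates every (sire_id, dam_id) pair exactly once,
    ordered dams-outer / sires-inner.
    """

    dam_ids: tuple[str, ...]
    sire_ids: tuple[str, ...]
    families: tuple[tuple[str, str], ...]

    @property
    def n_families(self) -> int:
        return len(self.families)

    def __post_init__(self) -> None:
        expected = len(self.dam_ids) * len(self.sire_ids)
        if len(self.families) != expected:
            raise ValueError(
                f"families has {len(self.families)} entries, expected "
                f"{expected} for a full factorial"
            )
        if len(set(self.families)) != len(self.families):
            raise ValueError("families contains duplicate sire x dam pairs")


@dataclass(frozen=True)
class TreatmentScheme:
    """Raw treatment groups and their pooling into analysis groups.

    The untreated control and both citrate dispersant controls pool into a
    single "control" analysis group; the pooling map is the identity on the
    six silver treatments.
    """

    raw_groups: tuple[str, ...] = RAW_GROUPS
    analysis_groups: tuple[str, ...] = ANALYSIS_GROUPS
    pooling_map: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_POOLING))
    dose_low: float = DOSE_LOW_UG_L
    dose_high: float = DOSE_HIGH_UG_L

    def __post_init__(self) -> None:
        targets = set(self.pooling_map.values())
        if targets != set(self.analysis_groups):
            raise ValueError("pooling_map targets do not match analysis_groups")
        if set(self.pooling_map) != set(self.raw_groups):
            raise ValueError("pooling_map keys do not match raw_groups")

    def pool(self, raw_group: str) -> str:
        return self.pooling_map[raw_group]


_DEFAULT_POOLING = tuple(
    (g, "control" if g in ("control", "citrate_low", "citrate_high") else g)
    for g in RAW_GROUPS
)


def make_design(n_dams: int, n_sires: int) -> CrossDesign:
    """Build the full-factorial NC II design.

    Parameters
    ----------
    n_dams, n_sires : int
        Number of dams and sires; every sire is crossed with every dam.
        The source experiment used 4 dams x 12 sires = 48 full-sib families.

    Returns
    -------
    CrossDesign
        Families ordered dams-outer, sires-inner (D1xS01, D1xS02, ...).
    """
    if n_dams < 1 or n_sires < 1:
        raise ValueError(f"n_dams and n_sires must be >= 1, got {n_dams}, {n_sires}")
    dam_ids = tuple(f"D{i + 1}" for i in range(n_dams))
    sire_ids = tuple(f"S{i + 1:02d}" for i in range(n_sires))
    families = tuple((s, d) for d in dam_ids for s in sire_ids)
    return CrossDesign(dam_ids=dam_ids, sire_ids=sire_ids, families=families)


def allocate_embryos(
    design: CrossDesign,
    scheme: TreatmentScheme,
    reps_min: int = 5,
    reps_max: int = 7,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Assign embryos to family x raw-group x replicate cells.

    Replicate counts are drawn independently and uniformly from
    ``[reps_min, reps_max]`` per family x raw-group cell (the experiment
    used five to seven replicates per full-sib family per treatment,
    depending on embryo availability).

    Returns
    -------
    DataFrame
        One row per embryo with columns ``sire_id, dam_id, raw_group,
        analysis_group, replicate``. Reproducible given ``seed``.
    """
    if design.n_families == 0:
        raise ValueError("design has no families")
    if not (1 <= reps_min <= reps_max):
        raise ValueError(f"need 1 <= reps_min <= reps_max, got {reps_min}, {reps_max}")
    rng = np.random.default_rng(seed)
    rows = []
    for sire, dam in design.families:
        for raw in scheme.raw_groups:
            n_rep = int(rng.integers(reps_min, reps_max + 1))
            for rep in range(1, n_rep + 1):
                rows.append((sire, dam, raw, scheme.pool(raw), rep))
    return pd.DataFrame(
        rows, columns=["sire_id", "dam_id", "raw_group", "analysis_group", "replicate"]
    )
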