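"""Hybrid ranking: base index, yield reduction, terciles, breeding efficiency.

The multiple-trait base index combines z-standardised low-N entry means as

    MI = 2*Z_GY + Z_EPP - Z_ASI - Z_PASP - Z_EASP - Z_STGR

(grain yield and ears per plant rewarded, anthesis-silking interval,
plant/ear aspect scores and stay-green penalised), positive values marking
low-N tolerant hybrids.

Breeding efficiency asks whether marker-derived heterotic groups predict
hybrid performance: hybrids are ranked by yield and split into three
equal terciles, every cross is classed inter- or intra-group from its
parents' marker groups, and

    BE = ( [HYINTERGH / TNINTERGH * 100] + [LYINTRAGH / TNINTRAGH * 100] ) / 2

with HYINTERGH the inter-group crosses in the top tercile, LYINTRAGH the
intra-group crosses in the bottom tercile, and TN* the class totals.  A
cross with a "mixed"-group parent shares no single assigned group with
its mate and therefore counts as inter-group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .simulate import MIXED_LABEL

#: Index weights in the order the traits enter MI.
MI_WEIGHTS = {"GY": 2.0, "EPP": 1.0, "ASI": -1.0, "PASP": -1.0, "EASP": -1.0, "STGR": -1.0}
MI_TRAITS = tuple(MI_WEIGHTS)


def multiple_trait_index(means: pd.DataFrame) -> pd.DataFrame:
    """Base index from per-hybrid low-N entry means.

    Parameters
    ----------
    means
        One row per hybrid (the index), one column per trait in
        ``MI_TRAITS``.  Traits are z-standardised over the hybrid panel
        (sample SD) before weighting.

    Returns
    -------
    DataFrame with the standardised columns ``Z_<trait>`` and ``MI``,
    sorted by MI descending.
    """
    missing = [t for t in MI_TRAITS if t not in means.columns]
    if missing:
        raise ValueError(f"means table lacks MI traits: {missing}")
    out = pd.DataFrame(index=means.index)
    mi = np.zeros(len(means))
    for trait in MI_TRAITS:
        col = means[trait].astype(float)
        sd = col.std(ddof=1)
        if not sd > 0:
            raise ValueError(f"trait {trait!r} has zero variance across hybrids")
        z = (col - col.mean()) / sd
        out[f"Z_{trait}"] = z
        mi += MI_WEIGHTS[trait] * z.to_numpy()
    out["MI"] = mi
    return out.sort_values("MI", ascending=False)


def yield_reduction(y_optimal: float, y_low_n: float) -> float:
    """Percent yield reduction under stress: 100 * (opt - low) / opt."""
    if not y_optimal > 0:
        raise ValueError(f"optimal yield must be positive, got {y_optimal}")
    return 100.0 * (y_optimal - y_low_n) / y_optimal


def yield_terciles(yields: pd.Series) -> pd.Series:
    """Rank hybrids by yield and split into three equal groups 1/2/3.

    Group 1 is the top third.  The hybrid count must be divisible by 3;
    ties are broken by stable input order with a warning.
    """
    n = len(yields)
    if n == 0 or n % 3 != 0:
        near = 3 * max(1, round(n / 3))
        raise ValueError(
            f"hybrid count {n} is not divisible by 3; nearest valid design is {near}"
        )
    if yields.duplicated().any():
        warnings.warn("tied yields resolved by stable input order", stacklevel=2)
    order = yields.sort_values(ascending=False, kind="stable").index
    third = n // 3
    groups = pd.Series(index=yields.index, dtype=int, name="yield_group")
    groups.loc[order[:third]] = 1
    groups.loc[order[third : 2 * third]] = 2
    groups.loc[order[2 * third :]] = 3
    return groups


def classify_crosses(
    parents: pd.DataFrame, groups: Mapping[str, str]
) -> pd.Series:
    """Label each hybrid inter- or intra-group from its parents' groups.

    ``parents`` must have ``male`` and ``female`` columns; ``groups`` maps
    every parent to an assigned group label or ``"mixed"``.  A cross is
    intra-group only when both parents carry the same non-mixed label.
    """
    for col in ("male", "female"):
        if col not in parents.columns:
            raise ValueError(f"parents table lacks column {col!r}")
    out = []
    for _, row in parents.iterrows():
        for p in (row["male"], row["female"]):
            if p not in groups:
                raise KeyError(f"parent {p!r} has no group label")
        gm, gf = groups[row["male"]], groups[row["female"]]
        intra = gm == gf and gm != MIXED_LABEL
        out.append("intra" if intra else "inter")
    return pd.Series(out, index=parents.index, name="cross_type")


@dataclass
class BreedingEfficiencyResult:
    """Tercile x cross-type counts and the breeding-efficiency percentage."""

    hy_intergh: int  # high-yielding (tercile 1) inter-group hybrids
    tn_intergh: int  # all inter-group hybrids
    ly_intragh: int  # low-yielding (tercile 3) intra-group hybrids
    tn_intragh: int  # all intra-group hybrids
    be: float  # percent
    table: pd.DataFrame  # counts per (yield_group, cross_type)

    def recompute(self) -> float:
        return (
            100.0 * self.hy_intergh / self.tn_intergh
            + 100.0 * self.ly_intragh / self.tn_intragh
        ) / 2.0


def breeding_efficiency(
    terciles: pd.Series, cross_types: pd.Series
) -> BreedingEfficiencyResult:
    """Breeding efficiency from aligned tercile and cross-type labels."""
    if not terciles.index.equals(cross_types.index):
        cross_types = cross_types.reindex(terciles.index)
        if cross_types.isna().any():
            raise ValueError("terciles and cross_types must cover the same hybrids")
    tn_inter = int((cross_types == "inter").sum())
    tn_intra = int((cross_types == "intra").sum())
    if tn_inter == 0 or tn_intra == 0:
        raise ValueError(
            "breeding efficiency undefined: need both inter- and intra-group crosses"
        )
    hy_inter = int(((cross_types == "inter") & (terciles == 1)).sum())
    ly_intra = int(((cross_types == "intra") & (terciles == 3)).sum())
    be = (100.0 * hy_inter / tn_inter + 100.0 * ly_intra / tn_intra) / 2.0
    table = (
        pd.crosstab(terciles, cross_types)
        .reindex(index=[1, 2, 3], columns=["inter", "intra"], fill_value=0)
        .rename_axis(index="yield_group", columns="cross_type")
    )
    return BreedingEfficiencyResult(
        hy_intergh=hy_inter,
        tn_intergh=tn_inter,
        ly_intragh=ly_intra,
        tn_intragh=tn_intra,
        be=be,
        table=table,
    )


def breeding_efficiency_from_counts(
    inter_per_tercile: tuple[int, int, int],
    intra_per_tercile: tuple[int, int, int],
) -> BreedingEfficiencyResult:
    """Breeding efficiency from per-tercile inter/intra cross counts.

    Convenience entry point for published count tables: expands the counts
    into per-hybrid labels and delegates to :func:`breeding_efficiency`.
    """
    terc, kinds = [], []
    for grp, (n_inter, n_intra) in enumerate(
        zip(inter_per_tercile, intra_per_tercile), start=1
    ):
        terc += [grp] * (n_inter + n_intra)
        kinds += ["inter"] * n_inter + ["intra"] * n_intra
    idx = pd.RangeIndex(len(terc))
    return breeding_efficiency(
        pd.Series(terc, index=idx, name="yield_group"),
        pd.Series(kinds, index=idx, name="cross_type"),
    )
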