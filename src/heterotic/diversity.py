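"""Per-marker and panel-level SNP diversity statistics.

For a biallelic locus with alternative-allele frequency p (q = 1 - p over
non-missing calls):

* major allele frequency  = max(p, q)
* gene diversity (expected heterozygosity)  D = 1 - p^2 - q^2
* polymorphic information content (Botstein form, two alleles)
  PIC = 1 - p^2 - q^2 - 2 p^2 q^2
* observed heterozygosity = fraction of heterozygous calls

No small-sample correction is applied to gene diversity: the plain
1 - sum(p^2) is the statistic conventionally reported for such panels and
is capped at exactly 0.5 for two alleles, which the corrected form can
exceed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import MISSING, GenotypeMatrix

#: Markers whose observed heterozygosity falls below this are counted as
#: identifying "homozygous individuals" in the panel summary.
HOMOZYGOUS_HET_CUTOFF = 0.05


def gene_diversity(p: float | np.ndarray) -> float | np.ndarray:
    q = 1.0 - np.asarray(p, dtype=float)
    return 1.0 - np.square(p) - np.square(q)


def pic(p: float | np.ndarray) -> float | np.ndarray:
    """Botstein polymorphic information content for a biallelic locus."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    return 1.0 - p**2 - q**2 - 2.0 * p**2 * q**2


def marker_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker statistics; requires every marker to have >= 1 call."""
    obs = g.calls != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        bad = [g.marker_ids[j] for j in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"markers with all calls missing (filter first): {bad}")
    p = g.alt_freq()
    q = 1.0 - p
    return pd.DataFrame(
        {
            "marker_id": g.marker_ids,
            "major_allele_freq": np.maximum(p, q),
            "gene_diversity": gene_diversity(p),
            "pic": pic(p),
            "observed_het": (g.calls == 1).sum(axis=0) / n_obs,
            "call_rate": g.call_rate(),
        }
    )


@dataclass
class PanelSummary:
    """Min/mean/max of each statistic plus panel heterozygosity bookkeeping."""

    table: pd.DataFrame  # rows: statistics, columns: min/mean/max
    mean_heterozygosity: float
    homozygous_marker_fraction: float  # share of markers with obs het < cutoff

    def __post_init__(self) -> None:
        t = self.table
        if not ((t["min"] <= t["mean"] + 1e-12) & (t["mean"] <= t["max"] + 1e-12)).all():
            raise ValueError("summary must satisfy min <= mean <= max")


def panel_summary(stats: pd.DataFrame) -> PanelSummary:
    """Summarise marker statistics over the retained panel."""
    if len(stats) == 0:
        raise ValueError("cannot summarise an empty marker list")
    cols = ["major_allele_freq", "gene_diversity", "pic", "observed_het"]
    table = pd.DataFrame(
        {
            "min": stats[cols].min(),
            "mean": stats[cols].mean(),
            "max": stats[cols].max(),
        }
    )
    return PanelSummary(
        table=table,
        mean_heterozygosity=float(stats["observed_het"].mean()),
        homozygous_marker_fraction=float(
            (stats["observed_het"] < HOMOZYGOUS_HET_CUTOFF).mean()
        ),
    )
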