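"""Synthetic genotype panels and NCII hybrid trials with known ground truth.

The panel generator produces a mostly-homozygous inbred panel drawn from a
small number of diverged latent groups plus a handful of admixed lines —
the situation a breeding programme faces when a new set of inbreds has been
genotyped and heterotic groups must be discovered.  Group divergence
follows the Balding–Nichols model: each group's allele frequency at a
locus is a Beta draw around a shared ancestral frequency p with a single
divergence knob F_ST (Beta parameters a = p(1−Fst)/Fst,
b = (1−p)(1−Fst)/Fst).  Inbreds are simulated as homozygote draws with a
residual heterozygosity flip, not as explicit selfing pedigrees; loci are
unlinked.

The trial generator produces balanced North Carolina design II multi-
environment phenotype tables: sets of male × female crosses observed in
every environment × replicate, with Gaussian male/female general combining
ability, specific combining ability, environment, G×E and plot-error
effects, plus a fixed yield offset for crosses whose parents come from
different latent groups (the heterosis signal that makes breeding
efficiency identifiable downstream).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .qc import MISSING, SUBSTITUTION_CLASSES, GenotypeMatrix

MIXED_LABEL = "mixed"

#: Default unadmixed group sizes: five groups of 25/8/14/13/6 lines, which
#: together with 4 admixed lines gives a 70-line panel.
DEFAULT_GROUP_SIZES = (25, 8, 14, 13, 6)


def derive_seed(master: int, *path: object) -> int:
    """Derive a stage seed (< 2^31) from a master seed and a key path.

    Stable across processes: path components are hashed with CRC32, not
    Python's per-process randomised ``hash``.
    """
    import zlib

    keys = [zlib.crc32(repr(p).encode()) % (2**31) for p in path]
    h = np.random.SeedSequence([int(master) % (2**31)] + keys)
    return int(h.generate_state(1)[0] % (2**31))


@dataclass
class PanelConfig:
    """Parameters of a synthetic inbred genotype panel.

    Defaults emulate a 70-line early-maturing maize inbred panel: five
    latent groups (25/8/14/13/6 lines) plus 4 admixed lines, 8171 biallelic
    markers, residual heterozygosity 5.6%, moderate divergence.
    """

    n_groups: int = 5
    n_per_group: int | Sequence[int] = DEFAULT_GROUP_SIZES
    n_mixed: int = 4
    n_markers: int = 8171
    fst: float = 0.30
    het_rate: float = 0.056
    missing_rate: float = 0.05
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def group_sizes(self) -> tuple[int, ...]:
        if isinstance(self.n_per_group, int):
            return (self.n_per_group,) * self.n_groups
        return tuple(self.n_per_group)

    def validate(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        sizes = self.group_sizes()
        if len(sizes) != self.n_groups or any(s < 1 for s in sizes):
            raise ValueError("n_per_group must give a positive size per group")
        if self.n_mixed < 0:
            raise ValueError("n_mixed must be >= 0")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie in the open interval (0, 1)")
        for name in ("het_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must be an interval within (0, 1)")


@dataclass
class PanelTruth:
    """Ground truth behind a simulated panel."""

    group_labels: list[str]  # per individual: "1".."K" or "mixed"
    q: np.ndarray  # individuals x groups ancestry proportions
    group_freqs: np.ndarray  # groups x markers alternative-allele frequencies
    ancestral_freqs: np.ndarray  # markers

    def to_json(self, path: str | Path) -> None:
        payload = {
            "group_labels": self.group_labels,
            "q": self.q.tolist(),
            "group_freqs": self.group_freqs.tolist(),
            "ancestral_freqs": self.ancestral_freqs.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def simulate_panel(config: PanelConfig) -> tuple[GenotypeMatrix, PanelTruth]:
    """Draw a genotype panel under the Balding–Nichols group model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes = config.group_sizes()
    k, m = config.n_groups, config.n_markers
    n_un = sum(sizes)
    n = n_un + config.n_mixed

    lo, hi = config.ancestral_freq_range
    p = rng.uniform(lo, hi, size=m)
    ratio = (1.0 - config.fst) / config.fst
    freqs = rng.beta(p * ratio, (1.0 - p) * ratio, size=(k, m))
    # keep loci polymorphic within the machine: avoid exact 0/1 draws
    freqs = np.clip(freqs, 1e-12, 1.0 - 1e-12)

    labels: list[str] = []
    q = np.zeros((n, k))
    origin = np.empty((n, m), dtype=np.int64)
    row = 0
    for gi, size in enumerate(sizes):
        for _ in range(size):
            labels.append(str(gi + 1))
            q[row, gi] = 1.0
            origin[row] = gi
            row += 1
    for _ in range(config.n_mixed):
        labels.append(MIXED_LABEL)
        q[row] = rng.dirichlet(np.ones(k))
        origin[row] = rng.choice(k, size=m, p=q[row])
        row += 1

    f_il = freqs[origin, np.arange(m)[None, :]]
    alt = rng.random((n, m)) < f_il
    calls = np.where(alt, 2, 0).astype(np.int8)
    het = rng.random((n, m)) < config.het_rate
    calls[het] = 1
    miss = rng.random((n, m)) < config.missing_rate
    calls[miss] = MISSING

    pair_idx = rng.integers(0, len(SUBSTITUTION_CLASSES), size=m)
    orient = rng.random(m) < 0.5
    alleles = []
    for j in range(m):
        a, b = SUBSTITUTION_CLASSES[pair_idx[j]].split("/")
        alleles.append((a, b) if orient[j] else (b, a))

    width = len(str(n))
    ids = [f"IND{i + 1:0{width}d}" for i in range(n)]
    g = GenotypeMatrix(
        individual_ids=ids,
        marker_ids=[f"M{j + 1}" for j in range(m)],
        alleles=alleles,
        calls=calls,
    )
    truth = PanelTruth(group_labels=labels, q=q, group_freqs=freqs, ancestral_freqs=p)
    return g, truth


# ----------------------------------------------------------------- trials


@dataclass
class TrialConfig:
    """Parameters of a balanced NCII multi-environment hybrid trial.

    Defaults emulate a 96-hybrid grain-yield trial (kg/ha) over four
    environments (two locations x two years) with two replicates: six sets
    of 4 males x 4 females.  Variance components are chosen so that
    entry-mean repeatability of yield is ~0.75 at E=4, r=2, and the
    inter-group heterosis offset is of the order of the genetic standard
    deviation.
    """

    n_sets: int = 6
    males_per_set: int = 4
    females_per_set: int = 4
    n_envs: int = 4
    n_reps: int = 2
    mu: float = 3540.0
    var_env: float = 500_000.0
    var_gca_m: float = 100_000.0
    var_gca_f: float = 100_000.0
    var_sca: float = 100_000.0
    var_gxe: float = 120_000.0
    var_error: float = 560_000.0
    heterosis_delta: float = 800.0
    trait: str = "GY"
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_sets", "males_per_set", "females_per_set", "n_envs", "n_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "var_env",
            "var_gca_m",
            "var_gca_f",
            "var_sca",
            "var_gxe",
            "var_error",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TrialTruth:
    """Simulated effects and the variance components that generated a trial."""

    gca_male: dict[str, float]
    gca_female: dict[str, float]
    sca: dict[tuple[str, str], float]
    env_effects: dict[str, float]
    variance_components: dict[str, float]
    heterosis_delta: float
    parent_groups: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gca_male": self.gca_male,
            "gca_female": self.gca_female,
            "sca": {f"{m}|{f}": v for (m, f), v in self.sca.items()},
            "env_effects": self.env_effects,
            "variance_components": self.variance_components,
            "heterosis_delta": self.heterosis_delta,
            "parent_groups": self.parent_groups,
        }
        Path(path).write_text(json.dumps(payload))


def default_parents(config: TrialConfig) -> tuple[list[list[str]], list[list[str]]]:
    """Auto-generated parent names per set: set{s}_male{i}, set{s}_female{j}."""
    males = [
        [f"set{s + 1}_male{i + 1}" for i in range(config.males_per_set)]
        for s in range(config.n_sets)
    ]
    females = [
        [f"set{s + 1}_female{j + 1}" for j in range(config.females_per_set)]
        for s in range(config.n_sets)
    ]
    return males, females


def simulate_ncii_trial(
    config: TrialConfig,
    parent_groups: Mapping[str, str],
    males: Sequence[Sequence[str]] | None = None,
    females: Sequence[Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, TrialTruth]:
    """Simulate one trait of a balanced NCII trial.

    y(m, f, e, r) = mu + E_e + g_m + g_f + s_mf + (ge)_mf,e + eps
                    + heterosis_delta * 1[group(m) != group(f)]

    Parameters
    ----------
    parent_groups
        Maps every parent name to its latent-group label (the ``mixed``
        label is allowed and never matches any group, including itself).
    males, females
        Per-set parent name lists; auto-generated names when omitted.

    Returns
    -------
    (trial, truth)
        ``trial`` is a tidy long table with columns
        (set, male, female, env, rep, trait, value).
    """
    config.validate()
    if males is None or females is None:
        auto_m, auto_f = default_parents(config)
        males = males if males is not None else auto_m
        females = females if females is not None else auto_f
    if len(males) != config.n_sets or len(females) != config.n_sets:
        raise ValueError("males/females must list parents for every set")

    all_parents = [p for ps in males for p in ps] + [p for ps in females for p in ps]
    for p in all_parents:
        if p not in parent_groups:
            raise KeyError(f"parent {p!r} has no group label in parent_groups")

    rng = np.random.default_rng(config.seed)
    sd = {k: np.sqrt(getattr(config, f"var_{k}")) for k in
          ("env", "gca_m", "gca_f", "sca", "gxe", "error")}

    envs = [f"E{e + 1}" for e in range(config.n_envs)]
    env_eff = {e: rng.normal(0.0, sd["env"]) for e in envs}
    gca_m = {p: rng.normal(0.0, sd["gca_m"]) for ps in males for p in ps}
    gca_f = {p: rng.normal(0.0, sd["gca_f"]) for ps in females for p in ps}

    rows = []
    sca: dict[tuple[str, str], float] = {}
    for s in range(config.n_sets):
        for m in males[s]:
            for f in females[s]:
                s_mf = rng.normal(0.0, sd["sca"])
                sca[(m, f)] = s_mf
                het = (
                    config.heterosis_delta
                    if (
                        parent_groups[m] != parent_groups[f]
                        or parent_groups[m] == MIXED_LABEL
                    )
                    else 0.0
                )
                for e in envs:
                    ge = rng.normal(0.0, sd["gxe"])
                    for r in range(config.n_reps):
                        eps = rng.normal(0.0, sd["error"])
                        y = (
                            config.mu
                            + env_eff[e]
                            + gca_m[m]
                            + gca_f[f]
                            + s_mf
                            + ge
                            + het
                            + eps
                        )
                        rows.append((f"set{s + 1}", m, f, e, r + 1, config.trait, y))

    trial = pd.DataFrame(
        rows, columns=["set", "male", "female", "env", "rep", "trait", "value"]
    )
    truth = TrialTruth(
        gca_male=gca_m,
        gca_female=gca_f,
        sca=sca,
        env_effects=env_eff,
        variance_components={
            "var_env": config.var_env,
            "var_gca_m": config.var_gca_m,
            "var_gca_f": config.var_gca_f,
            "var_sca": config.var_sca,
            "var_gxe": config.var_gxe,
            "var_error": config.var_error,
        },
        heterosis_delta=config.heterosis_delta,
        parent_groups=dict(parent_groups),
    )
    return trial, truth
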