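"""Latent-group admixture inference, K selection by the Evanno ΔK, assignment.

The model is the classic admixture likelihood: individual i's genotype at
locus l is Binomial(2, sum_k q_ik f_kl), where Q holds per-individual
ancestry proportions (rows on the simplex) and F holds per-group
alternative-allele frequencies.  The likelihood is maximised by
expectation-maximisation from a seeded random start, which is
deterministic given the seed and monotone in log-likelihood — the
properties the downstream K-selection logic needs.  The replicate
log-likelihoods per K play the role of the per-run LnP(D) values, and the
Evanno statistic

    ΔK = M[|L(K-1) - 2 L(K) + L(K+1)|] / S[L(K)]

(M the mean and S the standard deviation over replicate runs) selects K at
its peak.  Individuals are then assigned to the group of their largest
ancestry proportion when it reaches the membership threshold (default
0.70), and to a "mixed" group otherwise.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .qc import MISSING, GenotypeMatrix
from .simulate import MIXED_LABEL

_F_EPS = 1e-6  # clamp for group frequencies so the likelihood stays finite
_LL_BACKSTEP_TOL = 1e-6  # tolerated numerical loglik decrease per iteration


@dataclass
class AdmixtureFit:
    """Maximum-likelihood admixture solution for one K and one start."""

    k: int
    q: np.ndarray  # individuals x K, rows sum to 1
    f: np.ndarray  # K x markers, in (0, 1)
    loglik: float
    n_iter: int
    converged: bool
    seed: int | None

    def __post_init__(self) -> None:
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("Q rows must sum to 1")
        if not ((self.f > 0) & (self.f < 1)).all():
            raise ValueError("F entries must lie in (0, 1)")
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood must be finite")


def admixture_loglik(g: GenotypeMatrix, q: np.ndarray, f: np.ndarray) -> float:
    """Binomial admixture log-likelihood of a genotype panel at (Q, F)."""
    calls = g.calls
    obs = calls != MISSING
    dose = np.where(obs, calls, 0).astype(float)
    p = np.clip(q @ f, _F_EPS, 1.0 - _F_EPS)
    ll = dose * np.log(p) + (2.0 - dose) * np.log1p(-p)
    # binomial coefficient: log C(2, g) = log 2 for heterozygotes
    ll = ll + np.where(calls == 1, np.log(2.0), 0.0)
    return float(ll[obs].sum())


def fit_admixture(
    g: GenotypeMatrix,
    k: int,
    seed: int | None = None,
    max_iter: int = 2000,
    tol: float = 1e-6,
    n_starts: int = 1,
    select_iters: int = 50,
) -> AdmixtureFit:
    """EM maximisation of the admixture likelihood from a random start.

    Missing calls contribute nothing to either the likelihood or the
    updates.  The log-likelihood is checked for monotonicity at every
    iteration; convergence is declared when its increase falls below
    ``tol``.

    With ``n_starts > 1``, that many random starts are advanced for
    ``select_iters`` burn-in iterations and only the best continues —
    a standard guard against poor local optima that keeps the run
    deterministic given the seed.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    n, m = g.calls.shape
    if n == 0 or m == 0:
        raise ValueError("empty genotype panel")
    if k > n:
        raise ValueError(f"K={k} exceeds the number of individuals ({n})")
    obs = g.calls != MISSING
    if (~obs).all(axis=0).any():
        j = int(np.flatnonzero((~obs).all(axis=0))[0])
        raise ValueError(f"marker {g.marker_ids[j]} has no observed calls")

    w = obs.astype(float)
    galt = np.where(obs, g.calls, 0).astype(float)  # observed alt copies
    gref = np.where(obs, 2 - g.calls, 0).astype(float)
    l_i = w.sum(axis=1)  # observed loci per individual
    n_het = int((g.calls == 1).sum())
    const = n_het * np.log(2.0)
    base = galt.sum(axis=0) / np.maximum(2.0 * w.sum(axis=0), 1.0)

    def loglik(qm: np.ndarray, fm: np.ndarray) -> float:
        p = np.clip(qm @ fm, _F_EPS, 1.0 - _F_EPS)
        return float((galt * np.log(p) + gref * np.log1p(-p)).sum() + const)

    def random_start(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        # uniform-Dirichlet Q rows, F jittered around sample frequencies
        q0 = rng.dirichlet(np.ones(k), size=n)
        f0 = np.clip(
            base[None, :] + rng.normal(0.0, 0.1, size=(k, m)), _F_EPS, 1.0 - _F_EPS
        )
        return q0, f0

    def em_step(q: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = np.clip(q @ f, _F_EPS, 1.0 - _F_EPS)
        # responsibilities: expected allele copies attributed to group k are
        #   alt: g * q_ik f_kl / p_il ; ref: (2-g) * q_ik (1-f_kl) / (1-p_il).
        # Summing them over loci (for Q) or individuals (for F) factorises
        # into matrix products, so no 3-D array is ever materialised.
        u = galt / p
        v = gref / (1.0 - p)
        q_new = q * (u @ f.T + v @ (1.0 - f).T) / (2.0 * l_i[:, None])
        num = f * (q.T @ u)
        den = num + (1.0 - f) * (q.T @ v)
        f_new = np.where(den > 0, num / np.maximum(den, 1e-300), f)
        f_new = np.clip(f_new, _F_EPS, 1.0 - _F_EPS)
        return q_new / q_new.sum(axis=1, keepdims=True), f_new

    ss = np.random.SeedSequence(seed).spawn(n_starts)
    candidates = []
    burn = min(select_iters, max_iter) if n_starts > 1 else 0
    for child in ss:
        q, f = random_start(np.random.default_rng(child))
        ll = loglik(q, f)
        for _ in range(burn):
            q, f = em_step(q, f)
            ll_new = loglik(q, f)
            if ll_new < ll - _LL_BACKSTEP_TOL * max(1.0, abs(ll)):
                raise RuntimeError("EM log-likelihood decreased during burn-in")
            ll = ll_new
        candidates.append((ll, q, f))
        if n_starts == 1:
            break
    ll_old, q, f = max(candidates, key=lambda c: c[0])

    converged = False
    it = burn
    while it < max_iter:
        it += 1
        q, f = em_step(q, f)
        ll = loglik(q, f)
        if ll < ll_old - _LL_BACKSTEP_TOL * max(1.0, abs(ll_old)):
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: {ll_old} -> {ll}"
            )
        if abs(ll - ll_old) < tol:
            ll_old = ll
            converged = True
            break
        ll_old = ll

    return AdmixtureFit(
        k=k, q=q, f=f, loglik=ll_old, n_iter=it, converged=converged, seed=seed
    )


def match_group_labels(q_ref: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Column permutation of ``q`` best aligning it with ``q_ref``.

    Resolves label switching between replicate runs for reporting only;
    uses an optimal assignment on column correlations.
    """
    k = q_ref.shape[1]
    cost = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            cost[a, b] = -float(q_ref[:, a] @ q[:, b])
    _, cols = linear_sum_assignment(cost)
    return q[:, cols]


# ------------------------------------------------------------------ K sweep


@dataclass
class KSweep:
    """Replicate log-likelihoods over a range of K."""

    runs: pd.DataFrame  # columns: k, replicate, loglik, converged, n_iter, seed

    def summary(self) -> pd.DataFrame:
        g = self.runs.groupby("k")["loglik"]
        return pd.DataFrame(
            {"mean_loglik": g.mean(), "sd_loglik": g.std(ddof=1), "n_runs": g.size()}
        )


def k_sweep(
    g: GenotypeMatrix,
    k_range: Sequence[int] = range(1, 13),
    replicates: int = 10,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    n_starts: int = 3,
) -> KSweep:
    """Independent seeded admixture fits for every (K, replicate).

    Each replicate run is a best-of-``n_starts`` burn-in EM run (see
    :func:`fit_admixture`), which keeps run-to-run spread from the random
    starts while making poor local optima rare.
    """
    if replicates < 2:
        raise ValueError("need >= 2 replicates per K for the ΔK statistic")
    rows = []
    for k in k_range:
        for rep in range(replicates):
            run_seed = int(
                np.random.SeedSequence([seed % 2**31, k, rep]).generate_state(1)[0]
                % (2**31)
            )
            try:
                fit = fit_admixture(
                    g, k, seed=run_seed, max_iter=max_iter, tol=tol,
                    n_starts=n_starts,
                )
            except (ValueError, RuntimeError) as exc:
                warnings.warn(f"fit failed for K={k} replicate {rep}: {exc}", stacklevel=2)
                continue
            rows.append(
                {
                    "k": k,
                    "replicate": rep,
                    "loglik": fit.loglik,
                    "converged": fit.converged,
                    "n_iter": fit.n_iter,
                    "seed": run_seed,
                }
            )
    runs = pd.DataFrame(rows)
    # a K is usable only with >= 2 successful replicates
    ok = runs.groupby("k")["loglik"].transform("size") >= 2
    if (~ok).any():
        dropped = sorted(runs.loc[~ok, "k"].unique())
        warnings.warn(f"K values with < 2 successful replicates dropped: {dropped}",
                      stacklevel=2)
    return KSweep(runs=runs[ok].reset_index(drop=True))


@dataclass
class DeltaKTable:
    """Evanno ΔK per interior K and the selected K."""

    table: pd.DataFrame  # columns: k, delta_k, defined
    best_k: int | None


def delta_k(sweep: KSweep) -> DeltaKTable:
    """Evanno ΔK from replicate log-likelihoods.

    With equal replicate counts at K-1, K, K+1 the second difference is
    taken per replicate index and averaged in absolute value; with unequal
    counts it falls back to the second difference of replicate means.
    Either way the denominator is the replicate standard deviation
    S[L(K)]; a zero S makes ΔK undefined at that K.
    """
    runs = sweep.runs
    ks = sorted(runs["k"].unique())
    if len(ks) < 3:
        raise ValueError("ΔK needs at least three consecutive K values")
    by_k = {k: runs.loc[runs["k"] == k, "loglik"].to_numpy() for k in ks}
    rows = []
    for k in ks:
        if (k - 1) not in by_k or (k + 1) not in by_k:
            continue
        lm, l0, lp = by_k[k - 1], by_k[k], by_k[k + 1]
        s = float(np.std(l0, ddof=1))
        if len(lm) == len(l0) == len(lp):
            num = float(np.mean(np.abs(lm - 2.0 * l0 + lp)))
        else:
            num = abs(float(np.mean(lm) - 2.0 * np.mean(l0) + np.mean(lp)))
        if s <= 0.0 or not np.isfinite(s):
            rows.append({"k": k, "delta_k": np.nan, "defined": False})
        else:
            rows.append({"k": k, "delta_k": num / s, "defined": True})
    table = pd.DataFrame(rows)
    defined = table[table["defined"]]
    best = int(defined.loc[defined["delta_k"].idxmax(), "k"]) if len(defined) else None
    if (~table["defined"]).any():
        warnings.warn("ΔK undefined at some K (zero replicate SD)", stacklevel=2)
    return DeltaKTable(table=table, best_k=best)


# --------------------------------------------------------------- assignment


@dataclass
class GroupAssignment:
    """Threshold-based group membership: assigned group or "mixed"."""

    assignments: pd.DataFrame  # columns: individual, group, max_q
    threshold: float

    @property
    def counts(self) -> dict[str, int]:
        return self.assignments["group"].value_counts().to_dict()

    @property
    def n_mixed(self) -> int:
        return int((self.assignments["group"] == MIXED_LABEL).sum())

    @property
    def mixed_fraction_percent(self) -> float:
        return 100.0 * self.n_mixed / len(self.assignments)


def assign_groups(
    fit_or_q: AdmixtureFit | np.ndarray,
    individual_ids: Sequence[str] | None = None,
    threshold: float = 0.70,
) -> GroupAssignment:
    """Assign each individual to its argmax ancestry group, or to "mixed".

    Individuals whose largest ancestry proportion is >= ``threshold`` go
    to that group (labels "1".."K"); the rest constitute the mixed group.
    """
    if isinstance(fit_or_q, AdmixtureFit):
        q = fit_or_q.q
    else:
        q = np.asarray(fit_or_q, dtype=float)
    n = q.shape[0]
    if individual_ids is None:
        individual_ids = [f"IND{i + 1}" for i in range(n)]
    max_q = q.max(axis=1)
    arg = q.argmax(axis=1)
    groups = [
        str(arg[i] + 1) if max_q[i] >= threshold else MIXED_LABEL for i in range(n)
    ]
    df = pd.DataFrame(
        {"individual": list(individual_ids), "group": groups, "max_q": max_q}
    )
    return GroupAssignment(assignments=df, threshold=threshold)


# --------------------------------------------- external STRUCTURE-run import


def read_structure_run(path: str | Path) -> tuple[float, pd.DataFrame]:
    """Parse a STRUCTURE output file into (LnP(D), Q table).

    Extracts the "Estimated Ln Prob of Data" line and the "Inferred
    ancestry of individuals" block, so externally produced runs can feed
    the ΔK and assignment logic.
    """
    text = Path(path).read_text()
    m = re.search(r"Estimated Ln Prob of Data\s*=\s*(-?\d+\.?\d*)", text)
    if not m:
        raise ValueError(f"no 'Estimated Ln Prob of Data' line in {path}")
    loglik = float(m.group(1))
    rows = []
    in_block = False
    for line in text.splitlines():
        if "Inferred ancestry of individuals" in line:
            in_block = True
            continue
        if in_block:
            if not line.strip():
                if rows:
                    break
                continue
            if "Label" in line and "Inferred" in line:
                continue
            mm = re.match(r"\s*\d+\s+(\S+)\s+\(\s*\d+\s*\)\s*(?:\d+\s*)?:\s*(.+)", line)
            if mm:
                label, qs = mm.group(1), mm.group(2).split()
                rows.append([label] + [float(x) for x in qs])
    if not rows:
        raise ValueError(f"no inferred-ancestry block found in {path}")
    k = len(rows[0]) - 1
    df = pd.DataFrame(rows, columns=["individual"] + [f"Q{i + 1}" for i in range(k)])
    return loglik, df
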