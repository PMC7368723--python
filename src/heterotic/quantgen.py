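"""Balanced North Carolina design II analysis: ANOVA, GCA/SCA, repeatability.

The trial container is a tidy long table with columns
(set, male, female, env, rep, trait, value); every male x female cross
within a set must be observed in every environment x replicate (balance is
validated before any sums of squares are computed — incomplete-block
recovery is out of scope and the model is a randomised complete block per
environment).

The hybrid line of the ANOVA is partitioned into male GCA, female GCA and
SCA within sets (pooled over sets when there are several); hybrids are
fixed, environments and replicates random, so hybrid terms are tested over
their interaction with environments and the interactions over the pooled
error.  Variance components come from the expected mean squares of this
balanced layout (method of moments):

    sigma2_error = MS_error
    sigma2_GE    = (MS_hybxE - MS_error) / r
    sigma2_G     = (MS_hybrid - MS_hybxE) / (r E)

negative estimates are truncated to zero with a flag.  Entry-mean
repeatability is the broad-sense ratio

    R = sigma2_G / (sigma2_G + sigma2_GE / E + sigma2_error / (r E)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TRIAL_COLUMNS = ("set", "male", "female", "env", "rep", "trait", "value")


def validate_trial(df: pd.DataFrame, trait: str) -> None:
    """Check shape and balance of a trial table for one trait."""
    missing_cols = set(TRIAL_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"trial table lacks columns: {sorted(missing_cols)}")
    sub = df[df["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    counts = sub.groupby(["set", "male", "female", "env", "rep"]).size()
    if (counts != 1).any():
        dup = counts[counts > 1].index.tolist()[:5]
        raise ValueError(f"duplicated trial cells for trait {trait!r}: {dup}")
    hybrids = sub[["set", "male", "female"]].drop_duplicates()
    envs = sub["env"].unique()
    reps = sub["rep"].unique()
    expected = len(hybrids) * len(envs) * len(reps)
    if len(sub) != expected:
        full = pd.MultiIndex.from_frame(
            hybrids.merge(pd.DataFrame({"env": envs}), how="cross").merge(
                pd.DataFrame({"rep": reps}), how="cross"
            )
        )
        present = pd.MultiIndex.from_frame(sub[["set", "male", "female", "env", "rep"]])
        absent = full.difference(present).tolist()[:10]
        raise ValueError(
            f"unbalanced trial for trait {trait!r}; missing cells (first 10): {absent}"
        )


def _trial_cube(df: pd.DataFrame, trait: str):
    """Reshape a balanced trial into a (S, M, F, E, R) array plus index maps."""
    validate_trial(df, trait)
    sub = df[df["trait"] == trait]
    sets = sorted(sub["set"].unique())
    envs = sorted(sub["env"].unique())
    reps = sorted(sub["rep"].unique())
    males = {s: sorted(sub.loc[sub["set"] == s, "male"].unique()) for s in sets}
    females = {s: sorted(sub.loc[sub["set"] == s, "female"].unique()) for s in sets}
    n_m = {len(v) for v in males.values()}
    n_f = {len(v) for v in females.values()}
    if len(n_m) != 1 or len(n_f) != 1:
        raise ValueError("sets must share the same male and female counts")
    sm, fm = n_m.pop(), n_f.pop()
    cube = np.full((len(sets), sm, fm, len(envs), len(reps)), np.nan)
    si = sub["set"].map({s: i for i, s in enumerate(sets)})
    mi = sub.apply(lambda r: males[r["set"]].index(r["male"]), axis=1)
    fi = sub.apply(lambda r: females[r["set"]].index(r["female"]), axis=1)
    ei = sub["env"].map({e: i for i, e in enumerate(envs)})
    ri = sub["rep"].map({r: i for i, r in enumerate(reps)})
    cube[si, mi, fi, ei, ri] = sub["value"].to_numpy()
    if np.isnan(cube).any():
        raise ValueError("trial is unbalanced after reshaping")
    return cube, sets, males, females, envs, reps


@dataclass
class AnovaTable:
    """Sums of squares, F tests and denominators for the NCII partition."""

    table: pd.DataFrame  # index: source; columns: df, sum_sq, mean_sq, F, F_denom, p
    n_sets: int
    n_envs: int
    n_reps: int

    def ms(self, source: str) -> float:
        return float(self.table.loc[source, "mean_sq"])


def ncii_anova(df: pd.DataFrame, trait: str) -> AnovaTable:
    """Classical balanced least-squares ANOVA of an NCII trial."""
    cube, sets, males, females, envs, reps = _trial_cube(df, trait)
    s, m, f, e, r = cube.shape
    if e < 2 or r < 2:
        raise ValueError("ANOVA needs >= 2 environments and >= 2 replicates")
    grand = cube.mean()
    n_hyb = s * m * f

    y_e = cube.mean(axis=(0, 1, 2, 4))  # per env
    y_er = cube.mean(axis=(0, 1, 2))  # env x rep
    y_s = cube.mean(axis=(1, 2, 3, 4))  # per set
    y_sm = cube.mean(axis=(2, 3, 4))  # set x male
    y_sf = cube.mean(axis=(1, 3, 4))  # set x female
    y_smf = cube.mean(axis=(3, 4))  # hybrid means
    y_se = cube.mean(axis=(1, 2, 4))  # set x env
    y_sme = cube.mean(axis=(2, 4))
    y_sfe = cube.mean(axis=(1, 4))
    y_smfe = cube.mean(axis=4)

    ss_env = n_hyb * r * np.sum((y_e - grand) ** 2)
    ss_rep = n_hyb * np.sum((y_er - y_e[:, None]) ** 2)
    ss_set = m * f * e * r * np.sum((y_s - grand) ** 2)
    ss_gcam = f * e * r * np.sum((y_sm - y_s[:, None]) ** 2)
    ss_gcaf = m * e * r * np.sum((y_sf - y_s[:, None]) ** 2)
    ss_sca = e * r * np.sum(
        (y_smf - y_sm[:, :, None] - y_sf[:, None, :] + y_s[:, None, None]) ** 2
    )
    ss_hyb = ss_gcam + ss_gcaf + ss_sca  # hybrids within sets
    ss_sete = m * f * r * np.sum(
        (y_se - y_s[:, None] - y_e[None, :] + grand) ** 2
    )
    ss_gcam_e = f * r * np.sum(
        (y_sme - y_sm[:, :, None] - y_se[:, None, :] + y_s[:, None, None]) ** 2
    )
    ss_gcaf_e = m * r * np.sum(
        (y_sfe - y_sf[:, :, None] - y_se[:, None, :] + y_s[:, None, None]) ** 2
    )
    ss_hyb_e = r * np.sum(
        (
            y_smfe
            - y_smf[:, :, :, None]
            - y_se[:, None, None, :]
            + y_s[:, None, None, None]
        )
        ** 2
    )
    ss_sca_e = ss_hyb_e - ss_gcam_e - ss_gcaf_e
    resid = (
        cube
        - y_smfe[:, :, :, :, None]
        - y_er[None, None, None, :, :]
        + y_e[None, None, None, :, None]
    )
    ss_err = np.sum(resid**2)
    ss_total = np.sum((cube - grand) ** 2)

    rows = [
        ("environment", e - 1, ss_env, "rep(environment)"),
        ("rep(environment)", e * (r - 1), ss_rep, "error"),
    ]
    if s > 1:
        rows.append(("set", s - 1, ss_set, "set_x_env"))
    rows += [
        ("hybrid", s * (m * f - 1), ss_hyb, "hybrid_x_env"),
        ("gca_male", s * (m - 1), ss_gcam, "gca_male_x_env"),
        ("gca_female", s * (f - 1), ss_gcaf, "gca_female_x_env"),
        ("sca", s * (m - 1) * (f - 1), ss_sca, "sca_x_env"),
    ]
    if s > 1:
        rows.append(("set_x_env", (s - 1) * (e - 1), ss_sete, "error"))
    rows += [
        ("hybrid_x_env", s * (m * f - 1) * (e - 1), ss_hyb_e, "error"),
        ("gca_male_x_env", s * (m - 1) * (e - 1), ss_gcam_e, "error"),
        ("gca_female_x_env", s * (f - 1) * (e - 1), ss_gcaf_e, "error"),
        ("sca_x_env", s * (m - 1) * (f - 1) * (e - 1), ss_sca_e, "error"),
    ]
    df_err = e * (r - 1) * (n_hyb - 1)
    rows.append(("error", df_err, ss_err, None))

    table = pd.DataFrame(
        [(src, dof, ss) for src, dof, ss, _ in rows],
        columns=["source", "df", "sum_sq"],
    ).set_index("source")
    table["mean_sq"] = table["sum_sq"] / table["df"].replace(0, np.nan)
    denom_of = {src: den for src, _, _, den in rows}
    f_stat, p_val, denoms = [], [], []
    for src in table.index:
        den = denom_of[src]
        if den is None or not np.isfinite(table.loc[den, "mean_sq"]) or table.loc[
            den, "mean_sq"
        ] == 0:
            f_stat.append(np.nan)
            p_val.append(np.nan)
            denoms.append(den or "")
            continue
        fv = table.loc[src, "mean_sq"] / table.loc[den, "mean_sq"]
        f_stat.append(fv)
        p_val.append(
            float(stats.f.sf(fv, table.loc[src, "df"], table.loc[den, "df"]))
        )
        denoms.append(den)
    table["F"] = f_stat
    table["F_denom"] = denoms
    table["p"] = p_val
    table.attrs["ss_total"] = float(ss_total)
    return AnovaTable(table=table, n_sets=s, n_envs=e, n_reps=r)


# ------------------------------------------------------- combining ability


@dataclass
class CombiningAbility:
    """GCA effects per parent and SCA effects per cross (trait units)."""

    gca_male: pd.DataFrame  # columns: set, male, effect
    gca_female: pd.DataFrame  # columns: set, female, effect
    sca: pd.DataFrame  # columns: set, male, female, effect


def combining_ability(df: pd.DataFrame, trait: str) -> CombiningAbility:
    """Hallauer–Miranda estimators over environment x replicate means.

    Within each set: g_m = ybar_m.. - ybar..., g_f = ybar_.f. - ybar...,
    s_mf = ybar_mf - ybar_m.. - ybar_.f. + ybar..., so GCA effects sum to
    zero within parent class per set and SCA rows/columns sum to zero.
    """
    cube, sets, males, females, envs, reps = _trial_cube(df, trait)
    y_smf = cube.mean(axis=(3, 4))
    rows_m, rows_f, rows_s = [], [], []
    for si, s in enumerate(sets):
        set_mean = y_smf[si].mean()
        gm = y_smf[si].mean(axis=1) - set_mean
        gf = y_smf[si].mean(axis=0) - set_mean
        for i, male in enumerate(males[s]):
            rows_m.append({"set": s, "male": male, "effect": gm[i]})
        for j, fem in enumerate(females[s]):
            rows_f.append({"set": s, "female": fem, "effect": gf[j]})
        for i, male in enumerate(males[s]):
            for j, fem in enumerate(females[s]):
                rows_s.append(
                    {
                        "set": s,
                        "male": male,
                        "female": fem,
                        "effect": y_smf[si, i, j] - set_mean - gm[i] - gf[j],
                    }
                )
    return CombiningAbility(
        gca_male=pd.DataFrame(rows_m),
        gca_female=pd.DataFrame(rows_f),
        sca=pd.DataFrame(rows_s),
    )


# ----------------------------------------------------------- repeatability


@dataclass
class VarComps:
    """Method-of-moments variance components and entry-mean repeatability."""

    sigma2_g: float
    sigma2_ge: float
    sigma2_error: float
    truncated: list[str]
    n_envs: int
    n_reps: int
    repeatability: float  # NaN when undefined

    def recompute_r(self) -> float:
        denom = (
            self.sigma2_g
            + self.sigma2_ge / self.n_envs
            + self.sigma2_error / (self.n_reps * self.n_envs)
        )
        return self.sigma2_g / denom if denom > 0 else float("nan")


def repeatability(df: pd.DataFrame, trait: str) -> VarComps:
    """Variance components and broad-sense entry-mean repeatability."""
    an = ncii_anova(df, trait)
    e, r = an.n_envs, an.n_reps
    ms_err = an.ms("error")
    ms_ge = an.ms("hybrid_x_env")
    ms_g = an.ms("hybrid")
    truncated: list[str] = []
    sigma2_error = ms_err
    sigma2_ge = (ms_ge - ms_err) / r
    if sigma2_ge < 0:
        sigma2_ge = 0.0
        truncated.append("sigma2_ge")
    sigma2_g = (ms_g - ms_ge) / (r * e)
    if sigma2_g < 0:
        sigma2_g = 0.0
        truncated.append("sigma2_g")
    denom = sigma2_g + sigma2_ge / e + sigma2_error / (r * e)
    if denom <= 0:
        import warnings

        warnings.warn(f"zero total variance for trait {trait!r}; R undefined",
                      stacklevel=2)
        rep = float("nan")
    else:
        rep = sigma2_g / denom
    return VarComps(
        sigma2_g=float(sigma2_g),
        sigma2_ge=float(sigma2_ge),
        sigma2_error=float(sigma2_error),
        truncated=truncated,
        n_envs=e,
        n_reps=r,
        repeatability=rep,
    )


def hybrid_means(df: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Per-hybrid entry means over environments and replicates."""
    validate_trial(df, trait)
    sub = df[df["trait"] == trait]
    out = (
        sub.groupby(["set", "male", "female"], as_index=False)["value"]
        .mean()
        .rename(columns={"value": "mean"})
    )
    out["hybrid"] = out["male"] + " x " + out["female"]
    return out[["hybrid", "set", "male", "female", "mean"]]
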