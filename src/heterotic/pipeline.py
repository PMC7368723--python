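"""End-to-end orchestration: panel -> QC -> diversity -> groups -> hybrids -> BE.

A single run takes (or simulates) a genotype panel and NCII trials, then
chains marker QC, diversity statistics, the Nei/UPGMA/bootstrap tree with
a k-cut, the admixture K-sweep with Evanno ΔK and threshold assignment,
PCoA, per-trait ANOVA/repeatability, the low-N base index, and breeding
efficiency per research condition.  Every intermediate artifact is
persisted under the output directory in open formats so each reported
number is recomputable, and a single master seed fans out to fixed
stage-specific seeds so a rerun is numerically identical.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .admixture import assign_groups, delta_k, fit_admixture, k_sweep
from .diversity import marker_stats, panel_summary
from .disttree import bootstrap_support, nei_distance, pcoa
from .indices import (
    MI_TRAITS,
    breeding_efficiency,
    classify_crosses,
    multiple_trait_index,
    yield_reduction,
    yield_terciles,
)
from .qc import GenotypeMatrix, filter_markers, read_genotypes
from .quantgen import hybrid_means, ncii_anova, repeatability
from .simulate import (
    MIXED_LABEL,
    PanelConfig,
    TrialConfig,
    derive_seed,
    simulate_ncii_trial,
    simulate_panel,
)

CONDITIONS = ("low_n", "optimal")

#: Score-type traits simulated on a 1-9 scale; others are unconstrained.
_TRAIT_SETTINGS: dict[str, dict] = {
    # (mu_low_n, mu_optimal, scale, heterosis share) per trait; variances are
    # scaled from the yield defaults so score traits stay on a 1-9-ish scale.
    "GY": dict(mu=(3540.0, 5040.0), scale=1.0, het=1.0),
    "EPP": dict(mu=(0.81, 0.89), scale=0.08 / 750.0, het=0.3),
    "ASI": dict(mu=(4.0, 2.5), scale=1.0 / 750.0, het=-0.4),
    "PASP": dict(mu=(5.2, 4.2), scale=0.8 / 750.0, het=-0.4),
    "EASP": dict(mu=(4.7, 3.5), scale=0.8 / 750.0, het=-0.4),
    "STGR": dict(mu=(4.5, 3.0), scale=0.9 / 750.0, het=-0.4),
    "DS": dict(mu=(53.3, 52.1), scale=1.5 / 750.0, het=-0.2),
}


@dataclass
class PipelineConfig:
    """Settings for a full run; defaults are the study's analysis settings."""

    genotype_path: str | None = None  # VCF or dosage CSV; simulate when None
    genotype_format: str = "vcf"
    phenotype_path: str | None = None  # tidy trial CSV; simulate when None
    panel: PanelConfig = field(default_factory=PanelConfig)
    trial: TrialConfig = field(default_factory=TrialConfig)
    min_call_rate: float = 0.80
    max_missing: float = 0.10
    freq_bounds: tuple[float, float] = (0.05, 0.95)
    k_min: int = 1
    k_max: int = 12
    replicates: int = 10
    n_boot: int = 1000
    membership_threshold: float = 0.70
    em_max_iter: int = 3000
    em_tol: float = 1.0
    seed: int = 0
    outdir: str = "results/pipeline"


@dataclass
class RunReport:
    """Headline numbers of a pipeline run; everything is also on disk."""

    version: str
    seed: int
    qc_counts: dict
    panel_summary: dict
    selected_k: int | None
    assignment_counts: dict
    tree_cut_counts: dict
    pcoa_percent_variance: list[float]
    repeatability: dict  # condition -> trait -> R
    mi_top: list[str]
    yield_reduction_mean: float
    breeding_efficiency: dict  # condition -> BE percent
    started: str = ""
    elapsed_s: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _stage(outdir: Path, name: str):
    """Context-style error wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def simulate_trials(config: PipelineConfig, parent_groups: dict[str, str],
                    males, females) -> pd.DataFrame:
    """Simulate all traits under both research conditions as one long table."""
    frames = []
    base = config.trial
    for cond_i, cond in enumerate(CONDITIONS):
        for trait, ts in _TRAIT_SETTINGS.items():
            sc = ts["scale"] ** 2
            tc = dataclasses.replace(
                base,
                mu=ts["mu"][cond_i],
                var_env=base.var_env * sc,
                var_gca_m=base.var_gca_m * sc,
                var_gca_f=base.var_gca_f * sc,
                var_sca=base.var_sca * sc,
                var_gxe=base.var_gxe * sc,
                var_error=base.var_error * sc,
                heterosis_delta=base.heterosis_delta * ts["scale"] * ts["het"],
                trait=trait,
                seed=derive_seed(config.seed, "trial", cond, trait),
            )
            trial, _ = simulate_ncii_trial(tc, parent_groups, males, females)
            score_trait = trait in ("PASP", "EASP", "STGR")
            if score_trait:
                trial["value"] = trial["value"].clip(1.0, 9.0)
            trial["condition"] = cond
            frames.append(trial)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> RunReport:
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")

    # ---- genotypes
    with _stage(outdir, "genotypes"):
        if config.genotype_path is not None:
            g = read_genotypes(config.genotype_path, config.genotype_format)
            truth = None
        else:
            panel_cfg = dataclasses.replace(
                config.panel, seed=derive_seed(config.seed, "panel")
            )
            g, truth = simulate_panel(panel_cfg)
            g.write_dosage_csv(outdir / "genotypes_dosage.csv")
            truth.to_json(outdir / "panel_truth.json")

    # ---- QC
    with _stage(outdir, "qc"):
        g_qc, qc_report = filter_markers(
            g, config.min_call_rate, config.max_missing, config.freq_bounds
        )
        qc_counts = {
            "n_input_markers": qc_report.n_input_markers,
            "n_after_callrate": qc_report.n_after_callrate,
            "n_after_missing": qc_report.n_after_missing,
            "n_after_freq": qc_report.n_after_freq,
        }
        (outdir / "qc_report.json").write_text(json.dumps(qc_counts))

    # ---- diversity
    with _stage(outdir, "diversity"):
        stats = marker_stats(g_qc)
        stats.to_csv(outdir / "marker_stats.csv", index=False)
        summ = panel_summary(stats)
        summ.table.to_csv(outdir / "panel_summary.csv", index_label="statistic")

    # ---- distance / tree / PCoA
    with _stage(outdir, "distance_tree"):
        d = nei_distance(g_qc)
        d.write_csv(outdir / "nei_distance.csv")
        tree = bootstrap_support(
            g_qc, n_boot=config.n_boot, seed=derive_seed(config.seed, "bootstrap")
        )
        (outdir / "upgma.nwk").write_text(tree.to_newick())
        k_cut = config.panel.n_groups
        tree_groups = tree.cut(k_cut)
        pd.Series(tree_groups, name="tree_group").rename_axis("individual").to_csv(
            outdir / "tree_groups.csv"
        )
        ord_ = pcoa(d)
        ord_.to_frame().to_csv(outdir / "pcoa_coordinates.csv", index_label="individual")
        (outdir / "pcoa_eigenvalues.json").write_text(
            json.dumps(
                {
                    "eigenvalues": ord_.eigenvalues.tolist(),
                    "percent_variance": ord_.proportion_explained.tolist(),
                }
            )
        )

    # ---- admixture / ΔK / assignment
    with _stage(outdir, "admixture"):
        sweep = k_sweep(
            g_qc,
            k_range=range(config.k_min, config.k_max + 1),
            replicates=config.replicates,
            seed=derive_seed(config.seed, "sweep"),
            max_iter=config.em_max_iter,
            tol=config.em_tol,
        )
        sweep.runs.to_csv(outdir / "k_sweep_logliks.csv", index=False)
        dk = delta_k(sweep)
        dk.table.to_csv(outdir / "delta_k.csv", index=False)
        selected_k = dk.best_k
        best_fit = None
        if selected_k is not None:
            best_rows = sweep.runs[sweep.runs["k"] == selected_k]
            best_seed = int(
                best_rows.loc[best_rows["loglik"].idxmax(), "seed"]
            )
            best_fit = fit_admixture(
                g_qc,
                selected_k,
                seed=best_seed,
                max_iter=config.em_max_iter,
                tol=config.em_tol,
            )
            pd.DataFrame(
                best_fit.q,
                index=g_qc.individual_ids,
                columns=[f"Q{i + 1}" for i in range(selected_k)],
            ).to_csv(outdir / "q_matrix.csv", index_label="individual")
        assignment = assign_groups(
            best_fit, g_qc.individual_ids, threshold=config.membership_threshold
        )
        assignment.assignments.to_csv(outdir / "group_assignment.csv", index=False)

    # ---- hybrid trials
    with _stage(outdir, "trials"):
        if config.phenotype_path is not None:
            trials = pd.read_csv(config.phenotype_path)
            parent_groups = dict(
                zip(assignment.assignments["individual"], assignment.assignments["group"])
            )
        else:
            trials, parent_groups = _simulated_trials(config, g_qc, truth, assignment)
        trials.to_csv(outdir / "trials.csv", index=False)

    # ---- quantitative genetics per condition and trait
    with _stage(outdir, "quantgen"):
        rep_out: dict[str, dict[str, float]] = {}
        anova_frames = []
        for cond in sorted(trials["condition"].unique()):
            sub = trials[trials["condition"] == cond]
            rep_out[cond] = {}
            for trait in sorted(sub["trait"].unique()):
                an = ncii_anova(sub, trait)
                tb = an.table.reset_index()
                tb.insert(0, "trait", trait)
                tb.insert(0, "condition", cond)
                anova_frames.append(tb)
                rep_out[cond][trait] = repeatability(sub, trait).repeatability
        pd.concat(anova_frames, ignore_index=True).to_csv(
            outdir / "anova.csv", index=False
        )
        (outdir / "repeatability.json").write_text(json.dumps(rep_out))

    # ---- indices and breeding efficiency
    with _stage(outdir, "indices"):
        means = {}
        for cond in CONDITIONS:
            sub = trials[trials["condition"] == cond]
            cond_means = None
            for trait in sorted(sub["trait"].unique()):
                hm = hybrid_means(sub, trait).set_index("hybrid")
                if cond_means is None:
                    cond_means = hm[["set", "male", "female"]].copy()
                cond_means[trait] = hm["mean"]
            means[cond] = cond_means
        mi = multiple_trait_index(means["low_n"][list(MI_TRAITS)])
        mi.to_csv(outdir / "multiple_trait_index.csv", index_label="hybrid")
        yrd = pd.Series(
            [
                yield_reduction(o, l)
                for o, l in zip(means["optimal"]["GY"], means["low_n"]["GY"])
            ],
            index=means["optimal"].index,
            name="percent_yield_reduction",
        )
        yrd.to_csv(outdir / "yield_reduction.csv", index_label="hybrid")

        # classification must use the marker-inferred groups; the simulation
        # truth only fills in parents absent from the panel assignment
        group_map = dict(parent_groups)
        group_map.update(
            zip(assignment.assignments["individual"], assignment.assignments["group"])
        )
        be_out = {}
        yield_cols = {
            "low_n": means["low_n"]["GY"],
            "optimal": means["optimal"]["GY"],
            "across": (means["low_n"]["GY"] + means["optimal"]["GY"]) / 2.0,
        }
        parents = means["low_n"][["male", "female"]]
        cross_types = classify_crosses(parents, group_map)
        be_tables = []
        for cond, yields in yield_cols.items():
            terc = yield_terciles(yields)
            be = breeding_efficiency(terc, cross_types)
            be_out[cond] = be.be
            tb = be.table.reset_index()
            tb.insert(0, "condition", cond)
            be_tables.append(tb)
        pd.concat(be_tables, ignore_index=True).to_csv(
            outdir / "breeding_efficiency_counts.csv", index=False
        )
        (outdir / "breeding_efficiency.json").write_text(json.dumps(be_out))

    report = RunReport(
        version=__version__,
        seed=config.seed,
        qc_counts=qc_counts,
        panel_summary={
            "mean_heterozygosity": summ.mean_heterozygosity,
            "homozygous_marker_fraction": summ.homozygous_marker_fraction,
            "mean_gene_diversity": float(stats["gene_diversity"].mean()),
        },
        selected_k=selected_k,
        assignment_counts=assignment.counts,
        tree_cut_counts=pd.Series(tree_groups).value_counts().to_dict(),
        pcoa_percent_variance=[float(x) for x in ord_.proportion_explained[:5]],
        repeatability=rep_out,
        mi_top=list(mi.index[:5]),
        yield_reduction_mean=float(yrd.mean()),
        breeding_efficiency=be_out,
        started=started,
        elapsed_s=time.time() - t0,
    )
    report.to_json(outdir / "run_report.json")
    return report


def _simulated_trials(
    config: PipelineConfig, g: GenotypeMatrix, truth, assignment
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Pick NCII parents from the panel and simulate all trait trials.

    Parents are drawn (seeded) from the panel individuals; the simulation's
    heterosis uses the *true* latent groups while downstream cross
    classification uses the marker-inferred assignment — exactly the
    situation breeding efficiency is meant to probe.
    """
    tc = config.trial
    n_parents = tc.n_sets * (tc.males_per_set + tc.females_per_set)
    if n_parents > g.n_individuals:
        raise ValueError(
            f"trial design needs {n_parents} parents but the panel has "
            f"{g.n_individuals} individuals"
        )
    rng = np.random.default_rng(derive_seed(config.seed, "parents"))
    chosen = rng.choice(g.n_individuals, size=n_parents, replace=False)
    ids = [g.individual_ids[i] for i in chosen]
    males, females, pos = [], [], 0
    for _ in range(tc.n_sets):
        males.append(ids[pos : pos + tc.males_per_set])
        pos += tc.males_per_set
        females.append(ids[pos : pos + tc.females_per_set])
        pos += tc.females_per_set
    if truth is not None:
        true_groups = {
            g.individual_ids[i]: truth.group_labels[i] for i in range(g.n_individuals)
        }
    else:  # no ground truth: use the marker-derived assignment
        true_groups = dict(
            zip(assignment.assignments["individual"], assignment.assignments["group"])
        )
    trials = simulate_trials(config, true_groups, males, females)
    return trials, {p: true_groups[p] for p in ids}
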