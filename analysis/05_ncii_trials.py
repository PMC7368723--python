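"""Simulate the NCII hybrid trials and run the combining-ability analysis.

Draws 48 parents from the simulated panel (six sets of 4 males x 4
females, 96 single crosses), simulates every trait under low-N and
optimal research conditions over four environments x two replicates, and
runs the NCII ANOVA, GCA/SCA estimation and repeatability per trait.
Writes the tidy trial table and all result tables under results/trials/.
Found: grain-yield repeatability near the configured 0.75 and a clear
male/female GCA + SCA partition of the hybrid variation.
"""

import json
from pathlib import Path

import pandas as pd

import heterotic as ht
from heterotic.pipeline import simulate_trials

IN_DOSAGE = Path("results/diversity/filtered_dosage.csv")
IN_TRUTH = Path("results/panel/panel_truth.json")
OUT = Path("results/trials")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    g = ht.read_genotypes(IN_DOSAGE, "dosage_csv")
    truth = json.loads(IN_TRUTH.read_text())
    true_groups = dict(zip(g.individual_ids, truth["group_labels"]))

    cfg = ht.PipelineConfig(seed=SEED)
    import numpy as np

    rng = np.random.default_rng(ht.derive_seed(SEED, "parents"))
    tc = cfg.trial
    n_parents = tc.n_sets * (tc.males_per_set + tc.females_per_set)
    ids = [g.individual_ids[i]
           for i in rng.choice(g.n_individuals, n_parents, replace=False)]
    males, females, pos = [], [], 0
    for _ in range(tc.n_sets):
        males.append(ids[pos:pos + tc.males_per_set])
        pos += tc.males_per_set
        females.append(ids[pos:pos + tc.females_per_set])
        pos += tc.females_per_set

    trials = simulate_trials(cfg, true_groups, males, females)
    trials.to_csv(OUT / "trials.csv", index=False)
    print(f"trials: {len(trials)} plot records, "
          f"{trials.groupby(['set', 'male', 'female']).ngroups} hybrids")

    anova_frames, rep_rows = [], []
    for cond in ("low_n", "optimal"):
        sub = trials[trials["condition"] == cond]
        for trait in sorted(sub["trait"].unique()):
            an = ht.ncii_anova(sub, trait)
            tb = an.table.reset_index()
            tb.insert(0, "trait", trait)
            tb.insert(0, "condition", cond)
            anova_frames.append(tb)
            vc = ht.repeatability(sub, trait)
            rep_rows.append({"condition": cond, "trait": trait,
                             "repeatability": vc.repeatability})
    pd.concat(anova_frames, ignore_index=True).to_csv(OUT / "anova.csv", index=False)
    rep = pd.DataFrame(rep_rows)
    rep.to_csv(OUT / "repeatability.csv", index=False)
    print(rep.pivot(index="trait", columns="condition",
                    values="repeatability").round(2))

    ca = ht.combining_ability(trials[trials["condition"] == "low_n"], "GY")
    ca.gca_male.to_csv(OUT / "gca_male_lown.csv", index=False)
    ca.gca_female.to_csv(OUT / "gca_female_lown.csv", index=False)
    ca.sca.to_csv(OUT / "sca_lown.csv", index=False)


if __name__ == "__main__":
    main()
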