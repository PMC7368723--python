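"""Base index, yield reduction and breeding efficiency of the marker groups.

Combines the trial entry means with the marker-derived group assignment:
ranks hybrids by the low-N multiple-trait base index, computes percent
yield reduction per hybrid, and evaluates breeding efficiency under
low-N, optimal and across conditions.  Writes ranked tables and the BE
summary under results/selection/.  Found: inter-group crosses dominate
the top yield tercile wherever the simulated heterosis acts, and BE sits
in the range the formula permits (its ceiling is 75% when every hybrid is
classified and terciles are equal — see docs/methods.md).
"""

import json
from pathlib import Path

import pandas as pd

import heterotic as ht

TRIALS = Path("results/trials/trials.csv")
ASSIGN = Path("results/structure/group_assignment.csv")
OUT = Path("results/selection")


def entry_means(trials: pd.DataFrame, cond: str) -> pd.DataFrame:
    sub = trials[trials["condition"] == cond]
    means = None
    for trait in sorted(sub["trait"].unique()):
        hm = ht.hybrid_means(sub, trait).set_index("hybrid")
        if means is None:
            means = hm[["set", "male", "female"]].copy()
        means[trait] = hm["mean"]
    return means


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    trials = pd.read_csv(TRIALS)
    assign = pd.read_csv(ASSIGN)
    groups = dict(zip(assign["individual"], assign["group"]))

    low = entry_means(trials, "low_n")
    opt = entry_means(trials, "optimal")

    mi = ht.multiple_trait_index(low[list(ht.MI_TRAITS)])
    mi.to_csv(OUT / "multiple_trait_index.csv", index_label="hybrid")
    print("top five hybrids by low-N base index:")
    print(mi["MI"].head().round(2))

    yrd = pd.Series(
        [ht.yield_reduction(o, l) for o, l in zip(opt["GY"], low["GY"])],
        index=opt.index, name="percent_yield_reduction",
    )
    yrd.to_csv(OUT / "yield_reduction.csv", index_label="hybrid")
    print(f"yield reduction: {yrd.min():.0f}%-{yrd.max():.0f}% "
          f"(mean {yrd.mean():.0f}%)")

    kinds = ht.classify_crosses(low[["male", "female"]], groups)
    be_out = {}
    for cond, yields in {
        "low_n": low["GY"],
        "optimal": opt["GY"],
        "across": (low["GY"] + opt["GY"]) / 2.0,
    }.items():
        terc = ht.yield_terciles(yields)
        be = ht.breeding_efficiency(terc, kinds)
        be_out[cond] = be.be
        be.table.reset_index().to_csv(OUT / f"be_counts_{cond}.csv", index=False)
        print(f"{cond}: BE = {be.be:.2f}% "
              f"(inter {be.hy_intergh}/{be.tn_intergh} high, "
              f"intra {be.ly_intragh}/{be.tn_intragh} low)")
    (OUT / "breeding_efficiency.json").write_text(json.dumps(be_out))


if __name__ == "__main__":
    main()
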