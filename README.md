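# heterotic

Marker diversity, heterotic-group discovery and hybrid-performance
analysis for inbred breeding panels.

A maize breeding programme that has genotyped a panel of inbred lines
with genome-wide biallelic SNPs (e.g. DArTseq) and field-tested hybrids
derived from them faces one chained question: do the markers reveal
genetically distinct groups, and do crosses *between* those groups
out-yield crosses *within* them?  This package implements that workflow
end to end, for breeders and quantitative geneticists:

* **Marker QC** — call-rate > 0.80, missingness ≤ 0.10, allele frequency
  in [0.05, 0.95], applied in that order, with a per-stage report.
* **Diversity statistics** — per-marker major allele frequency, gene
  diversity D = 1 − p² − q², PIC = D − 2p²q², observed heterozygosity,
  and a panel summary.
* **Genetic structure** — Nei's D_A distance
  (1 − mean over loci of Σ_a √(x_a y_a)), UPGMA dendrograms with
  1000-replicate locus-bootstrap supports and a k-group cut, principal
  coordinate analysis, and an admixture model
  g_il ~ Binomial(2, Σ_k q_ik f_kl) fitted by EM, with K selected by the
  Evanno statistic ΔK = M[|L(K−1) − 2L(K) + L(K+1)|]/S[L(K)] and
  individuals assigned to groups at a 0.70 membership threshold.
* **NCII quantitative genetics** — balanced North Carolina design II
  ANOVA partitioning hybrids into male GCA, female GCA and SCA, the
  classical combining-ability estimators, method-of-moments variance
  components and entry-mean repeatability
  R = σ²_G/(σ²_G + σ²_GE/E + σ²_e/(rE)).
* **Selection indices** — the low-N base index
  MI = 2·Z_GY + Z_EPP − Z_ASI − Z_PASP − Z_EASP − Z_STGR, percent yield
  reduction 100(y_opt − y_lowN)/y_opt, yield terciles, inter/intra-group
  cross classification, and breeding efficiency
  BE = ([HYINTERGH/TNINTERGH·100] + [LYINTRAGH/TNINTRAGH·100])/2.
* **Synthetic data** — Balding–Nichols genotype panels and balanced NCII
  trials with known ground truth, so every stage is testable without any
  restricted download.

See `docs/methods.md` for the models, conventions and known limitations
(including why BE has a sharp 75% ceiling under equal terciles).

## Worked example

```python
import heterotic as ht

# a 70-line, five-group panel with 4 admixed lines (ground truth known)
g, truth = ht.simulate_panel(ht.PanelConfig(n_markers=2000, seed=3))
g_qc, report = ht.filter_markers(g)
print(report.n_input_markers, "->", report.n_after_freq)   # 2000 -> 1908

stats = ht.marker_stats(g_qc)
print(round(stats["gene_diversity"].mean(), 3))            # 0.377

d = ht.nei_distance(g_qc)
tree = ht.upgma(d)
print(sorted(tree.cut(5).values())[-1])                    # 5 groups

fit = ht.fit_admixture(g_qc, k=5, seed=11, max_iter=2000, tol=1e-3)
assign = ht.assign_groups(fit, g_qc.individual_ids)
print(assign.n_mixed)                                      # 4
```

The numbered drivers under `analysis/` run the full study-scale analysis
(8171 markers, 1000 bootstraps, K = 1..12 with 10 replicate runs, 96
hybrids under two research conditions) and write every table under
`results/`:

```
python analysis/01_simulate_panel.py
python analysis/02_marker_qc_diversity.py
python analysis/03_distance_tree_pcoa.py
python analysis/04_structure_deltak.py
python analysis/05_ncii_trials.py
python analysis/06_selection_breeding_efficiency.py
```

A `heterotic` command-line interface exposes each stage as a subcommand
(`simulate-panel`, `qc`, `diversity`, `distance`, `tree`, `pcoa`,
`structure`, `delta-k`, `assign`, `anova`, `repeatability`, `mi`,
`breeding-efficiency`, `run-all`); `heterotic --help` lists them.

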