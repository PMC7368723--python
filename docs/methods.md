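# Methods

This package implements the statistical workflow a maize breeding
programme runs when a panel of inbred lines has been genotyped with a
genome-wide biallelic SNP assay (e.g. DArTseq) and hybrids derived from
those inbreds have been evaluated in multi-environment trials: marker QC,
diversity statistics, heterotic-group discovery (distance/tree, admixture
model, ordination), North Carolina design II (NCII) combining-ability
analysis, and the selection indices that connect the marker groups to
hybrid performance.  Because the motivating study's deposited data are
restricted to authorised users, the package ships a synthetic-data module
that generates panels and trials with known ground truth; every claim the
test suite makes is a recovery or consistency statement on those
simulations, or an exact reproduction of published count tables.

## Genotype model and QC

Genotypes are dosages of the alternative allele (0/1/2, missing allowed).
The marker-retention cascade runs in a fixed order: (1) keep markers with
call rate strictly above 0.80; (2) drop markers with missing fraction
strictly above 0.10; (3) keep markers whose alternative-allele frequency
lies in the closed interval [0.05, 0.95].  Stage 1 and 2 overlap
logically (call rate > 0.80 implies missingness < 0.20) but are kept as
separate stages so the report shows where each marker fell.  The
frequency bounds are treated as closed — a marker at exactly 0.05 is
retained — and the filter is equivalent to a minor-allele-frequency floor
for biallelic loci.  The filter is idempotent.

## Diversity statistics

With p the alternative-allele frequency over non-missing calls and
q = 1 − p: major allele frequency max(p, q); gene diversity (expected
heterozygosity) D = 1 − p² − q²; polymorphic information content in the
Botstein form for two alleles PIC = D − 2p²q²; observed heterozygosity
the fraction of dosage-1 calls.  No small-sample (n/(n−1)) correction is
applied to D: the plain statistic is what marker-summary software
conventionally reports for such panels, and its biallelic maximum is then
exactly 0.500 (PIC 0.375) at p = 0.5.  The panel summary also reports the
share of markers whose observed heterozygosity is below 0.05 ("markers
identifying over-95%-homozygous individuals").

## Genetic distance, UPGMA, bootstrap, PCoA

The default distance is Nei's D_A (1983 frequency distance).  Per
individual and locus the within-individual allele frequencies are (1,0),
(0.5,0.5), (0,1) for dosages 0/1/2, and

    D_A(x, y) = 1 − (1/L_xy) Σ_loci Σ_alleles √(x_a y_a),

with L_xy the pairwise-complete locus count (no imputation; per-pair
renormalisation keeps D in [0,1]).  The sum of square-root products is a
dot product of per-locus √frequency vectors, so the whole matrix is one
matrix product — this is also why the locus bootstrap at 1000 replicates
is affordable.  Nei's 1972 standard distance (−ln of the normalised
identity) is available behind a flag for comparison; D_A is the default.

UPGMA merges the pair of clusters with smallest average distance; the
merge height is half that average (ultrametric convention, so two leaves
at distance d merge at height d/2).  Ties are broken toward the
lexicographically smallest pair of cluster representative labels
(representative = smallest member label), making runs bit-reproducible.
Bootstrap supports resample loci (columns) with replacement; the support
of a clade of the point-estimate tree is the fraction of replicate trees
containing it, and the root clade has support 1 by convention.  The
k-group cut undoes the k−1 latest merges; height ties across the cut are
resolved by merge order with a warning.

PCoA is classical Gower scaling: eigendecomposition of the double-centred
−½D∘D, coordinates scaled by √eigenvalue on the positive axes.  Negative
eigenvalues (D_A is not exactly Euclidean) are reported unmodified and
their axes dropped — no Cailliez/Lingoes correction, preferring
transparency over adjustment.  Percent variance is computed over the
positive eigenvalues only, so retained-axis percentages sum to at most
100.

## Admixture model, K selection, assignment

The latent-group model is the classic admixture likelihood: genotype
g_il ~ Binomial(2, Σ_k q_ik f_kl) with Q rows on the simplex and group
frequencies F.  It is maximised by expectation–maximisation from a seeded
random start (Q rows uniform-Dirichlet, F jittered around sample
frequencies); missing calls contribute nothing.  A run may optionally
advance several random starts for a 50-iteration burn-in and continue
only the best — K-sweep replicates use three starts each, which makes
poor local optima rare while leaving the winning start (and hence the
replicate-to-replicate spread) seed-dependent.  The E/M steps factorise
into matrix products, F is clamped to [1e−6, 1−1e−6] to keep the
likelihood finite, and the log-likelihood is checked for monotonicity at
every iteration (the run aborts if it ever decreases beyond numerical
tolerance).  A Bayesian MCMC engine would instead produce per-run LnP(D)
estimates; here each replicate run's maximized log-likelihood plays that
role.  This is deterministic given the seed and desk-scale, and the
downstream K-selection and assignment logic is engine-agnostic.

K is selected by the Evanno statistic over replicate runs per K:

    ΔK = M[|L(K−1) − 2L(K) + L(K+1)|] / S[L(K)],

with M the replicate mean and S the replicate standard deviation
(ddof = 1).  When replicate counts are equal across the three K values
the second difference is computed per replicate index before averaging
the absolute values; otherwise replicate means are differenced.  A K with
zero replicate SD is flagged undefined and excluded from the argmax.

Two numerical conventions matter here and are deliberate:

* **Sweep stopping rule.**  Replicate runs in a K-sweep stop when the
  per-iteration log-likelihood gain falls below 1.0 (cap 3000
  iterations).  Between-K log-likelihood differences on informative
  panels are in the thousands, so this loses nothing for model selection,
  and it leaves each run's end point mildly start-dependent — the source
  of the replicate-to-replicate spread that the ΔK denominator needs.  A
  fully deterministic optimiser run to machine convergence makes S[L(K)]
  collapse at any K whose optimum is unique, and ΔK degenerates.
* **Known limitation.**  ΔK inherits its documented artifact for
  unbalanced group sizes: when groups are very unequal, the
  log-likelihood increments decline smoothly before the true K and the
  statistic can peak at K = 2.  On balanced five-group panels the
  increments are flat up to the true K and ΔK identifies it with peaks
  three orders of magnitude above the background; the test suite asserts
  exactly that (9 of 10 seeded 70 × 2000 panels at F_ST 0.3).  On the
  default panel, which emulates a real programme's unequal groups, the
  persisted LnP(D) table should be read alongside ΔK.

Individuals whose largest ancestry proportion reaches the 0.70 threshold
are assigned to that group; the rest form a "mixed" group.  A reader for
STRUCTURE-format output files lets externally produced runs feed the same
ΔK and assignment code.  Replicate label switching is resolved for
reporting only, by optimal assignment on Q-column overlaps.

## NCII analysis

Trials are tidy long tables (set, male, female, env, rep, trait, value),
validated for balance before analysis; incomplete-block (lattice)
adjustment is out of scope and the model is a randomised complete block
per environment.  The hybrid line is partitioned into male GCA, female
GCA and SCA within sets (pooled over sets); hybrids are fixed,
environments and replicates random, so hybrid terms are tested over their
environment interactions and interactions over the pooled error.
Combining abilities are the classical factorial-means estimators over
environment × replicate means within set, with their zero-sum
constraints.  Variance components use the expected mean squares of the
balanced layout (method of moments): σ²_e = MS_error,
σ²_GE = (MS_GxE − MS_error)/r, σ²_G = (MS_hyb − MS_GxE)/(rE), negatives
truncated to zero with a flag.  REML would coincide in expectation on
these balanced designs; the moment estimators are deterministic and
dependency-free.  Entry-mean repeatability is the broad-sense ratio
R = σ²_G / (σ²_G + σ²_GE/E + σ²_e/(rE)); the suite checks its recovery
against the closed form R ≈ 0.727 at (σ²_G, σ²_GE, σ²_e, E, r) =
(1, 0.5, 2, 4, 2) over 500 simulated trials.

## Selection indices and breeding efficiency

The low-N base index standardises entry means over the hybrid panel
(sample SD) and combines them as MI = 2·Z_GY + Z_EPP − Z_ASI − Z_PASP −
Z_EASP − Z_STGR; standardisation uses entry means under low-N only.
Percent yield reduction is 100(y_opt − y_lowN)/y_opt (the optimal-yield
denominator is what reproduces the published per-hybrid percentages).

Breeding efficiency ranks hybrids by yield, splits them into three equal
terciles (count must be divisible by 3; ties broken by stable input
order), classifies each cross inter- or intra-group from its parents'
assigned marker groups (a mixed-group parent makes the cross inter-group,
since it shares no single assigned group with its mate), and computes

    BE = ([HYINTERGH/TNINTERGH × 100] + [LYINTRAGH/TNINTRAGH × 100]) / 2

with high = tercile 1 and low = tercile 3 only — the unique reading that
reproduces the published values (71.41 / 69.69 / 72.16) from their count
tables exactly.

**Ceiling.**  Under this definition BE cannot reach 100 when every hybrid
is classified: all inter-group crosses in tercile 1 requires
n_inter ≤ n/3, all intra-group crosses in tercile 3 requires
n_intra ≤ n/3, yet n_inter + n_intra = n.  The sharp upper bound is 75%,
attained when the intra fraction is exactly 1/3 (or 2/3) under total
separation.  The published values (69.7–72.2) sit just below this
ceiling, corroborating the analysis.  The separation-limit simulation in
the suite therefore asserts attainment of the composition ceiling, and
the permutation-null check asserts that BE centres on the shuffled-
tercile expectation when heterosis is absent.

## Synthetic data: what it emulates, what it does not

The panel generator emulates a 70-line early-maturing tropical maize
inbred panel: five latent groups (default sizes 25/8/14/13/6) plus 4
admixed lines, 8171 biallelic markers, 5.6% residual heterozygosity, 5%
missing calls.  Group divergence follows the Balding–Nichols model — per
locus an ancestral frequency p ~ U(0.1, 0.9) and group frequencies
Beta(p(1−F_ST)/F_ST, (1−p)(1−F_ST)/F_ST) with default F_ST 0.30, chosen
to put the simulated Nei-distance range near the published 0.02–0.46.
Inbreds are homozygote draws with a heterozygote flip (matching the
~94.4% observed homozygosity with one parameter) rather than explicit
selfing pedigrees; admixed lines draw Q from a symmetric Dirichlet and a
per-marker group of origin from Q.  Loci are unlinked and substitution
classes are assigned uniformly.  Not emulated: linkage disequilibrium,
pedigree structure, selection during inbreeding, allele-frequency
ascertainment of the genotyping platform, genotyping error.  Passing
tests therefore demonstrate correctness of the estimators under the
stated model, not robustness to those real-data features.

The trial generator produces balanced NCII tables
y = μ + E_e + g_m + g_f + s_mf + (ge)_{mf,e} + ε + δ·1[group(m)≠group(f)]
with independent Gaussian effects.  Defaults emulate the study's
96-hybrid grain-yield trials (six sets of 4 × 4, four environments =
2 locations × 2 years, two replicates, μ ≈ 3540 kg/ha under low N):
variance components (σ²_GCAm, σ²_GCAf, σ²_SCA, σ²_GE, σ²_e) =
(1.0, 1.0, 1.0, 1.2, 5.6) × 10⁵ give entry-mean repeatability ≈ 0.75 at
E = 4, r = 2 (the published low-N yield value), and the inter-group
heterosis offset δ = 800 kg/ha is of the order of the genetic standard
deviation.  Score traits (plant/ear aspect, stay-green) are simulated on
rescaled variances and clipped to the 1–9 scale; a mixed × mixed cross
counts as heterotic (neither parent has an assigned group).  The study's
exact parent count behind "96 crosses from 24 inbreds" is not fully
recoverable from the design description; six sets of 4 × 4 reproduces the
hybrid count, which is what the downstream indices consume.

## Pipeline, seeds, problem sizes

`run_pipeline` chains QC → diversity → distance/tree/PCoA →
K-sweep/ΔK/assignment → trials → ANOVA/repeatability → MI → BE, persists
every intermediate table in open formats (CSV/JSON/Newick/VCF), and fans
a single master seed out to fixed stage-specific seeds, so a rerun is
numerically identical.  Defaults follow the study's analysis settings
(filters 0.80/0.10/[0.05, 0.95], K 1–12 with 10 replicates, 1000
bootstraps, 0.70 threshold).  The test suite exercises the same code on
reduced problem sizes chosen as the package's own desk-scale defaults:
panels of 200–2000 markers, sweeps to K = 8 with 5 replicates, 20–100
bootstrap replicates, 6 × 6 or smaller trial designs; the ΔK recovery
experiment uses the full 70 × 2000 panels described above, and the
repeatability recovery uses 500 trial replicates.
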