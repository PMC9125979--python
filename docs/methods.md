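# Methods

This note documents the models and procedures implemented in `moltax`, the
parameters that matter, the numerical choices, and what the synthetic data
can and cannot show.

## Synthetic cohort model

The generator emulates a whole-blood RNA-seq case/control cohort whose
disease heterogeneity is modular. Gene g in sample s has negative binomial
counts with mean

    mu(g, s) = 2^( b_g + A[e(s), m(g)] + L[m(g), s] ) * c_s

and variance `mu + phi * mu^2`, where

- `b_g ~ Uniform(3, 9)` is the baseline log2 mean (counts roughly 8–512;
  no expression scale is imposed by the problem, so a broad uniform is
  used);
- `A` is the endotype × module **activation matrix** (log2 units);
  `e(s)` is the sample's endotype (controls contribute 0) and `m(g)` the
  gene's planted module (background genes contribute 0);
- `L[m, s] ~ N(0, 0.3)` is a per-module latent sample factor, so module
  genes are co-expressed *within* groups as well as between them — the
  correlation structure module detection consumes;
- `c_s = exp(N(0, 0.2))` is a lognormal library-size factor;
- `phi = 0.1` is a single shared dispersion, a stylized bulk-RNA-seq value.

The default cohort has 120 patients, 58 controls, 15,000 genes, nine
modules of sizes 300…80 (1,600 planted genes) and five endotypes with
proportions (0.242, 0.267, 0.25, 0.091, 0.15), i.e. group sizes
(29, 32, 30, 11, 18) at n = 120.

**Activation design.** Each endotype has a disjoint two-sided fingerprint:
one over-expressed primary module (+2.0 to +3.0) and, for four of the five
endotypes, one under-expressed secondary module (−2.0 to −2.2); the
smallest endotype carries a single strong (+3.0) primary, mirroring the
strongly shifted neutrophil-like signature of small active-nephritis
groups. Amplitudes are size-compensated so every module's between-sample
activation variance `a^2 p (1-p)` is comparable (~0.5 log2² units), which
keeps all nine modules detectable at one correlation cutoff. Because no
gene is moved by more than one endotype, differential signatures are
endotype-exclusive, and a planted drug "reverser" has a unique, identifiable
target — an earlier design with modules shared between endotype pairs made
reversers intrinsically ambiguous (a drug opposing a shared module
legitimately reverses two groups).

**What the generator does not model:** treatment effects, interferon or any
other named pathway biology, a case/control "susceptibility" offset shared
by all patients, gene-length or GC effects, batch structure, outlier
samples, or single-cell structure. Passing recovery tests on this model
shows the pipeline recovers modular NB signal at realistic depth and
dispersion; it does not certify performance on real whole blood, where
module boundaries are fuzzy and cell-composition gradients dominate.

**Drug library.** A reverser for endotype e takes e's top 400 genes by
|Wald| and sets log2FC to the negated endotype log2FC rescaled to mean
|log2FC| = `reversal_effect`, plus `N(0, noise_sd)` noise — an exact
anti-signature when `noise_sd = 0`. Neutral drugs draw random tested genes
with `N(0, 1)` log2FC (the 1.0 log2-unit scale is a fixed design constant).
Exactly `round(frac_significant * n)` rows per signature receive p-values
below 0.05, assigned to the largest-|log2FC| rows; the remainder are
uniform on (0.05, 1]. `genes_per_signature >= 301` is enforced so the
top-300 preprocessing cut is always exercised.

## Co-expression modules

Counts are normalized by median-of-ratios size factors (rescaled to
geometric mean 1; total-count fallback with a warning when no gene is
expressed everywhere) and transformed to `log2(count/sf + 1)`. The 10,000
most variable genes (sample variance of normalized values, ties by gene id)
enter the network; edges connect pairs with Pearson r ≥ cutoff. Positive
correlations only: the co-expression "color" convention, under which
anti-correlated genes separate into different modules on their own.

Modules are communities from seeded Louvain modularity maximization on the
unweighted graph (5 restarts, best modularity kept; deterministic given the
seed). Communities below `min_size = 20` genes go to "unassigned", and
surviving modules are named from a fixed color palette in decreasing-size
order. On random graphs of ≤ 9 nodes the returned partition attains the
exhaustively enumerated modularity optimum (test oracle: all set
partitions); this equals — not merely approaches — the optimum on the
tested families.

**Cutoff choice.** `choose_cutoff` scans candidates (0.50 … 0.90 by 0.05)
and returns the smallest with scale-free degree-distribution fit R² ≥ 0.8
*and* ≥ 50% non-isolated genes, else the R²-maximizing candidate; the
per-candidate diagnostics (R², nodes, edges, retention) are always
emitted. This heuristic targets empirical co-expression data, whose degree
distributions are heavy-tailed. The synthetic model is a block model — its
graphs are *not* scale-free — so the synthetic study pins `cutoff = 0.6`,
derived from the design: within-module correlation ≈ shared variance /
total variance = (a²p(1−p) + 0.3²) / (a²p(1−p) + 0.3² + noise) ≈ 0.6–0.7,
while background pairs are ~N(0, 1/√178). Users analyzing real data should
prefer `cutoff="auto"` and inspect the diagnostics.

## Stratification

Per-sample module score: mean over the module's genes of the cohort-
centered normalized value. This makes sample-level clustering and
group-level GFC two views of one quantity: the group GFC is the within-
group mean score, capped at ±2 after averaging (the usual heatmap
convention; the cap is reachable, e.g. a +3-activated module in its own
group). Controls are excluded from clustering but included in the gene-wise
centering, so scores are deviations from the full-cohort scale.

Patients are clustered by Ward/Euclidean agglomerative clustering; k
maximizes the mean silhouette over k = 2…10 (ties → smallest k; all-equal
rows → k = 1 with a warning). Clusters are renamed G1…Gk by decreasing
size. Module annotation is hypergeometric over-representation (upper tail,
BH across all module × gene-set pairs — BH is the only multiple-testing
procedure used anywhere in the package). Clinical association uses
Kruskal–Wallis for numeric features and Chi-squared (no continuity
correction) for categorical ones; constant features are flagged with p = 1
rather than erroring.

## Differential expression

A deliberately simplified NB Wald test stands in for a full DE framework:
per-gene method-of-moments dispersion pooled across the two groups (floored
at 1e-8), no dispersion shrinkage, no outlier or independent filtering.
Effects are `log2((mu_a + 0.5)/(mu_b + 0.5))` on normalized means — the
0.5 pseudo-count stabilizes low-count fold changes — with a delta-method
standard error including the size-factor correction, two-sided normal
p-values and BH adjustment over tested genes. Genes with zero counts in
both groups are excluded and flagged. Measured calibration: null
false-positive rate 0.051 at p < 0.05 over 2,000 genes (50 vs 50 samples);
a planted 4-fold gene at dispersion 0.1 is recovered at log2FC ≈ 2 with
padj ≪ 0.05. The swap-groups antisymmetry is exact; scale invariance under
sample doubling holds to ~1e-3 (the additive pseudo-count interacts with
the global 2^(1/n) rescaling median-of-ratios leaves, bounding the residual
at (0.5/mu)(2^(1/n) − 1)).

## Drug-reversal scoring (ΔNES)

Drug signatures keep rows with raw p < 0.05 (the significance convention of
perturbation databases' signature tables), sorted by decreasing |log2FC|
(ties by gene id), truncated to the top 300, and split by sign into up/down
sets; zero-log2FC rows are discarded.

Preranked GSEA uses the weighted Kolmogorov–Smirnov statistic with weight
exponent 1: walking down the ranking, hits add |score|/Σ_set|score| and
misses subtract 1/(N − |set|); the ES is the deviation of largest magnitude
(ties → positive). The null is `n_perm = 1000` random same-size gene sets;
NES = ES / mean(|null ES| of matching sign), and the p-value is the
one-sided same-sign permutation tail with +1 smoothing. On 8-gene rankings
the Monte-Carlo NES and p match the exhaustive null over all C(8,3) sets
within three standard errors.

ΔNES = NES(down) − NES(up). Both sides share one null seed, so identical
up/down sets cancel exactly; a missing side contributes 0 with a flag.
The ranking metric is the endotype signature's Wald statistic
(sign(log2FC)·(−log10 p) is available as an alternative ranking input by
passing a different score Series). Each (signature, endotype) cell derives
its own seed from a CRC32 of (master seed, signature id, endotype), so the
matrix is reproducible and independent of evaluation order; drug-set genes
absent from the ranking are dropped per cell and logged.

Drugs are clustered by k-means (10 restarts per k) on their per-endotype
ΔNES vectors. The elbow is the interior k maximizing the *relative*
curvature (WSS(k−1) − 2·WSS(k) + WSS(k+1)) / WSS(k) — the point after which
the curve flattens relative to its own level. The absolute second
difference was rejected: on a curve like 600 → 150 → 0.06 → … it peaks at
the first large drop (k = 2) even when three well-separated clusters
plainly exist; the relative form selects k = 3 there. Per-endotype
candidates are the top-ΔNES members of the cluster with the highest mean
ΔNES for that endotype.

## Repurposing and druggability

Platform filters are boundary-inclusive per their "≤" definitions:
concordance ≤ −0.5 on [−1, 1] scores, connectivity ≤ −50 on [−100, 100];
out-of-range records are rejected with a warning. Group-exclusive sets
subtract the union of all other groups; the full Venn-region table is
emitted and partitions the union.

The druggability re-ranking is **CoDReS-inspired** (the original algorithm
is not public; output headers carry the `codres_inspired_` prefix): the
functional score is min(1, −log10(p)/10) of the hypergeometric
target/disease-gene overlap (the /10 scale caps the score at p = 1e-10 and
is configurable); the structural score is the fraction of passed rules
among the evaluable ones of MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10
(Lipinski) and rotatable bonds ≤ 10, TPSA ≤ 140 Å² (Veber). The combined
score is the mean of the available components; compounds missing all
descriptors are ranked on the functional score alone and flagged.
Descriptors are inputs — nothing is computed from chemical structure.

## Problem sizes and determinism

The recovery studies run the full default cohort (15,000 × 178, 10,000
network genes) over five seeds for module/endotype recovery and drug
scoring (20-signature library at the weakest planted reversal the recovery
property is stated for: effect 1.5, noise 0.25); calibration uses 2,000
null genes at 50 vs 50. All randomness flows from explicit seeds: the
generators from their spec seed, Louvain and k-means from `random_state`,
and every GSEA cell from its derived CRC32 seed, so identical inputs and
seeds reproduce outputs byte-for-byte.

## Known limitations

- The NB Wald stand-in is anti-conservative for very small groups and has
  no dispersion shrinkage; it is calibrated at the cohort sizes used here,
  not at n ≤ 5 per group.
- The scale-free cutoff heuristic is inapplicable to block-structured
  correlation (see above); it is retained for empirical data with
  diagnostics, not used by the synthetic study.
- ES ties at |max| = |min| resolve to the positive deviation; with
  continuous scores this is measure-zero.
- The functional/structural druggability combination approximates the
  stated ingredients of compound re-ranking tools, not any specific
  published scoring function.
- Group-exclusive compound sets are computed per endotype over pooled
  platforms; per-sublibrary resolution is not modeled.
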