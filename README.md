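# moltax

Data-driven molecular taxonomy of systemic lupus erythematosus (SLE)
transcriptomes, and cluster-tailored *in silico* drug prediction.

SLE is clinically heterogeneous: patients who share a diagnosis differ in the
molecular processes driving their disease, and respond differently to the
same drugs. `moltax` implements the full analysis arc that turns a whole-blood
RNA-seq cohort into actionable patient subgroups:

1. **Co-expression modules** — the 10,000 most variable genes are connected
   by Pearson correlation (r ≥ cutoff) and partitioned into gene modules
   ("colors") by seeded Louvain community detection.
2. **Endotype stratification** — each sample is scored per module as the
   mean cohort-centered log2 expression of the module's genes; patients are
   clustered by Ward agglomerative clustering with silhouette-selected k,
   and each group's **group fold change** (GFC, the within-group mean module
   score capped at ±2) summarizes its fingerprint.
3. **Differential signatures** — every endotype is contrasted against the
   control pool with a negative-binomial Wald test (median-of-ratios size
   factors, method-of-moments dispersion, BH-adjusted p-values).
4. **Signature-reversal drug scoring** — a drug signature is reduced to its
   top-300 significant genes split into up/down sets; preranked GSEA against
   the endotype's Wald-statistic ranking gives a normalized enrichment score
   (NES) per set, and

   ΔNES = NES(down set) − NES(up set)

   is positive when the drug's transcriptional response opposes the disease
   signature. Drugs are k-means-clustered on their per-endotype ΔNES vectors
   (elbow-selected k) and candidates read from the best cluster per group.
5. **Repurposing and druggability** — platform score tables are filtered at
   concordance ≤ −0.5 (iLINCS-style) and connectivity ≤ −50 (CLUE-style),
   reduced to group-exclusive compound sets, and re-ranked by a
   CoDReS-inspired score that averages a functional component
   (hypergeometric overlap of drug targets with disease genes, mapped to
   min(1, −log10 p / 10)) with a structural component (fraction of passed
   Lipinski rule-of-five + Veber drug-likeness rules).

Because cohort-scale patient data are controlled-access, the package ships a
first-class **synthetic cohort generator** with full ground truth: negative
binomial counts (variance μ + φμ²), planted gene modules with
endotype-specific activation, lognormal library sizes, and a drug-signature
library with designed "reverser" drugs per endotype. Every downstream stage
is testable against the planted truth.

## Worked example

```python
from moltax import synthetic, pipeline, diffexp
from sklearn.metrics import adjusted_rand_score

cohort = synthetic.generate_cohort(synthetic.paper_default(seed=1))
res = pipeline.stratify_cohort(cohort.counts, cohort.patients, seed=1)

print(res.module_set.n_modules)          # 9
print(res.assignment.k)                  # 5
truth = cohort.sample_meta.set_index("sample_id").loc[
    cohort.patients, "true_endotype"]
print(adjusted_rand_score(truth, res.assignment.labels))  # 1.0
print(res.gfc.round(2).iloc[:2, :3])
```

On the default 120-patient / 58-control, 15,000-gene cohort this recovers
all **9** planted modules (gene-to-module adjusted Rand index ≈ 0.999),
clusters the patients into **5** endotypes that match the planted groups
exactly (ARI = 1.0), and the GFC table shows each group's module
fingerprint, e.g. `G1` at +1.62 on its primary module and −1.62 on its
suppressed module, and `G5` hitting the +2.00 cap on its strong primary.

Continuing with drug prediction:

```python
signatures = {
    endo: diffexp.de_test(
        cohort.counts,
        res.assignment.labels.index[res.assignment.labels == endo].tolist(),
        cohort.controls,
    )
    for endo in sorted(res.assignment.labels.unique())
}
lib = synthetic.generate_drug_library(
    synthetic.DrugLibrarySpec(n_drugs=20, seed=1), signatures)
drugs = pipeline.predict_drugs(
    cohort.counts, cohort.controls, res.assignment,
    library=lib.signatures, n_perm=1000, seed=1)
top = drugs.matrix.sort_values("delta_nes", ascending=False).head(1)
print(top[["signature_id", "endotype", "delta_nes"]])
```

The top-scoring (signature, endotype) pair is always a planted reverser
against its own target endotype (ΔNES ≈ 3–7 depending on the group's
signature strength; neutral drugs score near 0).

The same stages are available from the shell:

```bash
moltax simulate-cohort --preset paper-default --seed 1 --out run/
moltax modules --counts run/counts.tsv --cutoff 0.6 --out run/
moltax stratify --counts run/counts.tsv --meta run/sample_meta.tsv \
    --modules run/modules.gmt --out run/
moltax de --counts run/counts.tsv --meta run/sample_meta.tsv \
    --assignment run/assignment.tsv --out run/
moltax simulate-drugs --de-dir run/ --seed 1 --out run/library.tsv
moltax score-drugs --de-dir run/ --library run/library.tsv --out run/
```

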