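# cdp — computational drug prescription on cellular pathways across cancers

`cdp` implements a pathway-centric strategy for matching drugs to cancers.
Instead of asking whether a compound hits one protein, it asks whether the
compound *reverses* the expression signature of a whole dysregulated pathway
in a tumor type — and restricts attention to pathways that actually matter
for patient outcome. It is aimed at computational biologists working with
paired tumor/normal expression cohorts (TCGA-style), pathway gene-set
collections (GMT), clinical survival tables, and perturbation expression
compendia (connectivity-map-style treated/control instances).

## The model

**Pathway dysregulation (CNS).** For each cancer cohort, genes are ranked by
a tumor-vs-normal metric (signal-to-noise by default) and each pathway gene
set *S* is scored with the weighted Kolmogorov–Smirnov running sum
(enrichment score, ES ∈ [−1, 1]). The normalized enrichment score

&nbsp;&nbsp;&nbsp;&nbsp;NES = ES / mean(|ES_null| of matching sign)

with a permutation null (phenotype permutation for adequately sized cohorts,
gene-set permutation otherwise; 1,000 trials by default) gives the
pathways × cancers **CNS** matrix with empirical p-values and BH-FDR.

**Generality.** For pathway *i*, rank the *n* cancers ascending by NES
(r_ik = rank of cancer *k*), count significant enrichments w₁ (NES > 0,
p < 0.05) and depletions w₂ (NES < 0, p < 0.05), and form

&nbsp;&nbsp;&nbsp;&nbsp;a_i = w₁/(w₁+w₂) · Σ_{k enriched} r_ik/n
&nbsp;&nbsp;&nbsp;&nbsp;b_i = −w₂/(w₁+w₂) · Σ_{k depleted} (1 − (r_ik−1)/n)

The generality score S_i is a_i if |a_i| > |b_i|, b_i if smaller, 0 on ties;
|S_i| ≤ (n+1)/2, so at n = 20 a pathway significantly enriched in every
cancer scores exactly 10.5. Pathways also receive a mode-of-action label
(LoF = broadly depleted, GoF = broadly enriched, SoF = direction switches by
cancer) from consensus hierarchical clustering of the CNS (500 resamples at
80%, Euclidean distance, average linkage), with strong generality scores
overriding contradictory cluster labels.

**Prognostic pathways.** Each patient gets a per-pathway activation (PA)
score by single-sample GSEA (rank-based, exponent α = 0.25). For every
(pathway, cancer) the cohort is split at every observed PA value, each split
is tested by the log-rank test, and the smallest p wins; pathways reaching
p < 0.001 are prognostic — *favorable* when high activation predicts longer
survival, *adverse* otherwise.

**Prescription (PNS, PS).** Each drug instance (treated vs control ranking)
is scored for every pathway by the same GSEA machinery; the mean instance
NES is the drug's **PNS** for that pathway. The prescription score

&nbsp;&nbsp;&nbsp;&nbsp;PS = CNS − PNS

is large and positive when a drug pushes down an enriched pathway and large
and negative when it restores a depleted one. Candidate
(drug, pathway, cancer) triplets require the pathway to be prognostic in
that cancer and |CNS| > 1.5; drugs rank by |PS| and the filtered network is
exported as SIF or an edge table.

## Worked example

The package bundles nine reference drug–pathway scores for breast invasive
carcinoma (BRCA). Running `python examples/drug_prescription.py` recomputes
each PS from its CNS/PNS inputs:

```
drug             pathway                             CNS          PNS        PS
Lycorine         Basal_Transcription_Factors      1.2588    -1.966145   3.22494
Podophyllotoxin  Basal_Transcription_Factors      1.2588    -1.867784   3.12658
Cephaeline       Basal_Transcription_Factors      1.2588    -1.486685   2.74548
...
Thapsigargin     Arachidonic_Acid_Metabolism     -1.4763     2.044218  -3.52052
Demecolcine      Jak_Stat_Signaling_Pathway      -1.5188     1.720818  -3.23962
```

Basal transcription factors are enriched in BRCA tumors (CNS = +1.2588);
lycorine's perturbation signature depletes that pathway (PNS = −1.97), so
its PS of +3.22 is the strongest reversal of the nine. The depletion rows
read symmetrically: thapsigargin re-activates arachidonic-acid metabolism
(negative CNS, positive PNS, negative PS).

The other example scripts exercise each capability on synthetic data with
planted truths: `pathway_dysregulation.py` (CNS), `generality_and_moa.py`
(generality + clustering), `prognostic_pathways.py` (survival scan).

A `cdp` console script exposes each stage (`simulate`, `diffexpr`, `cns`,
`generality`, `moa`, `prognostic`, `prescribe`, `run`); see `cdp --help`.

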