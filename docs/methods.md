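# Methods

This note records the statistical procedures the package implements, the
defaults it ships, and the design decisions taken where the method family
leaves choices open.

## Enrichment scoring

The enrichment score is the weighted Kolmogorov–Smirnov running sum with
weight exponent 1: walking down the ranked list, a set member at position
*i* adds |m_i| / Σ_{j∈S} |m_j| and a non-member subtracts 1/(N − |S|); ES is
the signed maximum deviation, clipped to [−1, 1] against ~1-ulp cumsum
overshoot. If every member's metric is zero the hit weights fall back to
equal weights rather than dividing by zero.

*Ranking metric.* Tumor-vs-normal ranking uses signal-to-noise,
(μ_case − μ_ctrl)/(σ_case + σ_ctrl), with each σ floored at
max(0.2·|μ|, 0.2) so zero-variance genes cannot produce infinite metrics.
Cohorts with fewer than two samples in a class fall back to
log2 fold change on +1-pseudo-counted means. Rank ties break by gene id
(stable), making every ranking deterministic.

*Permutation null and NES.* Two schemes build the null ES sample.
Phenotype permutation (relabel samples, re-rank, re-score) is used when both
classes have ≥ 7 samples — below that, 1,000 distinct relabelings do not
exist and the scheme is silently degenerate, so the engine falls back to
gene-set permutation (score random same-size sets on the fixed ranking)
with a logged warning. NES divides ES by the mean |ES| of same-sign null
scores (flagged, not NaN, when no same-sign nulls exist); the empirical p is
(1 + #{same-sign nulls at least as extreme}) / (1 + #same-sign nulls), so
1,000 trials can never report p = 0. FDR is Benjamini–Hochberg across
pathways within a cohort. Within a cohort all pathways share one permutation
stream, which is both the standard economy and what makes 178-set scans
affordable.

*ssGSEA.* The per-patient pathway-activation score ranks the sample's genes
descending (ties by gene id), weights in-set positions by rank^α with
α = 0.25 (the top gene has rank N), and sums the difference between the
weighted in-set ECDF and the unweighted out-of-set ECDF over all positions.
The score depends only on within-sample ranks, hence is invariant to any
strictly increasing transform of one sample's values. No cross-sample
normalization is applied: each PA score is only ever compared within one
cancer's cutoff scan, which is itself invariant to monotone rescaling.

## Generality score

Definitions as in the README. Two numerical choices matter:

- The sums in a_i and b_i run over the significant cancers only (the masks
  that define w₁ and w₂), not over all *n*. This is the only reading under
  which the 19-of-20 configuration can score 10.45 at n = 20 — with the
  lowest-ranked cancer non-significant, a = (Σ_{r=2..20} r)/20 = 10.45 —
  while full-range summation could only produce multiples of the w-weights.
- The |a| = |b| → 0 tie rule is applied with a 1e-12 relative tolerance:
  the two statistics are computed by different floating-point sums, and
  exactly mirrored configurations (enriched at top ranks matching depleted
  at bottom ranks) would otherwise resolve the tie by round-off noise. The
  tolerance is far below the 1/(n²(w₁+w₂)) granularity of genuinely distinct
  values, so no real comparison is affected (verified against exact rational
  arithmetic in the tests).

Pathways significant nowhere (w₁ + w₂ = 0) score 0: a pathway deregulated
in no cancer is by definition not generally deregulated.

## Mode-of-action classification

Pathways with NES-row SD above 1.0 (configurable) enter consensus
clustering: 500 subsamples of 80% of the pathways, each clustered by
average-linkage agglomerative clustering on Euclidean distance and cut at
k = 3; the consensus matrix of co-clustering fractions (normalized by
co-sampling counts) is itself average-linkage clustered on 1 − consensus
and cut at k = 3. Clusters are labeled by their median NES: most negative →
LoF, most positive → GoF, middle → SoF. Low-variance pathways are assigned
to the nearest cluster centroid in NES space. A pathway clustered LoF with
generality ≥ +7 moves to GoF (and symmetrically GoF → LoF at ≤ −7), flagged
as reassigned; the ±7 default sits just below the strongest observed
disagreement the rule is meant to catch (a score of 7.2) and is
configurable. The reassignment is idempotent and never touches SoF.

## SAM differential expression

d = (μ_case − μ_ctrl)/(s + s₀) with s the Tusher pooled standard error and
s₀ chosen from the {0, 5, …, 100} percentiles of the SEs by minimizing the
coefficient of variation of windowed median-absolute-deviations of d across
SE-quantile windows. Significance comes from label permutations (exhaustive
enumeration when C(n, n_case) ≤ n_perm): the per-gene p pools null |d|
across genes; the q-value at each gene's |d| is median null call count over
permutations divided by observed call count, then monotonized as
q_i = min over thresholds ≤ |d_i| — the minimum estimated FDR over every
threshold that would still call gene *i* — so a larger |d| never carries a
larger q. log₂ fold changes use +1-pseudo-counted means. The signature
filter is strict on both sides: |log₂FC| > 2 and q < 0.01 by default, so a
gene at exactly the fold-change boundary is excluded.

A caveat on s₀ selection: when the per-gene mean difference is independent
of the *estimated* SE (as in artificially homoscedastic Gaussian data), the
windowed d-spread anti-correlates with SE and the CV objective prefers
large s₀; with exactly identical SEs the procedure degenerates and returns
0. On realistic heteroscedastic data (per-gene scales coupled to means, as
the synthetic generator produces) the selected s₀ is positive and modest.
Any fixed non-negative s₀ can be supplied instead for reproducibility work.

## Survival screening

The log-rank statistic is the standard (O − E)²/V chi-square with df = 1
(lifelines provides the public two-group test). The optimal-cutoff scan
evaluates every distinct observed PA value as a high/low split, skipping
splits that leave either stratum below 10% of the cohort — without a floor,
extreme splits trivially minimize p. The scan runs a vectorized
implementation that shares risk-set computations across all candidate
splits; tests verify it against the per-candidate lifelines result. Ties in
the minimum p break toward the more balanced split. No multiplicity
correction is applied inside the scan: taking the minimum p over candidates
is anti-conservative by construction, which is why the downstream
prognostic call uses the stringent p < 0.001 and why null-data scans are
expected to clear nominal α far more often than 5% — users comparing
pathways should treat the scan p as a selection statistic, not a calibrated
tail probability. Patients lacking survival records are dropped before
scanning. Direction is decided by the restricted-mean survival time of the
Kaplan–Meier curves up to the largest follow-up shared by both strata.

## Prescription

PNS is the unweighted mean of a drug's instance NES values (instances are
scored independently, each with its own gene-set-permutation null);
per-cell-line aggregation can be layered on by grouping instances before
calling the aggregator. PS = CNS − PNS is kept signed — the sign encodes
which direction of dysregulation the drug opposes — with |PS| used for
ranking. Triplet emission requires the pathway to be prognostic
(p < 0.001) in the cancer and |CNS| > 1.5 (strict); drugs whose PS sign
matches the CNS sign oppose the dysregulation and are kept, but only drugs
whose PNS sign is actually opposite to the CNS are flagged as reversers —
a drug with a weak same-direction PNS ranks low without the flag.

## Synthetic data

The generator emulates the input families the pipeline assumes, not any
particular tumor biology: log-normal expression with per-gene
μ ~ U(3, 8) and σ ~ U(0.5, 1.5) on the log₂ scale (heteroscedastic, so s₀
selection is exercised nontrivially); planted sets shift member genes by a
configurable multiple of their own σ in case samples. Survival is
exponential with hazard h₀·HR^z, z the standardized PA score and
HR defaulting to 3 per PA standard deviation, with independent uniform
censoring (30% by default). Perturbation libraries carry 3 instances per
drug; reversers offset their target genes' ranking metric by ∓2 (opposing
the planted direction), decoys are pure noise. The generator does not model
gene–gene correlation, batch effects, cell-line-specific pharmacology, or
realistic tumor covariance — so passing tests demonstrate that the
machinery recovers planted structure under its own assumptions, not that it
is robust to real-data artifacts.

Defaults (2,000 genes, 50 sets of 20–80 genes, 3 cancers at 20+20 samples,
50 drugs) keep a full pipeline run to about two minutes on one CPU; tests
use smaller slices of the same generators (hundreds of genes, 100–300
permutations) chosen to keep each property check to seconds while retaining
the planted effects' detectability.

## Verification problem sizes

The test suite checks the enrichment running sum against a brute-force
position-by-position oracle on 200 random instances (≤ 50 genes), the
hypergeometric test against full enumeration of all C(N, n) draws for every
population size N ≤ 12, the generality statistics against exact rational
arithmetic on 1,000 random configurations, and the log-rank statistic
against a hand-computed (O − E)²/V oracle on small tied cohorts. Null
calibration uses 500 null cohort–set GSEA simulations (phenotype
permutation, 200 trials each) and 1,000 null SAM gene tests; planted-truth
recovery uses 50 seeds each for the survival scan (HR = 3, n = 300,
detection at p < 0.001) and the reverser ranking (1 reverser among 50
drugs, top |PS|).
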