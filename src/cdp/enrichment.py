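"""Gene set enrichment scoring: case-control GSEA (building the CNS matrix)
and single-sample ssGSEA pathway-activation scores.

The enrichment score is the classic weighted Kolmogorov-Smirnov running sum:
walking down a ranked gene list, set members ("hits") increment the sum in
proportion to |metric|^w (weight exponent w = 1) and non-members decrement it
by 1/(N - |S|); the ES is the signed maximum deviation from zero. The NES
divides the ES by the mean |ES| of same-sign permutation-null scores, and the
empirical p-value counts null scores as or more extreme than the observed one
among nulls of matching sign (with a +1/+1 pseudo-count so p > 0 always).

Two permutation schemes build the null: phenotype permutation (shuffle the
case/control labels and re-rank; preferred when each class has enough samples
to support ~1000 distinct relabelings) and gene-set permutation (score random
gene sets of the same size on the fixed ranked list; used for small cohorts
and for drug-instance rankings where no phenotype exists).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, GeneSetCollection, ScoreMatrix, ValidationError

logger = logging.getLogger(__name__)

#: Below this per-class sample count, phenotype permutation cannot supply
#: ~1000 distinct relabelings and the null falls back to gene-set permutation.
MIN_SAMPLES_PHENOTYPE = 7


@dataclass
class RankedList:
    """Genes ordered by a ranking metric, descending.

    Ties in the metric are broken by gene id (stable and deterministic), so
    an identical input always yields an identical ordering.
    """

    gene_ids: list[str]
    metric_values: np.ndarray

    def __post_init__(self) -> None:
        self.metric_values = np.asarray(self.metric_values, dtype=float)
        if len(self.gene_ids) != len(self.metric_values):
            raise ValidationError("ranked list ids and metric lengths differ")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate genes in ranked list")
        if np.any(np.diff(self.metric_values) > 0):
            raise ValidationError("metric values must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_emp: float
    fdr: float = np.nan
    flagged: bool = False  # True when the null could not normalize the ES


def _sort_genes(gene_ids: list[str], metric: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Sort descending by metric, ties broken ascending by gene id."""
    order = sorted(range(len(gene_ids)), key=lambda i: (-metric[i], gene_ids[i]))
    return [gene_ids[i] for i in order], metric[order]


def signal_to_noise(
    case: np.ndarray, control: np.ndarray, sd_floor_frac: float = 0.2
) -> np.ndarray:
    """Per-gene signal-to-noise ratio with floored standard deviations.

    snr = (mean_case - mean_control) / (sd_case + sd_control), where each sd
    is floored at max(sd_floor_frac * |mean|, sd_floor_frac) so that
    zero-variance genes cannot produce infinite metrics.
    """
    mc, mn = case.mean(axis=1), control.mean(axis=1)
    sc = np.maximum(case.std(axis=1, ddof=1), np.maximum(sd_floor_frac * np.abs(mc), sd_floor_frac))
    sn = np.maximum(control.std(axis=1, ddof=1), np.maximum(sd_floor_frac * np.abs(mn), sd_floor_frac))
    return (mc - mn) / (sc + sn)


def log2_fold_change(case: np.ndarray, control: np.ndarray, pseudo: float = 1.0) -> np.ndarray:
    """log2((mean_case + pseudo)/(mean_control + pseudo)); for tiny cohorts."""
    return np.log2(case.mean(axis=1) + pseudo) - np.log2(control.mean(axis=1) + pseudo)


_METRICS = {"signal_to_noise": signal_to_noise, "log2_fold_change": log2_fold_change}


def rank_genes(expr: ExpressionMatrix, metric: str = "signal_to_noise") -> RankedList:
    """Rank genes of a case/control cohort by a two-class metric, descending."""
    if metric not in _METRICS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    case, control = expr.case_values(), expr.control_values()
    if metric == "signal_to_noise" and (case.shape[1] < 2 or control.shape[1] < 2):
        raise ValidationError(
            "signal_to_noise needs >=2 samples per class; use log2_fold_change"
        )
    values = _METRICS[metric](case, control)
    ids, vals = _sort_genes(expr.gene_ids, values)
    return RankedList(ids, vals)


def _running_es(metric_sorted: np.ndarray, hits: np.ndarray, weight: float = 1.0) -> float:
    """Signed max deviation of the weighted KS running sum (ES).

    ``hits`` is a boolean mask over the sorted list. Hit increments are
    |metric|^weight normalized by their sum; if every hit metric is zero the
    hits fall back to equal weights. Misses decrement by 1/(N - n_hits).
    """
    n = metric_sorted.shape[0]
    nh = int(hits.sum())
    w = np.where(hits, np.abs(metric_sorted) ** weight, 0.0)
    total = w.sum()
    if total == 0.0:
        w = hits.astype(float)
        total = float(nh)
    running = np.cumsum(w / total - (~hits) / (n - nh))
    idx = int(np.argmax(np.abs(running)))
    # cumsum round-off can overshoot the mathematical bounds by ~1 ulp
    return float(np.clip(running[idx], -1.0, 1.0))


def enrichment_score(ranked: RankedList, gene_set, weight: float = 1.0) -> float:
    """ES of a gene set against a ranked list; bounded in [-1, 1]."""
    members = set(gene_set)
    hits = np.fromiter((g in members for g in ranked.gene_ids), bool, len(ranked))
    nh = int(hits.sum())
    if nh == 0:
        raise ValidationError("gene set has no members in the ranked list")
    if nh == len(ranked):
        raise ValidationError("gene set covers the entire ranked list")
    return _running_es(ranked.metric_values, hits, weight)


def _es_batch_random_sets(
    metric_sorted: np.ndarray, set_size: int, n_perm: int, rng: np.random.Generator,
    weight: float = 1.0,
) -> np.ndarray:
    """Null ES from random same-size gene sets on a fixed ranked list (vectorized)."""
    n = metric_sorted.shape[0]
    hits = np.zeros((n_perm, n), dtype=bool)
    # vectorized sampling without replacement: argpartition of random keys
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
    np.put_along_axis(hits, idx, True, axis=1)
    w = np.where(hits, np.abs(metric_sorted) ** weight, 0.0)
    totals = w.sum(axis=1, keepdims=True)
    degenerate = totals[:, 0] == 0.0
    if degenerate.any():
        w[degenerate] = hits[degenerate].astype(float)
        totals = w.sum(axis=1, keepdims=True)
    running = np.cumsum(w / totals - (~hits) / (n - set_size), axis=1)
    flat = np.abs(running).argmax(axis=1)
    return running[np.arange(n_perm), flat]


def _null_phenotype_rankings(
    expr: ExpressionMatrix, metric: str, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Permuted-label metric matrices: (orders, metrics) each (n_perm, n_genes).

    ``orders[b]`` is the gene index order (descending metric) of permutation b.
    """
    values = expr.values
    n_samples = values.shape[1]
    n_case = expr.n_case
    metrics = np.empty((n_perm, values.shape[0]))
    fn = _METRICS[metric]
    for b in range(n_perm):
        perm = rng.permutation(n_samples)
        case_idx, ctrl_idx = perm[:n_case], perm[n_case:]
        metrics[b] = fn(values[:, case_idx], values[:, ctrl_idx])
    # ties broken by gene index (stable argsort of -metric)
    orders = np.argsort(-metrics, axis=1, kind="stable")
    return orders, np.take_along_axis(metrics, orders, axis=1)


def _nes_p_from_null(es: float, null_es: np.ndarray) -> tuple[float, float, bool]:
    """NES and empirical p from a null ES sample, same-sign convention."""
    if es >= 0:
        same = null_es[null_es >= 0]
    else:
        same = null_es[null_es < 0]
    if same.size == 0:
        return np.nan, 1.0, True
    mean_abs = np.abs(same).mean()
    if mean_abs == 0.0:
        return np.nan, 1.0, True
    nes = es / mean_abs
    p = (1.0 + int(np.sum(np.abs(same) >= abs(es)))) / (1.0 + same.size)
    return float(nes), float(p), False


def nes_and_significance(
    es: float,
    ranked: RankedList,
    gene_set,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    weight: float = 1.0,
) -> EnrichmentResult:
    """Normalize an ES and attach an empirical p via gene-set permutation.

    The null scores random gene sets of the same (measured) size against the
    observed ranked list. FDR across a collection is attached by
    :func:`compute_cns` / callers via Benjamini-Hochberg.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    members = set(gene_set)
    size = sum(g in members for g in ranked.gene_ids)
    null = _es_batch_random_sets(ranked.metric_values, size, n_perm, rng, weight)
    nes, p, flagged = _nes_p_from_null(es, null)
    name = getattr(gene_set, "name", "")
    return EnrichmentResult(name, es, nes, p, flagged=flagged)


def _score_cohort(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    metric: str,
    scheme: str,
    n_perm: int,
    rng: np.random.Generator,
    weight: float = 1.0,
) -> list[EnrichmentResult]:
    """GSEA of every set against one cohort, sharing one permutation null."""
    ranked = rank_genes(expr, metric)
    gene_pos = {g: i for i, g in enumerate(ranked.gene_ids)}
    metric_sorted = ranked.metric_values

    if scheme == "phenotype":
        orders, null_metrics = _null_phenotype_rankings(expr, metric, n_perm, rng)
        # gene id -> original row index, to locate set members inside orders
        orig_pos = {g: i for i, g in enumerate(expr.gene_ids)}

    results = []
    for name, genes in sets:
        hits = np.zeros(len(ranked), dtype=bool)
        measured = [g for g in genes if g in gene_pos]
        hits[[gene_pos[g] for g in measured]] = True
        es = _running_es(metric_sorted, hits, weight)

        if scheme == "phenotype":
            member_rows = np.zeros(len(expr.gene_ids), dtype=bool)
            member_rows[[orig_pos[g] for g in measured]] = True
            null_hits = member_rows[orders]  # (n_perm, n_genes)
            n, nh = len(expr.gene_ids), len(measured)
            w = np.where(null_hits, np.abs(null_metrics) ** weight, 0.0)
            totals = w.sum(axis=1, keepdims=True)
            degenerate = totals[:, 0] == 0.0
            if degenerate.any():
                w[degenerate] = null_hits[degenerate].astype(float)
                totals = w.sum(axis=1, keepdims=True)
            running = np.cumsum(w / totals - (~null_hits) / (n - nh), axis=1)
            arg = np.abs(running).argmax(axis=1)
            null = running[np.arange(n_perm), arg]
        else:
            null = _es_batch_random_sets(metric_sorted, len(measured), n_perm, rng, weight)

        nes, p, flagged = _nes_p_from_null(es, null)
        results.append(EnrichmentResult(name, es, nes, p, flagged=flagged))
    return results


def compute_cns(
    cohorts: dict[str, ExpressionMatrix],
    sets: GeneSetCollection,
    metric: str = "signal_to_noise",
    permutation_scheme: str = "auto",
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> ScoreMatrix:
    """Pathways x cancers NES matrix (the CNS) with empirical p and BH-FDR layers.

    One GSEA per (pathway, cohort); permutation nulls are shared across
    pathways within a cohort. ``permutation_scheme`` is ``phenotype``,
    ``gene_set`` or ``auto`` (phenotype when both classes have at least
    ``MIN_SAMPLES_PHENOTYPE`` samples, otherwise gene-set, with a warning).
    FDR is Benjamini-Hochberg across pathways within each cohort. Cohorts with
    tiny classes where ``metric='signal_to_noise'`` is undefined fall back to
    ``log2_fold_change`` with a warning.
    """
    if not cohorts:
        raise ValidationError("need at least one cohort")
    if permutation_scheme not in {"auto", "phenotype", "gene_set"}:
        raise ValidationError(f"unknown permutation scheme {permutation_scheme!r}")
    names = sets.names()
    cancer_ids = list(cohorts)
    nes = np.full((len(names), len(cancer_ids)), np.nan)
    p = np.full_like(nes, np.nan)
    fdr = np.full_like(nes, np.nan)
    rng = np.random.default_rng(seed)
    for j, cancer in enumerate(cancer_ids):
        expr = cohorts[cancer]
        filtered, dropped = sets.filter_to_measured(expr.gene_ids)
        if dropped:
            logger.info("%s: dropped %d sets without measured genes", cancer, dropped)
        scheme = permutation_scheme
        if scheme in ("auto", "phenotype"):
            ok = min(expr.n_case, expr.n_control) >= MIN_SAMPLES_PHENOTYPE
            if not ok and scheme == "phenotype":
                logger.warning(
                    "%s: classes too small for phenotype permutation; "
                    "falling back to gene-set permutation", cancer,
                )
            scheme = "phenotype" if ok else "gene_set"
        cohort_metric = metric
        if metric == "signal_to_noise" and (expr.n_case < 2 or expr.n_control < 2):
            logger.warning("%s: <2 samples per class; using log2_fold_change", cancer)
            cohort_metric = "log2_fold_change"
        results = {
            r.set_name: r
            for r in (
                EnrichmentResult(name, np.nan, np.nan, np.nan)
                for name in names
            )
        }
        cohort_results = _score_cohort(
            expr, filtered, cohort_metric, scheme, n_perm, rng, weight
        )
        for name, r in zip(filtered.names(), cohort_results):
            r.set_name = name
            results[name] = r
        ps = np.array([results[n].p_emp for n in names])
        valid = np.isfinite(ps)
        qs = np.full_like(ps, np.nan)
        if valid.any():
            qs[valid] = multipletests(ps[valid], method="fdr_bh")[1]
        for i, name in enumerate(names):
            nes[i, j] = results[name].nes
            p[i, j] = results[name].p_emp
            fdr[i, j] = qs[i]
    return ScoreMatrix(names, cancer_ids, nes, p=p, fdr=fdr)


def ssgsea_score(
    sample_values: np.ndarray,
    gene_ids: list[str],
    gene_set,
    alpha: float = 0.25,
) -> float:
    """Single-sample pathway-activation score (ssGSEA).

    Genes are ranked by expression within the sample (descending; ties broken
    by gene id). The score sums, over all ranked positions, the difference
    between the rank-weighted in-set ECDF (weights = rank^alpha, where the
    top gene has rank N) and the unweighted out-of-set ECDF. The score depends
    only on within-sample ranks, so any strictly increasing transform of the
    expression values leaves it unchanged.
    """
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    values = np.asarray(sample_values, dtype=float)
    if values.ndim != 1 or len(values) != len(gene_ids):
        raise ValidationError("sample vector and gene ids must align")
    if np.all(values == values[0]):
        raise ValidationError("constant expression vector: ranks undefined")
    members = set(gene_set)
    order = sorted(range(len(values)), key=lambda i: (-values[i], gene_ids[i]))
    hits = np.fromiter((gene_ids[i] in members for i in order), bool, len(order))
    nh = int(hits.sum())
    if nh == 0:
        raise ValidationError("sample covers no gene-set member")
    if nh == len(order):
        raise ValidationError("gene set covers the entire sample")
    n = len(order)
    ranks = np.arange(n, 0, -1, dtype=float)  # N for the top gene
    w = np.where(hits, ranks**alpha, 0.0)
    ecdf_in = np.cumsum(w) / w.sum()
    ecdf_out = np.cumsum(~hits) / (n - nh)
    return float(np.sum(ecdf_in - ecdf_out))


def pa_score_matrix(
    expr: ExpressionMatrix, sets: GeneSetCollection, alpha: float = 0.25
) -> ScoreMatrix:
    """Pathway-activation (ssGSEA) scores for every (pathway, sample) pair."""
    filtered, _ = sets.filter_to_measured(expr.gene_ids)
    names = filtered.names()
    scores = np.empty((len(names), len(expr.sample_ids)))
    for j in range(len(expr.sample_ids)):
        col = expr.values[:, j]
        for i, name in enumerate(names):
            scores[i, j] = ssgsea_score(col, expr.gene_ids, filtered.sets[name], alpha)
    return ScoreMatrix(names, list(expr.sample_ids), scores)
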