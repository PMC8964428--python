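"""SAM-style two-group differential expression.

The d-statistic is a moderated t: d = (mean_case - mean_control) / (s + s0),
where s is the Tusher pooled standard error and s0 ("fudge factor") a small
non-negative offset that stabilizes the denominator for low-variance genes.
s0 is chosen by the Tusher procedure: the percentile of the pooled SEs that
minimizes the coefficient of variation of the d-statistics across SE-quantile
windows. Significance comes from label permutations; per-gene q-values are
SAM-style (median false-call count over permutations divided by the observed
call count at each gene's |d|), monotonized so that a larger |d| never has a
larger q. The signature filter keeps genes with |log2FC| above a fold-change
threshold and q below an FDR threshold (strict inequalities on both sides).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, ValidationError


@dataclass
class FudgeFactor:
    """The SAM variance-stabilizing offset s0 (expression units, >= 0)."""

    s0: float

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValidationError("s0 must be non-negative")


def pooled_se(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Tusher pooled standard error per gene (rows = genes)."""
    n1, n2 = case.shape[1], control.shape[1]
    ss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (control - control.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    a = (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    return np.sqrt(a * ss)


def sam_statistic(
    case_values: np.ndarray, control_values: np.ndarray, s0: float = 0.0
) -> np.ndarray:
    """SAM d-statistic per gene: (mean_case - mean_control) / (pooled SE + s0).

    Accepts 1-D vectors (one gene) or 2-D matrices (genes x samples).
    """
    scalar = np.asarray(case_values).ndim == 1
    case = np.atleast_2d(np.asarray(case_values, dtype=float))
    control = np.atleast_2d(np.asarray(control_values, dtype=float))
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValidationError("sam_statistic needs >=2 values per group")
    if s0 < 0:
        raise ValidationError("s0 must be non-negative")
    d = (case.mean(axis=1) - control.mean(axis=1)) / (pooled_se(case, control) + s0)
    return float(d[0]) if scalar else d

def select_s0(d_numerators: np.ndarray, ses: np.ndarray) -> FudgeFactor:
    """Tusher s0 selection: the SE percentile minimizing the CV of d.

    Candidate s0 values are the percentiles {0, 5, ..., 100} of the pooled
    SEs. For each candidate, d = numerator / (SE + s0) is computed and the
    genes are split into 100 windows by SE quantile; the candidate minimizing
    the coefficient of variation of the median absolute deviation of d across
    windows is selected. With fewer than 2 distinct SEs the procedure is
    vacuous and s0 = 0 is returned.
    """
    ses = np.asarray(ses, dtype=float)
    d_numerators = np.asarray(d_numerators, dtype=float)
    if np.unique(ses).size < 2:
        return FudgeFactor(0.0)
    candidates = np.percentile(ses, np.arange(0, 101, 5))
    n_windows = min(100, max(2, ses.size // 10))
    # window assignment by SE quantile (fixed across candidates)
    order = np.argsort(ses, kind="stable")
    windows = np.array_split(order, n_windows)
    best_s0, best_cv = 0.0, np.inf
    for s0 in candidates:
        d = d_numerators / (ses + s0)
        mads = np.array(
            [np.median(np.abs(d[w] - np.median(d[w]))) for w in windows if w.size]
        )
        mean = mads.mean()
        if mean == 0:
            continue
        cv = mads.std(ddof=0) / mean
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(s0)
    return FudgeFactor(best_s0)


def _all_label_splits(n_total: int, n_case: int):
    """Exhaustive case-index combinations (used when few distinct splits exist)."""
    for idx in combinations(range(n_total), n_case):
        yield np.array(idx)


def permutation_fdr(
    expr: ExpressionMatrix,
    s0: float | None = None,
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene permutation significance for the SAM d-statistic.

    Returns a DataFrame indexed by gene with columns ``d``, ``p`` (per-gene
    permutation p for |d|), and ``q`` (SAM-style FDR: median false-call count
    over permutations / observed call count at each gene's |d| threshold,
    clipped to [0, 1] and monotonized so q is non-increasing in |d|).

    When the number of distinct label splits is at most ``n_perm``, the null
    is built by exhaustive enumeration instead of sampling.
    """
    if n_perm < 10:
        raise ValidationError("n_perm must be >= 10")
    values = expr.values
    mask = expr.case_mask
    n_case, n_total = int(mask.sum()), values.shape[1]
    if s0 is None:
        case, control = values[:, mask], values[:, ~mask]
        num = case.mean(axis=1) - control.mean(axis=1)
        s0 = select_s0(num, pooled_se(case, control)).s0
    d_obs = sam_statistic(values[:, mask], values[:, ~mask], s0)
    abs_obs = np.abs(d_obs)

    from math import comb

    n_distinct = comb(n_total, n_case)
    rng = np.random.default_rng(seed)
    null_abs = []
    if n_distinct <= n_perm:
        splits = _all_label_splits(n_total, n_case)
    else:
        splits = (rng.permutation(n_total)[:n_case] for _ in range(n_perm))
    for case_idx in splits:
        pmask = np.zeros(n_total, dtype=bool)
        pmask[np.asarray(case_idx)] = True
        null_abs.append(np.abs(sam_statistic(values[:, pmask], values[:, ~pmask], s0)))
    null_abs = np.asarray(null_abs)  # (B, n_genes)
    B = null_abs.shape[0]

    # per-gene p: share of null |d| values (pooled over genes) >= observed
    pooled = np.sort(null_abs.ravel())
    exceed = pooled.size - np.searchsorted(pooled, abs_obs, side="left")
    p = (1.0 + exceed) / (1.0 + pooled.size)

    # SAM q: at threshold |d_i|, called = #{obs |d| >= |d_i|},
    # false = median over permutations of #{null |d| >= |d_i|}
    sorted_obs = np.sort(abs_obs)
    called = abs_obs.size - np.searchsorted(sorted_obs, abs_obs, side="left")
    null_sorted = np.sort(null_abs, axis=1)
    false_counts = null_abs.shape[1] - np.stack(
        [np.searchsorted(null_sorted[b], abs_obs, side="left") for b in range(B)]
    )
    median_false = np.median(false_counts, axis=0)
    q_raw = np.clip(median_false / np.maximum(called, 1), 0.0, 1.0)
    # q_i = min FDR over thresholds t <= |d_i| (every threshold that calls
    # gene i); running min along ascending |d| enforces that a larger |d|
    # never has a larger q
    order = np.argsort(abs_obs, kind="stable")
    q_mono = np.empty_like(q_raw)
    q_mono[order] = np.minimum.accumulate(q_raw[order])

    # pseudo-counted fold change on mean expression; means clipped at 0 so
    # that already-normalized inputs containing negatives stay defined
    case, control = values[:, mask], values[:, ~mask]
    log2fc = np.log2(np.maximum(case.mean(axis=1), 0.0) + 1.0) - np.log2(
        np.maximum(control.mean(axis=1), 0.0) + 1.0
    )
    return pd.DataFrame(
        {"d": d_obs, "log2fc": log2fc, "p": p, "q": q_mono},
        index=pd.Index(expr.gene_ids, name="gene"),
    )


def deg_filter(
    results: pd.DataFrame, fc_threshold: float = 2.0, q_threshold: float = 0.01
) -> tuple[list[str], list[str]]:
    """Split significant genes into up/down signatures.

    up: log2fc > fc_threshold and q < q_threshold; down: log2fc < -fc_threshold
    and q < q_threshold. Both inequalities are strict, so a gene at exactly the
    fold-change threshold is excluded.
    """
    if fc_threshold <= 0 or q_threshold <= 0:
        raise ValidationError("thresholds must be positive")
    sig = results["q"] < q_threshold
    up = results.index[sig & (results["log2fc"] > fc_threshold)].tolist()
    down = results.index[sig & (results["log2fc"] < -fc_threshold)].tolist()
    return up, down


def run_diffexpr(
    expr: ExpressionMatrix,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.01,
    s0: float | None = None,
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """SAM analysis end to end; adds a ``direction`` column (up/down/ns)."""
    results = permutation_fdr(expr, s0=s0, n_perm=n_perm, seed=seed)
    up, down = deg_filter(results, fc_threshold, q_threshold)
    direction = pd.Series("ns", index=results.index)
    direction[up] = "up"
    direction[down] = "down"
    results = results.assign(direction=direction)
    return results
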