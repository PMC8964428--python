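"""Prognostic pathway discovery by optimal-cutoff survival stratification.

For each (pathway, cancer) pair the per-patient ssGSEA pathway-activation
(PA) score stratifies the cohort into a high and a low group at a candidate
cutoff; every distinct observed PA value is tried (skipping splits that leave
either group below a minimum fraction of the cohort), each split is assessed
by a two-group log-rank test, and the cutoff with the smallest p is kept.
Pathways whose best split reaches p < 0.001 are called prognostic; the
direction is favorable when the high-PA stratum survives longer (by the
restricted-mean survival time of the Kaplan-Meier curves up to the largest
shared follow-up) and adverse otherwise.

The per-candidate scan uses an internal vectorized log-rank (all cutoffs
evaluated in one pass over the risk sets); the public
:func:`logrank_test` wraps lifelines and serves as the reference
implementation the scan is checked against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import restricted_mean_survival_time

from .datatypes import ClinicalTable, ExpressionMatrix, GeneSetCollection, ValidationError
from .enrichment import pa_score_matrix

logger = logging.getLogger(__name__)


@dataclass
class CutoffScanResult:
    pathway: str
    cancer: str
    best_cutoff: float
    best_p: float
    n_high: int
    n_low: int
    scanned: int
    valid: bool = True  # False when no admissible split exists


@dataclass
class PrognosticPathway:
    pathway: str
    cancer: str
    p: float
    direction: str  # "favorable" or "adverse"
    cutoff: float
    n_high: int = 0
    n_low: int = 0


def logrank_test(
    time_a: np.ndarray,
    event_a: np.ndarray,
    time_b: np.ndarray,
    event_b: np.ndarray,
) -> tuple[float, float]:
    """Two-group log-rank chi-square statistic (df=1) and p-value."""
    time_a, time_b = np.asarray(time_a, float), np.asarray(time_b, float)
    event_a, event_b = np.asarray(event_a, int), np.asarray(event_b, int)
    if time_a.size == 0 or time_b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if event_a.sum() + event_b.sum() == 0:
        raise ValidationError("no events to compare")
    res = _ll_logrank(time_a, time_b, event_observed_A=event_a, event_observed_B=event_b)
    return float(res.test_statistic), float(res.p_value)


def _batch_logrank(
    time: np.ndarray, event: np.ndarray, group_masks: np.ndarray
) -> np.ndarray:
    """Log-rank chi-square for many binary stratifications of one cohort.

    ``group_masks`` is (n_splits, n_patients) boolean (True = high group).
    Returns the chi-square per split (NaN where a group is empty or the
    statistic is degenerate). Vectorized over splits: risk sets and event
    counts at the distinct event times are shared across splits.
    """
    from scipy.stats import chi2  # noqa: F401  (p handled by caller)

    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    masks = group_masks[:, order]  # (S, n)
    event_times = np.unique(t[e == 1])
    # at-risk and events in group-1 per split per event time
    n = t.size
    S = masks.shape[0]
    o1 = np.zeros(S)
    exp1 = np.zeros(S)
    var = np.zeros(S)
    for et in event_times:
        at_risk = t >= et
        d = int(((t == et) & (e == 1)).sum())
        n_tot = int(at_risk.sum())
        if n_tot < 2:
            continue
        n1 = masks[:, at_risk].sum(axis=1).astype(float)  # per split
        d1 = masks[:, (t == et) & (e == 1)].sum(axis=1).astype(float)
        o1 += d1
        exp1 += d * n1 / n_tot
        if n_tot > 1:
            var += d * (n1 / n_tot) * (1.0 - n1 / n_tot) * (n_tot - d) / (n_tot - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi = (o1 - exp1) ** 2 / var
    chi[var <= 0] = np.nan
    return chi


def optimal_cutoff_scan(
    pa_scores: np.ndarray,
    clinical: ClinicalTable,
    min_group_frac: float = 0.1,
    pathway: str = "",
    cancer: str = "",
) -> CutoffScanResult:
    """Find the PA-score cutoff minimizing the log-rank p over all candidates.

    Candidates are the distinct observed PA scores; a candidate c stratifies
    patients into high (PA > c) vs low (PA <= c). Splits leaving either group
    below ``min_group_frac`` of the cohort are skipped. Ties in p are broken
    toward the more balanced split. Returns a no-split result (valid=False)
    when no candidate is admissible (constant PA or a tiny cohort).
    """
    if not 0 < min_group_frac < 0.5:
        raise ValidationError("min_group_frac must be in (0, 0.5)")
    pa = np.asarray(pa_scores, dtype=float)
    if pa.size != len(clinical):
        raise ValidationError("PA scores and clinical table must align")
    n = pa.size
    min_size = int(np.ceil(min_group_frac * n))
    cuts = np.unique(pa)
    masks, kept_cuts = [], []
    for c in cuts:
        high = pa > c
        nh = int(high.sum())
        if nh < min_size or n - nh < min_size:
            continue
        masks.append(high)
        kept_cuts.append(c)
    if not masks:
        return CutoffScanResult(pathway, cancer, np.nan, np.nan, 0, 0, 0, valid=False)
    masks = np.asarray(masks)
    if clinical.event.sum() == 0:
        raise ValidationError("no events to compare")
    chi = _batch_logrank(clinical.time, clinical.event, masks)
    from scipy.stats import chi2

    with np.errstate(invalid="ignore"):
        pvals = chi2.sf(chi, df=1)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    best_p = pvals.min()
    tied = np.flatnonzero(pvals <= best_p + 0.0)
    if tied.size > 1:  # prefer the most balanced split
        balance = np.abs(masks[tied].sum(axis=1) - n / 2.0)
        tied = tied[np.argsort(balance, kind="stable")]
    best = int(tied[0])
    nh = int(masks[best].sum())
    return CutoffScanResult(
        pathway, cancer, float(kept_cuts[best]), float(best_p), nh, n - nh,
        scanned=len(kept_cuts),
    )


def _rmst(time: np.ndarray, event: np.ndarray, horizon: float) -> float:
    km = KaplanMeierFitter().fit(time, event)
    return float(restricted_mean_survival_time(km, t=horizon))


def classify_prognostic(
    scan: CutoffScanResult,
    pa_scores: np.ndarray,
    clinical: ClinicalTable,
    p_threshold: float = 0.001,
) -> PrognosticPathway | None:
    """Label a scan result prognostic (favorable/adverse) or return None.

    Prognostic requires best_p strictly below ``p_threshold``. Direction is
    favorable when the high-PA stratum has the larger restricted-mean
    survival up to the largest follow-up time shared by both strata.
    """
    if not scan.valid or not np.isfinite(scan.best_p) or scan.best_p >= p_threshold:
        return None
    pa = np.asarray(pa_scores, dtype=float)
    high = pa > scan.best_cutoff
    t, e = clinical.time, clinical.event
    horizon = min(t[high].max(), t[~high].max())
    rm_high = _rmst(t[high], e[high], horizon)
    rm_low = _rmst(t[~high], e[~high], horizon)
    direction = "favorable" if rm_high > rm_low else "adverse"
    return PrognosticPathway(
        scan.pathway, scan.cancer, scan.best_p, direction, scan.best_cutoff,
        scan.n_high, scan.n_low,
    )


def prognostic_screen(
    cohorts: dict[str, ExpressionMatrix],
    sets: GeneSetCollection,
    clinical: dict[str, ClinicalTable],
    p_threshold: float = 0.001,
    min_group_frac: float = 0.1,
    alpha: float = 0.25,
    case_only: bool = True,
) -> list[PrognosticPathway]:
    """Scan every (pathway, cancer) pair and collect prognostic pathways.

    PA scores are computed per patient by ssGSEA (on tumor samples only when
    ``case_only``), matched to the clinical table by sample id; patients
    without survival records are dropped. Output is sorted by p ascending.
    """
    found: list[PrognosticPathway] = []
    for cancer, expr in cohorts.items():
        clin = clinical.get(cancer)
        if clin is None:
            logger.warning("%s: no clinical table; skipped", cancer)
            continue
        pa = pa_score_matrix(expr, sets, alpha=alpha)
        if case_only:
            keep = [s for s, c in zip(expr.sample_ids, expr.condition) if c == "case"]
        else:
            keep = list(expr.sample_ids)
        matched = [s for s in keep if s in set(clin.sample_ids)]
        if len(matched) < 4:
            logger.warning("%s: %d matched patients; skipped", cancer, len(matched))
            continue
        clin_m = clin.subset(matched)
        col_idx = [pa.col_ids.index(s) for s in matched]
        n_prognostic = 0
        for i, pathway in enumerate(pa.row_ids):
            scores = pa.nes[i, col_idx]
            scan = optimal_cutoff_scan(
                scores, clin_m, min_group_frac, pathway=pathway, cancer=cancer
            )
            hit = classify_prognostic(scan, scores, clin_m, p_threshold)
            if hit is not None:
                found.append(hit)
                n_prognostic += 1
        logger.info("%s: %d prognostic pathways", cancer, n_prognostic)
    found.sort(key=lambda r: r.p)
    return found
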