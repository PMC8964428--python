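"""Pan-cancer pathway landscape: the generality score, pathway mode-of-action
(MoA) classification by consensus clustering, and gene-list enrichment.

The generality score quantifies how consistently a pathway is enriched
(positive) or depleted (negative) across the n cancer types under study.
For pathway i, the n cancers are ranked ascending by NES (rank 1 = lowest
NES). Writing w1 for the number of cancers where the pathway is significantly
enriched (NES > 0, p < 0.05) and w2 where significantly depleted (NES < 0,
p < 0.05), two statistics are formed over the significant cancers only:

    a_i = w1/(w1+w2) * sum_{k enriched-significant} r_ik / n
    b_i = w2/(w1+w2) * sum_{k depleted-significant} (1 - (r_ik - 1)/n) * (-1)

and the score S_i is a_i when |a_i| > |b_i|, b_i when |a_i| < |b_i|, and 0
when |a_i| = |b_i| (and when the pathway is nowhere significant). |S_i| is
bounded by (n+1)/2, attained when all n cancers are significant in one
direction: for enrichment the ranks are 1..n and a_i = (1/n) * n(n+1)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom, rankdata, spearmanr

from .datatypes import GeneList, ScoreMatrix, ValidationError

LOF, SOF, GOF = "LoF", "SoF", "GoF"


@dataclass
class GeneralityResult:
    pathway: str
    a: float
    b: float
    w1: int
    w2: int
    s: float


@dataclass
class MoAAssignment:
    pathway: str
    cluster: str  # LoF / SoF / GoF
    reassigned: bool = False
    consensus_fraction: float = 1.0


def build_rank_matrix(cns: ScoreMatrix) -> np.ndarray:
    """Per-pathway ascending ranks of the cancers by NES (rank 1 = lowest).

    Each row is a permutation of 1..n; NES ties are broken by cancer position
    (stable), so the result is deterministic for a fixed column order.
    """
    if not np.all(np.isfinite(cns.nes)):
        raise ValidationError("rank matrix requires a complete NES matrix")
    n = len(cns.col_ids)
    ranks = np.empty_like(cns.nes, dtype=int)
    for i in range(cns.nes.shape[0]):
        order = np.argsort(cns.nes[i], kind="stable")  # ascending, stable ties
        ranks[i, order] = np.arange(1, n + 1)
    return ranks


def significance_weights(
    cns: ScoreMatrix, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Counts and masks of significant enrichment/depletion per pathway.

    Returns (w1, w2, enriched_mask, depleted_mask); enrichment requires
    NES > 0 with p < alpha, depletion NES < 0 with p < alpha.
    """
    if cns.p is None:
        raise ValidationError("CNS matrix carries no p-value layer")
    sig = cns.p < alpha
    enriched = (cns.nes > 0) & sig
    depleted = (cns.nes < 0) & sig
    return enriched.sum(axis=1), depleted.sum(axis=1), enriched, depleted


def generality_score(
    ranks: np.ndarray,
    w1: int,
    w2: int,
    enriched_mask: np.ndarray,
    depleted_mask: np.ndarray,
    n: int,
) -> tuple[float, float, float]:
    """(a, b, s) for one pathway given its rank row and significance masks.

    Sums run over the significant cancers only; a pathway significant nowhere
    (w1 + w2 = 0) scores 0 by convention.
    """
    if w1 + w2 == 0:
        return 0.0, 0.0, 0.0
    ranks = np.asarray(ranks, dtype=float)
    a = (w1 / (w1 + w2)) * float(np.sum(ranks[enriched_mask] / n))
    b = (w2 / (w1 + w2)) * float(np.sum((1.0 - (ranks[depleted_mask] - 1.0) / n) * -1.0))
    # |a| = |b| means "no dominant direction"; compare with a small relative
    # tolerance so float round-off in the two sums cannot break the tie rule
    if np.isclose(abs(a), abs(b), rtol=1e-12, atol=1e-12):
        s = 0.0
    elif abs(a) > abs(b):
        s = a
    else:
        s = b
    return a, b, s


def generality_table(cns: ScoreMatrix, alpha: float = 0.05) -> list[GeneralityResult]:
    """Generality scores for every pathway of a CNS matrix with p layer."""
    ranks = build_rank_matrix(cns)
    w1, w2, enr, dep = significance_weights(cns, alpha)
    n = len(cns.col_ids)
    out = []
    for i, pathway in enumerate(cns.row_ids):
        a, b, s = generality_score(ranks[i], int(w1[i]), int(w2[i]), enr[i], dep[i], n)
        out.append(GeneralityResult(pathway, a, b, int(w1[i]), int(w2[i]), s))
    return out


def generality_frame(results: list[GeneralityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.pathway, r.a, r.b, r.w1, r.w2, r.s) for r in results],
        columns=["pathway", "a", "b", "w1", "w2", "generality"],
    ).set_index("pathway")


# ---------------------------------------------------------------------------
# Mode-of-action classification
# ---------------------------------------------------------------------------


def _cut3(dist_condensed: np.ndarray, k: int) -> np.ndarray:
    link = linkage(dist_condensed, method="average")
    return fcluster(link, t=k, criterion="maxclust")


def classify_moa(
    cns: ScoreMatrix,
    k: int = 3,
    n_resample: int = 500,
    subsample: float = 0.8,
    seed: int = 0,
    sd_threshold: float = 1.0,
) -> list[MoAAssignment]:
    """Partition pathways into LoF / SoF / GoF by consensus clustering.

    Pathways whose NES row has SD > ``sd_threshold`` enter consensus
    clustering: ``n_resample`` subsamples of ``subsample`` of the pathways,
    agglomerative hierarchical clustering (Euclidean, average linkage) cut at
    k clusters each; the consensus matrix holds co-clustering fractions and is
    itself hierarchically clustered (average linkage on 1 - consensus) and cut
    at k. Clusters are labeled by their median NES across cancers: the most
    negative cluster is LoF (broadly depleted), the most positive GoF, the
    remainder SoF. Low-variance pathways are assigned to the nearest cluster
    centroid (Euclidean distance in NES space).
    """
    X = cns.nes
    m = X.shape[0]
    if k > m:
        raise ValidationError(f"k={k} exceeds the number of pathways ({m})")
    rng = np.random.default_rng(seed)
    sds = X.std(axis=1, ddof=0)
    active = np.flatnonzero(sds > sd_threshold)
    if active.size < k:
        active = np.arange(m)  # too few variable pathways: cluster them all
    Xa = X[active]
    na = Xa.shape[0]
    n_sub = max(k, int(round(subsample * na)))

    co_count = np.zeros((na, na))
    co_sampled = np.zeros((na, na))
    for _ in range(n_resample):
        idx = rng.choice(na, size=n_sub, replace=False)
        sub = Xa[idx]
        labels = _cut3(squareform(_euclidean_dist(sub), checks=False), k)
        sampled = np.zeros(na, dtype=bool)
        sampled[idx] = True
        co_sampled[np.ix_(idx, idx)] += 1
        for c in np.unique(labels):
            members = idx[labels == c]
            co_count[np.ix_(members, members)] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sampled > 0, co_count / np.maximum(co_sampled, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    final = _cut3(squareform(1.0 - consensus, checks=False), k)

    # label clusters by median NES across cancers
    medians = {c: float(np.median(Xa[final == c])) for c in np.unique(final)}
    ordered = sorted(medians, key=medians.get)
    label_of = {ordered[0]: LOF, ordered[-1]: GOF}
    for c in ordered[1:-1]:
        label_of[c] = SOF
    if k == 2:  # degenerate: no middle cluster
        label_of = {ordered[0]: LOF, ordered[-1]: GOF}

    centroids = {c: Xa[final == c].mean(axis=0) for c in np.unique(final)}
    assignments: dict[int, MoAAssignment] = {}
    for pos, row in enumerate(active):
        c = final[pos]
        within = consensus[pos, final == c]
        assignments[row] = MoAAssignment(
            cns.row_ids[row], label_of[c], consensus_fraction=float(within.mean())
        )
    for row in range(m):
        if row in assignments:
            continue
        dists = {c: np.linalg.norm(X[row] - cen) for c, cen in centroids.items()}
        c = min(dists, key=dists.get)
        assignments[row] = MoAAssignment(cns.row_ids[row], label_of[c])
    return [assignments[row] for row in range(m)]


def _euclidean_dist(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def reassign_moa(
    assignments: list[MoAAssignment],
    generality_results: list[GeneralityResult],
    threshold: float = 7.0,
) -> list[MoAAssignment]:
    """Correct cluster labels that contradict a strong generality score.

    A pathway clustered LoF but with generality >= +threshold moves to GoF
    (and symmetrically GoF with generality <= -threshold moves to LoF), with
    the ``reassigned`` flag set; SoF pathways are never moved. Idempotent.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    s_of = {r.pathway: r.s for r in generality_results}
    out = []
    for a in assignments:
        s = s_of.get(a.pathway, 0.0)
        cluster, reassigned = a.cluster, a.reassigned
        if a.cluster == LOF and s >= threshold:
            cluster, reassigned = GOF, True
        elif a.cluster == GOF and s <= -threshold:
            cluster, reassigned = LOF, True
        out.append(MoAAssignment(a.pathway, cluster, reassigned, a.consensus_fraction))
    return out


def hypergeometric_enrichment(query_set, annotation_list: GeneList, universe) -> float:
    """Upper-tail hypergeometric p for overlap of a query with an annotation.

    Population = |universe|, successes = |annotation ∩ universe|, draws =
    |query|, observed k = |query ∩ annotation|; returns P(X >= k).
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    query = set(query_set) & universe
    ann = set(annotation_list.genes) & universe
    k = len(query & ann)
    return float(hypergeom.sf(k - 1, len(universe), len(ann), len(query)))


def cluster_cancers(cns: ScoreMatrix) -> tuple[np.ndarray, list[str]]:
    """Hierarchical clustering of cancers by pathway-profile similarity.

    Distance = 1 - Spearman correlation between cancer NES columns; average
    linkage. Returns the scipy linkage matrix and the cancer ids in dendrogram
    leaf order. Deterministic given input order.
    """
    from scipy.cluster.hierarchy import leaves_list

    rho = spearmanr(cns.nes).statistic
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # two columns: spearmanr returns a scalar
        r = float(rho[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    link = linkage(squareform(dist, checks=False), method="average")
    order = [cns.col_ids[i] for i in leaves_list(link)]
    return link, order
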