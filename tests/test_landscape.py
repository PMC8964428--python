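import numpy as np
import pytest

from cdp.datatypes import GeneList, ScoreMatrix, ValidationError
from cdp.landscape import (
    GeneralityResult,
    MoAAssignment,
    build_rank_matrix,
    classify_moa,
    cluster_cancers,
    generality_score,
    generality_table,
    hypergeometric_enrichment,
    reassign_moa,
    significance_weights,
)


def _cns(nes, p=None, rows=None, cols=None):
    nes = np.atleast_2d(np.asarray(nes, dtype=float))
    m, n = nes.shape
    return ScoreMatrix(
        rows or [f"p{i}" for i in range(m)],
        cols or [f"c{j}" for j in range(n)],
        nes,
        p=None if p is None else np.atleast_2d(np.asarray(p, dtype=float)),
    )


class TestRankMatrix:
    def test_ascending_ranks(self):
        ranks = build_rank_matrix(_cns([[0.1, 0.5, -0.2]]))
        np.testing.assert_array_equal(ranks, [[2, 3, 1]])

    def test_ties_resolve_to_permutation(self):
        ranks = build_rank_matrix(_cns([[1.0, 1.0, 1.0, 1.0]]))
        assert sorted(ranks[0]) == [1, 2, 3, 4]
        np.testing.assert_array_equal(ranks, [[1, 2, 3, 4]])  # stable: column order

    def test_rows_sum_to_triangular_number(self):
        rng = np.random.default_rng(0)
        ranks = build_rank_matrix(_cns(rng.normal(size=(10, 6))))
        assert (ranks.sum(axis=1) == 21).all()


class TestSignificanceWeights:
    def test_all_enriched(self):
        cns = _cns(np.full((1, 20), 2.0), p=np.full((1, 20), 0.01))
        w1, w2, enr, dep = significance_weights(cns)
        assert w1[0] == 20 and w2[0] == 0

    def test_nothing_significant(self):
        cns = _cns(np.full((1, 20), 2.0), p=np.full((1, 20), 0.2))
        w1, w2, *_ = significance_weights(cns)
        assert w1[0] == 0 and w2[0] == 0

    def test_mixed_manual_tally(self):
        nes = [[2.0, -1.5, 0.5, -0.2, 3.0]]
        p = [[0.01, 0.04, 0.01, 0.9, 0.2]]
        w1, w2, enr, dep = significance_weights(_cns(nes, p))
        assert w1[0] == 2  # c0 (2.0, 0.01) and c2 (0.5, 0.01)
        assert w2[0] == 1  # c1 (-1.5, 0.04)

    def test_missing_p_layer_is_error(self):
        with pytest.raises(ValidationError, match="p-value"):
            significance_weights(_cns([[1.0]]))


class TestGeneralityScore:
    n = 20

    def test_all_enriched_gives_max(self):
        ranks = np.arange(1, 21)
        enr, dep = np.ones(20, bool), np.zeros(20, bool)
        a, b, s = generality_score(ranks, 20, 0, enr, dep, self.n)
        assert s == pytest.approx(10.5)

    def test_all_depleted_gives_min(self):
        ranks = np.arange(1, 21)
        enr, dep = np.zeros(20, bool), np.ones(20, bool)
        a, b, s = generality_score(ranks, 0, 20, enr, dep, self.n)
        assert s == pytest.approx(-10.5)

    def test_19_of_20_with_lowest_rank_nonsignificant(self):
        ranks = np.arange(1, 21)
        enr = np.ones(20, bool)
        enr[0] = False  # the rank-1 cancer misses significance
        a, b, s = generality_score(ranks, 19, 0, enr, np.zeros(20, bool), self.n)
        assert s == pytest.approx(10.45)

    def test_mirror_symmetric_configuration_scores_zero(self):
        # w1 = w2 with |a| = |b|: enriched at top ranks mirror depleted at bottom
        ranks = np.arange(1, 21)
        enr = np.zeros(20, bool)
        dep = np.zeros(20, bool)
        enr[19] = True  # rank 20 enriched: a = (1/2)(20/20) = 0.5
        dep[0] = True  # rank 1 depleted: b = (1/2)(-(1 - 0/20)) = -0.5
        a, b, s = generality_score(ranks, 1, 1, enr, dep, self.n)
        assert abs(a) == pytest.approx(abs(b))
        assert s == 0.0

    def test_nowhere_significant_scores_zero(self):
        z = np.zeros(20, bool)
        assert generality_score(np.arange(1, 21), 0, 0, z, z, self.n) == (0, 0, 0)

    def test_matches_brute_force_formula(self):
        """a/b/s agree with an exact rational evaluation on random configs."""
        from fractions import Fraction

        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(2, 25))
            ranks = rng.permutation(n) + 1
            enr = rng.random(n) < 0.3
            dep = ~enr & (rng.random(n) < 0.3)
            w1, w2 = int(enr.sum()), int(dep.sum())
            a, b, s = generality_score(ranks, w1, w2, enr, dep, n)
            if w1 + w2 == 0:
                assert s == 0.0
                continue
            a_ref = Fraction(w1, w1 + w2) * sum(
                (Fraction(int(r), n) for r, e in zip(ranks, enr) if e), Fraction(0)
            )
            b_ref = Fraction(w2, w1 + w2) * sum(
                (-(1 - Fraction(int(r) - 1, n)) for r, d in zip(ranks, dep) if d),
                Fraction(0),
            )
            assert a == pytest.approx(float(a_ref))
            assert b == pytest.approx(float(b_ref))
            s_ref = a_ref if abs(a_ref) > abs(b_ref) else (
                b_ref if abs(a_ref) < abs(b_ref) else Fraction(0)
            )
            assert s == pytest.approx(float(s_ref))

    def test_bound_and_cancer_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(2, 21))
            nes = rng.normal(size=(1, n))
            p = rng.random((1, n))
            cns = _cns(nes, p)
            res = generality_table(cns)[0]
            assert abs(res.s) <= (n + 1) / 2 + 1e-12
            perm = rng.permutation(n)
            cns_p = _cns(nes[:, perm], p[:, perm])
            res_p = generality_table(cns_p)[0]
            assert res_p.s == pytest.approx(res.s)


class TestClassifyMoa:
    @staticmethod
    def _block_matrix(seed, sigma=0.2):
        rng = np.random.default_rng(seed)
        n_cancers, per_block = 10, 8
        neg = rng.normal(-2.0, sigma, size=(per_block, n_cancers))
        switch = np.tile(
            np.where(np.arange(n_cancers) % 2 == 0, 2.0, -2.0), (per_block, 1)
        ) + rng.normal(0, sigma, size=(per_block, n_cancers))
        pos = rng.normal(2.0, sigma, size=(per_block, n_cancers))
        nes = np.vstack([neg, switch, pos])
        rows = (
            [f"lof{i}" for i in range(per_block)]
            + [f"sof{i}" for i in range(per_block)]
            + [f"gof{i}" for i in range(per_block)]
        )
        return _cns(nes, rows=rows)

    def test_planted_blocks_recovered(self):
        recovered = 0
        for seed in range(20):
            cns = self._block_matrix(seed)
            moa = classify_moa(cns, n_resample=40, seed=seed, sd_threshold=0.0)
            by_cluster = {a.pathway: a.cluster for a in moa}
            ok = (
                all(by_cluster[f"lof{i}"] == "LoF" for i in range(8))
                and all(by_cluster[f"sof{i}"] == "SoF" for i in range(8))
                and all(by_cluster[f"gof{i}"] == "GoF" for i in range(8))
            )
            recovered += ok
        assert recovered >= 19

    def test_degenerate_consensus_equals_plain_clustering(self):
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import pdist

        cns = self._block_matrix(3)
        moa = classify_moa(cns, n_resample=1, subsample=1.0, seed=0, sd_threshold=0.0)
        plain = fcluster(
            linkage(pdist(cns.nes), method="average"), t=3, criterion="maxclust"
        )
        # same partition (cluster labels may differ)
        ours = np.array([{"LoF": 0, "SoF": 1, "GoF": 2}[a.cluster] for a in moa])
        for c in np.unique(plain):
            assert len(set(ours[plain == c])) == 1

    def test_fixed_seed_reproducible(self):
        cns = self._block_matrix(5)
        a = classify_moa(cns, n_resample=30, seed=11)
        b = classify_moa(cns, n_resample=30, seed=11)
        assert [(x.pathway, x.cluster) for x in a] == [(x.pathway, x.cluster) for x in b]

    def test_k_exceeding_pathways_is_error(self):
        with pytest.raises(ValidationError, match="exceeds"):
            classify_moa(_cns(np.ones((2, 4))), k=3)

    def test_low_variance_pathways_assigned_by_centroid(self):
        cns = self._block_matrix(7)
        flat = _cns(np.full((1, 10), 1.9), rows=["flat"])
        combined = ScoreMatrix(
            cns.row_ids + ["flat"], cns.col_ids, np.vstack([cns.nes, flat.nes])
        )
        moa = classify_moa(combined, n_resample=30, seed=0, sd_threshold=0.0)
        assert {a.pathway: a.cluster for a in moa}["flat"] == "GoF"


class TestReassignMoa:
    def _gen(self, pathway, s):
        return GeneralityResult(pathway, 0, 0, 0, 0, s)

    def test_lof_with_high_generality_moves_to_gof(self):
        moa = [MoAAssignment("p", "LoF")]
        out = reassign_moa(moa, [self._gen("p", 7.2)])
        assert out[0].cluster == "GoF" and out[0].reassigned

    def test_symmetric_rule_and_below_threshold(self):
        moa = [MoAAssignment("a", "GoF"), MoAAssignment("b", "LoF")]
        out = reassign_moa(moa, [self._gen("a", -8.0), self._gen("b", 3.0)])
        assert out[0].cluster == "LoF" and out[0].reassigned
        assert out[1].cluster == "LoF" and not out[1].reassigned

    def test_idempotent(self):
        moa = [MoAAssignment("a", "LoF"), MoAAssignment("b", "SoF")]
        gen = [self._gen("a", 9.0), self._gen("b", 9.0)]
        once = reassign_moa(moa, gen)
        twice = reassign_moa(once, gen)
        assert [(x.pathway, x.cluster, x.reassigned) for x in once] == [
            (x.pathway, x.cluster, x.reassigned) for x in twice
        ]


class TestHypergeometric:
    def test_disjoint_and_total_overlap(self):
        universe = [f"g{i}" for i in range(20)]
        ann = GeneList("ann", universe[:5])
        assert hypergeometric_enrichment(universe[5:10], ann, universe) == pytest.approx(1.0)
        full = GeneList("all", universe)
        assert hypergeometric_enrichment(universe[:5], full, universe) == pytest.approx(1.0)

    def test_extreme_overlap_exact_value(self):
        universe = [f"g{i}" for i in range(20)]
        ann = GeneList("ann", universe[:5])
        p = hypergeometric_enrichment(universe[:5], ann, universe)
        from math import comb

        assert p == pytest.approx(1.0 / comb(20, 5))

    def test_empty_universe_is_error(self):
        with pytest.raises(ValidationError, match="universe"):
            hypergeometric_enrichment(["g"], GeneList("a", ["g"]), [])


def test_cluster_cancers_deterministic_leaf_order():
    rng = np.random.default_rng(9)
    base = rng.normal(size=(30, 6))
    base[:, 3] = base[:, 0] + rng.normal(0, 0.1, 30)  # c3 tracks c0
    cns = _cns(base)
    link1, order1 = cluster_cancers(cns)
    link2, order2 = cluster_cancers(cns)
    assert order1 == order2
    i0, i3 = order1.index("c0"), order1.index("c3")
    assert abs(i0 - i3) == 1  # correlated cancers are adjacent leaves
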