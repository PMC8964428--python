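import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdp.datatypes import CASE, CONTROL, ExpressionMatrix, ValidationError
from cdp.enrichment import (
    RankedList,
    compute_cns,
    enrichment_score,
    nes_and_significance,
    rank_genes,
    ssgsea_score,
)


def brute_force_es(ranked: RankedList, members: set, weight: float = 1.0) -> float:
    """Position-by-position running-sum oracle, independent of the cumsum path."""
    hits = [g in members for g in ranked.gene_ids]
    n, nh = len(hits), sum(hits)
    denom = sum(abs(m) ** weight for m, h in zip(ranked.metric_values, hits) if h)
    running, best = 0.0, 0.0
    for i in range(n):
        if hits[i]:
            running += (abs(ranked.metric_values[i]) ** weight / denom) if denom else 1.0 / nh
        else:
            running -= 1.0 / (n - nh)
        if abs(running) > abs(best):
            best = running
    return best


class TestRankGenes:
    def test_signal_to_noise_arithmetic(self):
        # one gene: mean_case=4, mean_control=2, sd floors at 0.2*|mean|
        values = np.array([[3.0, 5.0, 1.0, 3.0], [1.0, 1.0, 1.0, 1.0]])
        expr = ExpressionMatrix(
            ["g1", "g2"], ["a", "b", "c", "d"], values, [CASE, CASE, CONTROL, CONTROL]
        )
        ranked = rank_genes(expr, "signal_to_noise")
        # sd_case = sd_control = sqrt(2); snr = 2/(2*sqrt(2))
        assert ranked.gene_ids[0] == "g1"
        assert ranked.metric_values[0] == pytest.approx(2 / (2 * np.sqrt(2)))

    def test_identical_groups_tie_break_by_gene_id(self):
        values = np.ones((3, 4))
        expr = ExpressionMatrix(
            ["gC", "gA", "gB"], list("abcd"), values, [CASE, CASE, CONTROL, CONTROL]
        )
        ranked = rank_genes(expr)
        assert np.all(ranked.metric_values == 0)
        assert ranked.gene_ids == ["gA", "gB", "gC"]

    def test_planted_gene_ranks_first(self):
        rng = np.random.default_rng(0)
        values = rng.lognormal(2, 0.3, size=(10, 10))
        values[4, :5] *= 4.0  # 4-fold shift in cases
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(10)],
            [f"s{i}" for i in range(10)],
            values,
            [CASE] * 5 + [CONTROL] * 5,
        )
        assert rank_genes(expr).gene_ids[0] == "g4"

    def test_single_sample_group_rejected_for_snr(self):
        expr = ExpressionMatrix(
            ["g"], ["a", "b", "c"], np.array([[1.0, 2.0, 3.0]]),
            [CASE, CONTROL, CONTROL],
        )
        with pytest.raises(ValidationError, match="log2_fold_change"):
            rank_genes(expr, "signal_to_noise")


class TestEnrichmentScore:
    def test_single_hit_at_top_and_bottom(self):
        ranked = RankedList(list("abcd"), np.array([3.0, 2.0, 1.0, 0.5]))
        assert enrichment_score(ranked, {"a"}) == pytest.approx(1.0)
        assert enrichment_score(ranked, {"d"}) == pytest.approx(-1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(6, 21))
            metric = np.sort(rng.normal(size=n))[::-1]
            ids = [f"g{i}" for i in range(n)]
            size = int(rng.integers(2, n - 1))
            members = set(rng.choice(ids, size=size, replace=False))
            ranked = RankedList(ids, metric)
            assert enrichment_score(ranked, members) == pytest.approx(
                brute_force_es(ranked, members)
            )

    def test_degenerate_sets_rejected(self):
        ranked = RankedList(list("abc"), np.array([2.0, 1.0, 0.0]))
        with pytest.raises(ValidationError, match="no members"):
            enrichment_score(ranked, {"z"})
        with pytest.raises(ValidationError, match="entire"):
            enrichment_score(ranked, {"a", "b", "c"})

    @given(
        st.lists(
            st.floats(-10, 10, allow_nan=False), min_size=5, max_size=30, unique=True
        ),
        st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_antisymmetric_under_reversal(self, metric, data):
        """|ES| <= 1 always; reversing the list with negated metric flips ES."""
        metric = np.array(sorted(metric, reverse=True))
        ids = [f"g{i}" for i in range(len(metric))]
        size = data.draw(st.integers(1, len(ids) - 1))
        members = set(ids[:size] if size % 2 else ids[-size:])
        ranked = RankedList(ids, metric)
        es = enrichment_score(ranked, members)
        assert -1.0 <= es <= 1.0
        reversed_ranked = RankedList(ids[::-1], -metric[::-1])
        es_rev = enrichment_score(reversed_ranked, members)
        assert es_rev == pytest.approx(-es, abs=1e-9)


class TestNesAndSignificance:
    def test_fixed_seed_is_deterministic(self):
        ranked = RankedList([f"g{i}" for i in range(30)], np.linspace(3, -3, 30))
        members = {f"g{i}" for i in range(5)}
        es = enrichment_score(ranked, members)
        r1 = nes_and_significance(es, ranked, members, n_perm=200, seed=7)
        r2 = nes_and_significance(es, ranked, members, n_perm=200, seed=7)
        assert (r1.nes, r1.p_emp) == (r2.nes, r2.p_emp)

    def test_planted_enrichment_detected(self):
        """Set genes shifted to the top => positive NES, significant p."""
        rng = np.random.default_rng(1)
        hits = 0
        for trial in range(20):
            metric = rng.normal(size=100)
            members = {f"g{i}" for i in rng.choice(100, 10, replace=False)}
            ids = [f"g{i}" for i in range(100)]
            metric = np.array(
                [m + (2.5 if g in members else 0.0) for g, m in zip(ids, metric)]
            )
            order = np.argsort(-metric)
            ranked = RankedList([ids[i] for i in order], metric[order])
            es = enrichment_score(ranked, members)
            res = nes_and_significance(es, ranked, members, n_perm=200, seed=trial)
            if res.nes > 0 and res.p_emp <= 0.05:
                hits += 1
        assert hits >= 19

    def test_p_has_pseudocount(self):
        """Empirical p can never be exactly zero."""
        ranked = RankedList([f"g{i}" for i in range(50)], np.linspace(5, -5, 50))
        members = {f"g{i}" for i in range(5)}
        es = enrichment_score(ranked, members)
        res = nes_and_significance(es, ranked, members, n_perm=100, seed=0)
        assert res.p_emp > 0


class TestComputeCns:
    def test_planted_signs_and_shape(self, planted_cohort):
        cfg, sets, expr = planted_cohort
        cns = compute_cns({"C1": expr}, sets, n_perm=200, seed=0)
        assert cns.shape == (8, 1)
        up = cns.value("SET_000", "C1")
        down = cns.value("SET_001", "C1")
        assert up > 0 and down < 0
        assert cns.value("SET_000", "C1", "p") < 0.05
        assert cns.value("SET_001", "C1", "p") < 0.05

    def test_column_order_follows_cohort_order(self, planted_cohort):
        cfg, sets, expr = planted_cohort
        a = compute_cns({"X": expr, "Y": expr}, sets, n_perm=50, seed=0)
        b = compute_cns({"Y": expr, "X": expr}, sets, n_perm=50, seed=0)
        assert a.col_ids == ["X", "Y"] and b.col_ids == ["Y", "X"]

    def test_small_cohort_falls_back_to_gene_set_scheme(self, caplog):
        rng = np.random.default_rng(3)
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(60)],
            [f"s{i}" for i in range(6)],
            rng.lognormal(2, 1, size=(60, 6)),
            [CASE] * 3 + [CONTROL] * 3,
        )
        from cdp.datatypes import GeneSetCollection

        sets = GeneSetCollection({"S": [f"g{i}" for i in range(10)]})
        import logging

        with caplog.at_level(logging.WARNING, logger="cdp.enrichment"):
            cns = compute_cns({"C": expr}, sets, permutation_scheme="phenotype",
                              n_perm=50, seed=0)
        assert "gene-set permutation" in caplog.text
        assert np.isfinite(cns.nes).all()


class TestSsgsea:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=40)
        ids = [f"g{i}" for i in range(40)]
        members = {f"g{i}" for i in range(0, 40, 7)}
        s1 = ssgsea_score(vals, ids, members)
        s2 = ssgsea_score(np.exp(vals) * 10 + 3, ids, members)
        assert s1 == pytest.approx(s2)

    def test_top_ranks_score_higher_than_bottom(self):
        vals = np.linspace(10, 1, 20)
        ids = [f"g{i}" for i in range(20)]
        top = {f"g{i}" for i in range(4)}
        bottom = {f"g{i}" for i in range(16, 20)}
        assert ssgsea_score(vals, ids, top) > ssgsea_score(vals, ids, bottom)

    def test_matches_weighted_ecdf_oracle(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=50)
        ids = [f"g{i}" for i in range(50)]
        members = set(rng.choice(ids, 5, replace=False))
        alpha = 0.25
        # independent oracle: explicit double loop over positions
        order = sorted(range(50), key=lambda i: (-vals[i], ids[i]))
        in_cum = out_cum = 0.0
        w_total = sum(
            (50 - pos) ** alpha
            for pos, i in enumerate(order)
            if ids[i] in members
        )
        n_out = 50 - len(members)
        expected = 0.0
        for pos, i in enumerate(order):
            if ids[i] in members:
                in_cum += (50 - pos) ** alpha / w_total
            else:
                out_cum += 1.0 / n_out
            expected += in_cum - out_cum
        assert ssgsea_score(vals, ids, members, alpha) == pytest.approx(expected)

    def test_score_increases_as_members_move_up(self):
        ids = [f"g{i}" for i in range(30)]
        vals = np.linspace(30, 1, 30)
        members_positions = [(20, 25), (10, 25), (10, 15), (0, 5)]
        scores = []
        for a, b in members_positions:
            scores.append(ssgsea_score(vals, ids, {ids[a], ids[b]}))
        assert scores == sorted(scores)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            ssgsea_score(np.ones(10), [f"g{i}" for i in range(10)], {"g1"})
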