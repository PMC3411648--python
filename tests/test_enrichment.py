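"""Hypergeometric scoring, null baselines, empirical P and weighted ranking."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mirvote as mv
from mirvote.enrichment import EnrichmentError, NullBaseline, add_bh_column

from oracles import upper_tail_by_enumeration


class TestHyperPvalue:
    def test_k_zero_is_one(self):
        assert mv.hyper_pvalue(0, 4, 5, 10) == 1.0
        assert mv.hyper_pvalue(0, 1, 1, 2) == 1.0

    def test_worked_enumeration_case(self):
        # (C(4,3)C(6,2) + C(4,4)C(6,1)) / C(10,5) = 66/252
        expected = Fraction(66, 252)
        assert mv.hyper_pvalue(3, 4, 5, 10) == pytest.approx(float(expected), abs=1e-12)
        assert upper_tail_by_enumeration(3, 4, 5, 10) == expected

    def test_forced_full_overlap(self):
        assert mv.hyper_pvalue(5, 5, 5, 5) == pytest.approx(1.0)

    @pytest.mark.parametrize("k,K,n,N", [(-1, 4, 5, 10), (5, 4, 5, 10), (3, 11, 5, 10), (3, 4, 11, 10)])
    def test_domain_errors(self, k, K, n, N):
        with pytest.raises(ValueError):
            mv.hyper_pvalue(k, K, n, N)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(1, 30), st.integers(1, 30), st.integers(0, 30))
    def test_monotone_nonincreasing_in_k(self, K, n, N_extra):
        N = max(K, n) + N_extra
        ps = [mv.hyper_pvalue(k, K, n, N) for k in range(min(K, n) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_matches_enumeration_small_universe(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    if K == 0 or n == 0:
                        continue
                    for k in range(min(K, n) + 1):
                        exact = float(upper_tail_by_enumeration(k, K, n, N))
                        assert mv.hyper_pvalue(k, K, n, N) == pytest.approx(exact, abs=1e-12)


def pw(pid, genes, name="p", src="DB"):
    return mv.PathwayRecord(pid, name, src, frozenset(genes))


class TestEnrich:
    universe = [f"g{i}" for i in range(10)]

    def test_disjoint_pathway_scores_zero(self):
        rows = mv.enrich({"g0", "g1"}, [pw("P1", ["g8", "g9"])], self.universe)
        (r,) = rows
        assert r.overlap == 0 and r.raw_p == 1.0 and r.neg_log_p == 0.0

    def test_worked_overlap(self):
        targets = {f"g{i}" for i in range(5)}
        rows = mv.enrich(targets, [pw("P1", ["g0", "g1", "g2", "g9"])], self.universe)
        assert rows[0].raw_p == pytest.approx(66 / 252, abs=1e-12)

    def test_identical_gene_sets_identical_p(self):
        ps = [pw("A1", ["g0", "g1"], src="DB1"), pw("A2", ["g0", "g1"], src="DB2")]
        rows = mv.enrich({"g0"}, ps, self.universe)
        assert rows[0].raw_p == rows[1].raw_p and len(rows) == 2

    def test_targets_outside_universe_dropped(self):
        rows = mv.enrich({"g0", "not_in_universe"}, [pw("P1", ["g0"])], self.universe)
        assert rows[0].n_targets == 1

    def test_empty_targets_error(self):
        with pytest.raises(EnrichmentError, match="no targets"):
            mv.enrich(set(), [pw("P1", ["g0"])], self.universe)

    def test_sorted_by_neg_log_p(self):
        ps = [pw("B", ["g0", "g1", "g2"]), pw("A", ["g8", "g9"]), pw("C", ["g0"])]
        rows = mv.enrich({"g0", "g1"}, ps, self.universe)
        vals = [r.neg_log_p for r in rows]
        assert vals == sorted(vals, reverse=True)

    def test_bh_column_optional_extra(self):
        ps = [pw("B", ["g0", "g1"]), pw("A", ["g8", "g9"])]
        rows = mv.enrich({"g0", "g1"}, ps, self.universe)
        assert all(r.bh_q is None for r in rows)
        add_bh_column(rows)
        assert all(0 <= r.bh_q <= 1 for r in rows)


class TestNullBaseline:
    def test_single_rep_bookkeeping(self, default_fixture, default_store):
        bl = mv.build_null_baseline(
            default_store, default_fixture.pathways, sizes=[4], reps=1, seed=5
        )
        assert bl.values[4].shape == (len(default_fixture.pathways), 1)

    def test_same_seed_bit_identical(self, default_fixture, default_store, tmp_path):
        kw = dict(sizes=[3], reps=5, seed=11)
        a = mv.build_null_baseline(default_store, default_fixture.pathways, **kw)
        b = mv.build_null_baseline(default_store, default_fixture.pathways, **kw)
        assert np.array_equal(a.values[3], b.values[3])
        a.save(tmp_path / "a.json")
        b.save(tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_metadata_records_defaults(self, default_fixture, default_store):
        bl = mv.build_null_baseline(
            default_store, default_fixture.pathways, sizes=[2], reps=1, seed=0
        )
        md = bl.metadata
        assert md["min_oe"] == 2.0 and md["min_hits"] == 3 and md["include_validated"]

    def test_size_exceeding_universe(self, default_fixture, default_store):
        with pytest.raises(ValueError, match="exceed"):
            mv.build_null_baseline(
                default_store, default_fixture.pathways, sizes=[10_000], reps=1
            )

    def test_round_trip_and_fingerprint_guard(self, default_fixture, default_store, tmp_path):
        bl = mv.build_null_baseline(
            default_store, default_fixture.pathways, sizes=[2], reps=3, seed=1
        )
        bl.save(tmp_path / "b.json")
        loaded = NullBaseline.load(tmp_path / "b.json", default_store.fingerprint())
        assert np.array_equal(loaded.values[2], bl.values[2])
        with pytest.raises(EnrichmentError, match="different prediction store"):
            NullBaseline.load(tmp_path / "b.json", "deadbeef")


class TestEmpiricalPvalue:
    @staticmethod
    def synthetic_baseline(nulls, pid="P1", size=3):
        arr = np.sort(np.asarray(nulls, dtype=float))[None, :]
        return NullBaseline(sizes=[size], reps=arr.shape[1], pathway_ids=[pid],
                            values={size: arr})

    def test_smaller_than_all_nulls(self):
        bl = self.synthetic_baseline(np.linspace(0.01, 1.0, 1000))
        assert mv.empirical_pvalue(0.001, bl, 3, "P1") == pytest.approx(1 / 1001)

    def test_observed_one_saturates(self):
        bl = self.synthetic_baseline(np.linspace(0.01, 1.0, 1000))
        assert mv.empirical_pvalue(1.0, bl, 3, "P1") == 1.0

    def test_observed_at_median(self):
        nulls = np.linspace(0.0005, 0.9995, 999)
        bl = self.synthetic_baseline(nulls)
        emp = mv.empirical_pvalue(float(np.median(nulls)), bl, 3, "P1")
        assert emp == pytest.approx(0.5, abs=0.01)

    def test_unknown_pathway(self):
        bl = self.synthetic_baseline([0.5])
        with pytest.raises(EnrichmentError, match="absent"):
            mv.empirical_pvalue(0.5, bl, 3, "nope")

    def test_nearest_size_fallback(self):
        bl = self.synthetic_baseline(np.linspace(0.01, 1.0, 100), size=10)
        assert mv.empirical_pvalue(0.005, bl, 99, "P1") == pytest.approx(1 / 101)


class TestWeightedScores:
    def test_weight_normalisation_with_signs(self):
        w = mv.expression_weights({"a": 2.0, "b": -2.0})
        assert w == {"a": 0.5, "b": 0.5}

    def test_all_zero_expression_error(self):
        with pytest.raises(EnrichmentError, match="degenerate"):
            mv.expression_weights({"a": 0.0, "b": 0.0})

    def test_worked_score(self):
        per = {"a": {"P": 0.01}, "b": {"P": 0.1}}
        scores = mv.weighted_scores(per, {"a": 1.0, "b": -1.0})
        assert scores["P"] == pytest.approx(0.5 * 2 + 0.5 * 1)

    def test_single_mirna_reverts_to_neg_log_ranking(self):
        per = {"a": {"P1": 0.5, "P2": 0.01, "P3": 0.2}}
        scores = mv.weighted_scores(per, {"a": 3.7})
        ranked = sorted(scores, key=lambda p: -scores[p])
        by_logp = sorted(per["a"], key=lambda p: per["a"][p])
        assert ranked == by_logp
        for p, raw in per["a"].items():
            assert scores[p] == pytest.approx(-math.log10(raw))

    def test_equal_weights_match_mean_neg_log_ranking(self):
        rng = np.random.default_rng(3)
        per = {
            m: {f"P{j}": float(rng.uniform(1e-6, 1)) for j in range(8)}
            for m in ("a", "b", "c")
        }
        scores = mv.weighted_scores(per, {"a": 1.0, "b": 1.0, "c": 1.0})
        mean_neglog = {
            p: np.mean([-math.log10(per[m][p]) for m in per]) for p in per["a"]
        }
        assert sorted(scores, key=lambda p: -scores[p]) == sorted(
            mean_neglog, key=lambda p: -mean_neglog[p]
        )

    def test_missing_expression_error(self):
        with pytest.raises(EnrichmentError, match="missing"):
            mv.weighted_scores({"a": {"P": 0.1}}, {"b": 1.0})

    def test_end_to_end_weighted_ranking(self, planted_fixture):
        store = planted_fixture.store()
        query = planted_fixture.truth["pairs"]["planted_query"]
        expr = {m: 1.5 for m in query}
        q = mv.QuerySet.from_list(query, expr)
        ranking = mv.weighted_pathway_ranking(q, store, planted_fixture.pathways)
        assert ranking[0][0] == planted_fixture.truth["pathways"]["planted_pathway_id"]
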