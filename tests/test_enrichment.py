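"""Over-representation analysis against exact brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netpathad.datatypes import GeneSet, PathwayRecord
from netpathad.enrichment import bh_adjust, enrich, hypergeom_tail
from netpathad.synth import make_pathway_db, make_query, make_universe

from _oracles import bh_stepup, hypergeom_tail_exact


class TestHypergeomTail:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_tail(0, 10, 5, 40) == 1.0

    def test_full_overlap_single_arrangement(self):
        # drawing all 5 special genes in 5 draws from 20: 1 / C(20,5)
        assert hypergeom_tail(5, 5, 5, 20) == pytest.approx(1 / 15504,
                                                            rel=1e-12)

    def test_query_equals_universe(self):
        assert hypergeom_tail(7, 7, 30, 30) == 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hypergeom_tail(3, 2, 5, 10)  # k > K
        with pytest.raises(ValueError):
            hypergeom_tail(0, 11, 5, 10)  # K > N
        with pytest.raises(ValueError):
            hypergeom_tail(-1, 2, 5, 10)

    def test_matches_exact_oracle_on_sampled_grid(self):
        rng = np.random.default_rng(20240917)
        for _ in range(400):
            N = int(rng.integers(1, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            got = hypergeom_tail(k, K, n, N)
            want = hypergeom_tail_exact(k, K, n, N)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-300)


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_hand_computed_vectors(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03])
        assert bh_adjust([0.005, 0.04, 0.9]) == pytest.approx(
            [0.015, 0.06, 0.9])

    def test_empty(self):
        assert bh_adjust([]) == []

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([1.5])

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_matches_stepup_oracle(self, ps):
        assert bh_adjust(ps) == pytest.approx(bh_stepup(ps), rel=1e-12)

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2,
                    max_size=20),
           st.randoms(use_true_random=False))
    @settings(max_examples=60, derandomize=True)
    def test_permutation_equivariance(self, ps, rng):
        idx = list(range(len(ps)))
        rng.shuffle(idx)
        direct = bh_adjust(ps)
        permuted = bh_adjust([ps[i] for i in idx])
        assert permuted == pytest.approx([direct[i] for i in idx])

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(max_examples=60, derandomize=True)
    def test_outputs_bounded(self, ps):
        adj = bh_adjust(ps)
        assert all(a >= p and a <= 1.0 for a, p in zip(adj, ps))


class TestEnrich:
    def test_query_equals_single_pathway_universe(self):
        gs = GeneSet("q", ["A", "B", "C"])
        db = [PathwayRecord("P1", "P1", GeneSet("P1", ["A", "B", "C"]))]
        (res,) = enrich(gs, db, universe=gs)
        assert res.p_raw == 1.0 and not res.significant

    def test_planted_pathway_detected(self):
        universe = make_universe(2000)
        db = make_pathway_db(universe, 1, (50, 50), 0.0, seed=3)
        query = make_query(universe, db, 100, 0.3, seed=4)
        (res,) = enrich(query, db, universe=universe)
        assert res.k >= 25 and res.p_bh < 1e-10 and res.significant

    def test_disjoint_query_no_significant(self):
        universe = make_universe(100)
        db = make_pathway_db(universe, 3, (10, 10), 0.0, seed=5,
                             disjoint=True)
        member = set().union(*(r.members.genes for r in db))
        query = GeneSet("q", sorted(universe.genes - member)[:10])
        results = enrich(query, db, universe=universe, keep_empty=True)
        assert all(not r.significant for r in results)
        assert all(r.k == 0 for r in results)

    def test_sorting_and_invariants(self):
        universe = make_universe(500)
        db = make_pathway_db(universe, 8, (20, 40), 0.4, seed=6)
        query = make_query(universe, db[:2], 60, 0.5, seed=7)
        results = enrich(query, db, universe=universe)
        p_raws = [r.p_raw for r in results]
        assert p_raws == sorted(p_raws)
        for r in results:
            assert r.k == len(r.overlap_genes) >= 1
            assert r.p_raw <= r.p_bh <= 1.0

    def test_bad_threshold(self):
        db = [PathwayRecord("P1", "P1", GeneSet("P1", ["A", "B"]))]
        with pytest.raises(ValueError):
            enrich(GeneSet("q", ["A"]), db, fdr_threshold=1.0)

    def test_query_outside_universe_errors(self):
        db = [PathwayRecord("P1", "P1", GeneSet("P1", ["A", "B"]))]
        with pytest.raises(ValueError, match="universe"):
            enrich(GeneSet("q", ["ZZZ"]), db)


class TestCalibration:
    """Power and type-I behaviour under the planted-enrichment generator."""

    N_REPLICATES = 200

    def _detection_rate(self, planted_frac: float, background: str) -> float:
        universe = make_universe(2000)
        db = make_pathway_db(universe, 1, (50, 50), 0.0, seed=11)
        hits = 0
        for rep in range(self.N_REPLICATES):
            query = make_query(universe, db, 100, planted_frac,
                               seed=100_000 + rep, background=background)
            (res,) = enrich(query, db, universe=universe, keep_empty=True)
            hits += bool(res.significant)
        return hits / self.N_REPLICATES

    def test_power_with_planted_effect(self):
        assert self._detection_rate(0.3, "complement") >= 0.99

    def test_type_one_error_without_effect(self):
        # uniform null: query drawn from the whole universe, chance overlap
        rate = self._detection_rate(0.0, "universe")
        assert rate <= 0.075
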