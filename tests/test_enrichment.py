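"""Overlap/enrichment statistics against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mpem_interactome import interactome as inter
from mpem_interactome.enrichment import (
    ValidationError,
    bh_adjust,
    fisher_enrichment,
    hypergeom_overlap,
    interactome_overlap,
    overlap_test_from_counts,
)
from mpem_interactome.io import EdgeRecord, GeneSetCollection


def genes(prefix, n):
    return [f"{prefix}{i}" for i in range(n)]


class TestHypergeomOverlap:
    def test_disjoint_sets_give_p_one(self):
        u = genes("U", 20)
        r = hypergeom_overlap(u[:5], u[5:10], u)
        assert r.p == 1.0
        assert r.table.k == 0

    def test_enumeration_oracle_small_universe(self):
        """n_univ=10, n_a=5, n_b=4, k=4: exhaustive enumeration of all
        C(10,4) draws gives P(K >= 4) = 5/210."""
        u = genes("U", 10)
        a, b = u[:5], u[:4]
        count = sum(
            1 for draw in itertools.combinations(u, 4) if len(set(draw) & set(a)) >= 4
        )
        expected = count / math.comb(10, 4)
        assert expected == pytest.approx(5 / 210)
        r = hypergeom_overlap(a, b, u)
        assert r.p == pytest.approx(expected, rel=1e-12)

    def test_set_a_equal_universe_forces_full_overlap(self):
        u = genes("U", 12)
        r = hypergeom_overlap(u, u[:4], u)
        assert r.table.k == 4
        assert r.p == 1.0

    def test_members_outside_universe_are_dropped(self):
        u = genes("U", 10)
        r = hypergeom_overlap(u[:3] + ["ALIEN"], u[:3], u)
        assert r.table.n_a == 3

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_overlap(["A"], ["A"], [])

    def test_zero_cell_odds_ratio_finite(self):
        u = genes("U", 10)
        r = hypergeom_overlap(u[:4], u[:4], u)  # c cell = 0
        assert np.isfinite(r.odds_ratio) and r.odds_ratio > 0


class TestFisherEnrichment:
    def test_single_set_q_equals_p(self):
        u = genes("U", 50)
        coll = GeneSetCollection("c", {"S": frozenset(u[:10])})
        (r,) = fisher_enrichment(u[:10], coll, u)
        assert r.q == r.p

    def test_matching_set_ranks_first_vs_direct_fisher(self):
        u = genes("U", 100)
        coll = GeneSetCollection(
            "c",
            {
                "match": frozenset(u[:10]),
                "half": frozenset(u[5:15]),
                "off": frozenset(u[50:60]),
            },
        )
        results = fisher_enrichment(u[:10], coll, u)
        by_p = sorted(results, key=lambda r: r.p)
        assert by_p[0].label == "match"
        # oracle: direct Fisher on the 2x2 table
        _, p_direct = stats.fisher_exact([[10, 0], [0, 90]], alternative="greater")
        assert by_p[0].p == pytest.approx(p_direct, rel=1e-12)

    def test_identical_sets_get_identical_p_and_q(self):
        u = genes("U", 40)
        coll = GeneSetCollection(
            "c", {f"S{i}": frozenset(u[:8]) for i in range(3)}
        )
        results = fisher_enrichment(u[:8], coll, u)
        assert len({r.p for r in results}) == 1
        assert len({r.q for r in results}) == 1

    def test_disjoint_query_rejected(self):
        u = genes("U", 10)
        coll = GeneSetCollection("c", {"S": frozenset(u[:3])})
        with pytest.raises(ValidationError):
            fisher_enrichment(["ALIEN"], coll, u)


class TestBhAdjust:
    def test_hand_step_up_values(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        # classic staggered vector, computed by hand:
        # sorted p (m=4): .005 -> .02, .04 -> .08, .06 -> .08, .9 -> .9
        assert bh_adjust([0.04, 0.9, 0.005, 0.06]) == pytest.approx([0.08, 0.9, 0.02, 0.08])

    def test_single_p_unchanged_and_ones_stay_ones(self):
        assert bh_adjust([0.2]) == [pytest.approx(0.2)]
        assert bh_adjust([1.0, 1.0]) == [1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, derandomize=True)
    def test_permutation_invariance_and_bounds(self, ps, rnd):
        q = bh_adjust(ps)
        assert all(qi >= pi - 1e-15 for qi, pi in zip(q, ps))
        assert all(qi <= 1.0 for qi in q)
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        q_perm = bh_adjust([ps[i] for i in perm])
        assert q_perm == pytest.approx([q[i] for i in perm])


class TestInteractomeOverlap:
    def test_identical_interactomes_full_overlap(self, small_interactome):
        u = sorted(small_interactome.nodes) + genes("U", 50)
        res = interactome_overlap(small_interactome, small_interactome, u)
        assert res["n_shared"] == len(small_interactome.nodes)
        assert res["enrichment"].table.k == len(small_interactome.nodes)
        assert sorted(res["shared_seeds"]) == sorted(small_interactome.seeds)

    def test_planted_node_sharing_recovered_exactly(self):
        u = genes("U", 1000)
        shared = u[:50]
        net_a = inter.assemble(
            ["SA"], [EdgeRecord.make("SA", g) for g in shared + u[50:100]]
        )
        net_b = inter.assemble(
            ["SB"], [EdgeRecord.make("SB", g) for g in shared + u[100:150]]
        )
        universe = u + ["SA", "SB"]
        res = interactome_overlap(net_a, net_b, universe)
        assert res["n_shared"] == 50  # the planted 50% sharing, exactly
        assert res["enrichment"].p < 1e-20
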