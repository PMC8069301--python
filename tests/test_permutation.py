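import itertools
import math
import random

import numpy as np
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

from nicd.candidates import find_primary_candidates
from nicd.disgenet import DiseaseGeneMapping, DiseaseQuery
from nicd.network import GeneNetwork, GeneSet
from nicd.permutation import (
    PermutationConfig,
    bh_adjust,
    empirical_pvalue,
    run_permutation,
    sample_null_replicate,
    significant_drivers,
)

import test_disgenet


class TestEmpiricalPvalue:
    @pytest.mark.parametrize(
        "x,iters,expected",
        [(0, 1000, 0.0), (1000, 1000, 1.0), (49, 361_000, 49 / 361_000)],
    )
    def test_exact_ratio(self, x, iters, expected):
        assert empirical_pvalue(x, iters) == expected

    def test_matches_printed_reference_precision(self):
        # 3/361000 prints as 8.31e-6; 49/361000 prints as 1.36e-4
        assert f"{empirical_pvalue(3, 361_000):.2e}" == "8.31e-06"
        assert f"{empirical_pvalue(49, 361_000):.2e}" == "1.36e-04"

    def test_plus_one_mode(self):
        assert empirical_pvalue(0, 99, plus_one=True) == pytest.approx(0.01)

    def test_count_exceeding_iterations_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(5, 4)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.5], [0.5]),
            ([0.05, 0.01], [0.05, 0.02]),
        ],
    )
    def test_hand_worked_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.2, 1.5])

    def test_empty(self):
        assert bh_adjust([]) == []

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50),
           st.randoms(use_true_random=False))
    def test_matches_stepup_oracle_and_statsmodels(self, p, rnd):
        def stepup(ps):
            m = len(ps)
            order = sorted(range(m), key=lambda i: ps[i])
            q = [0.0] * m
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, ps[i] * m / rank)
                q[i] = running
            return q

        got = bh_adjust(p)
        assert got == pytest.approx(stepup(p))
        assert got == pytest.approx(multipletests(p, method="fdr_bh")[1].tolist())
        for qi, pi in zip(got, p):
            assert qi >= pi - 1e-12
        # monotone along sorted p
        pairs = sorted(zip(p, got))
        for (_, q1), (_, q2) in zip(pairs, pairs[1:]):
            assert q2 >= q1 - 1e-12


class TestSampleNullReplicate:
    def test_deterministic_given_seed(self):
        uni = ("A", "B", "C")
        a1 = sample_null_replicate(np.random.default_rng(5), "gene",
                                   universe=uni, size_a=1, size_b=1)
        a2 = sample_null_replicate(np.random.default_rng(5), "gene",
                                   universe=uni, size_a=1, size_b=1)
        assert a1 == a2

    def test_zero_size(self):
        a, b = sample_null_replicate(np.random.default_rng(0), "gene",
                                     universe=("A", "B"), size_a=0, size_b=2)
        assert a == set() and len(b) == 2

    def test_oversized_request_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            sample_null_replicate(np.random.default_rng(0), "gene",
                                  universe=("A", "B", "C"), size_a=4, size_b=1)

    def test_disease_id_mode_expands_cuis(self):
        t = test_disgenet.dvt([("C01", "rs1"), ("C02", "rs2")])
        m = test_disgenet.vgt([("rs1", "G1"), ("rs2", "G2")])
        mapping = DiseaseGeneMapping(t, m, DiseaseQuery("a", ["C01"]),
                                     DiseaseQuery("b", ["C02"]))
        a, b = sample_null_replicate(np.random.default_rng(1), "disease_id",
                                     universe=("C01", "C02"), size_a=2, size_b=2,
                                     mapping=mapping)
        assert a == b == {"G1", "G2"}


def toy_exact_probability():
    """Enumerate all 25 ordered (A, B) single-gene samples on the 5-node toy.

    c1's neighbours are {d1, o1}; c1 is a null candidate iff A and B both
    fall in that set, hence 2/5 · 2/5 = 4/25.
    """
    universe = ["D1", "O1", "C1", "C2", "X5"]
    adj = {"C1": {"D1", "O1"}, "C2": {"D1"}, "D1": {"C1", "C2"},
           "O1": {"C1"}, "X5": set()}
    hits = 0
    for a, b in itertools.product(universe, repeat=2):
        sa, sb = {a}, {b}
        if adj["C1"] & sa and adj["C1"] & sb and "C1" not in sa | sb:
            hits += 1
    return hits / 25


class TestRunPermutation:
    def test_complete_graph_candidate_always_rediscovered(self):
        nodes = [f"g{i}" for i in range(6)]
        net = GeneNetwork.from_edges(itertools.combinations(nodes, 2))
        # size-2 samples: any pair contains a neighbour of every node in K6
        set_a, set_b = GeneSet("a", ["g0", "g1"]), GeneSet("b", ["g2", "g3"])
        cands = find_primary_candidates(net, set_a, set_b, exclude_seeds=False)
        cfg = PermutationConfig(mode="gene", iterations=200, seed=0)
        res = run_permutation(net, set_a, set_b, cands, cfg)
        # every node neighbours every sampled gene: always rediscovered, p = 1
        assert all(res.p[g] == 1.0 for g in res.genes)
        assert all(res.x[g] == res.iterations for g in res.genes)

    def test_toy_exact_null(self, toy5):
        exact = toy_exact_probability()
        assert exact == pytest.approx(4 / 25)
        set_a, set_b = GeneSet("a", ["d1"]), GeneSet("b", ["o1"])
        cands = find_primary_candidates(toy5, set_a, set_b)
        assert cands.genes() == ["C1"]
        iters = 10_000
        res = run_permutation(toy5, set_a, set_b, cands,
                              PermutationConfig(mode="gene", iterations=iters, seed=42))
        se = math.sqrt(exact * (1 - exact) / iters)
        assert abs(res.p["C1"] - exact) <= 4 * se

    def test_bit_identical_given_seed(self, toy5):
        set_a, set_b = GeneSet("a", ["d1"]), GeneSet("b", ["o1"])
        cands = find_primary_candidates(toy5, set_a, set_b)
        cfg = PermutationConfig(mode="gene", iterations=500, seed=7)
        r1 = run_permutation(toy5, set_a, set_b, cands, cfg)
        r2 = run_permutation(toy5, set_a, set_b, cands, cfg)
        assert r1.x == r2.x and r1.p == r2.p and r1.q == r2.q

    def test_default_iterations_is_100n(self, toy5):
        set_a, set_b = GeneSet("a", ["d1"]), GeneSet("b", ["o1"])
        cands = find_primary_candidates(toy5, set_a, set_b)
        res = run_permutation(toy5, set_a, set_b, cands,
                              PermutationConfig(mode="gene", seed=0))
        assert res.iterations == 100 * len(cands)

    def test_q_at_least_p_and_in_unit_interval(self, toy5):
        set_a, set_b = GeneSet("a", ["d1"]), GeneSet("b", ["o1"])
        cands = find_primary_candidates(toy5, set_a, set_b)
        res = run_permutation(toy5, set_a, set_b, cands,
                              PermutationConfig(mode="gene", iterations=2000, seed=1))
        for g in res.genes:
            assert res.p[g] <= res.q[g] <= 1.0

    def test_count_conservation_across_replicates(self):
        rng = random.Random(3)
        nodes = [f"g{i}" for i in range(12)]
        edges = [(a, b) for a, b in itertools.combinations(nodes, 2)
                 if rng.random() < 0.3]
        net = GeneNetwork.from_edges(edges, nodes=nodes)
        set_a = GeneSet("a", nodes[:3])
        set_b = GeneSet("b", nodes[3:5])
        cands = find_primary_candidates(net, set_a, set_b, exclude_seeds=False)
        cfg = PermutationConfig(mode="gene", iterations=800, seed=11,
                                record_replicates=True)
        res = run_permutation(net, set_a, set_b, cands, cfg)
        assert sum(res.x.values()) == sum(res.replicate_hits)
        assert len(res.replicate_hits) == 800

    def test_disease_id_mode_deterministic(self):
        dv = [("C01", "rs1"), ("C02", "rs2"), ("C03", "rs3"), ("C04", "rs4")]
        vg = [("rs1", "d1"), ("rs2", "o1"), ("rs3", "c2"), ("rs4", "x5")]
        mapping = DiseaseGeneMapping(
            test_disgenet.dvt(dv), test_disgenet.vgt(vg),
            DiseaseQuery("a", ["C01"]), DiseaseQuery("b", ["C02"]),
        )
        net = GeneNetwork.from_edges([("d1", "c1"), ("o1", "c1"), ("d1", "c2")],
                                     nodes=["x5"])
        set_a = mapping.gene_set(mapping.query_a)
        set_b = mapping.gene_set(mapping.query_b)
        cands = find_primary_candidates(net, set_a, set_b)
        cfg = PermutationConfig(mode="disease_id", iterations=400, seed=9)
        r1 = run_permutation(net, set_a, set_b, cands, cfg, mapping=mapping)
        r2 = run_permutation(net, set_a, set_b, cands, cfg, mapping=mapping)
        assert r1.x == r2.x
        # exact null: the sampled CUI expands to one of {d1},{o1},{c2},{x5};
        # c1 (neighbours {d1,o1}) is a null candidate iff both draws land in
        # {C01, C02}: P = 2/4 · 2/4 = 1/4
        se = math.sqrt((1 / 4) * (3 / 4) / 400)
        assert abs(r1.p["C1"] - 1 / 4) <= 4 * se

    def test_disease_id_requires_mapping(self, toy5):
        set_a, set_b = GeneSet("a", ["d1"]), GeneSet("b", ["o1"])
        cands = find_primary_candidates(toy5, set_a, set_b)
        with pytest.raises(ValueError, match="mapping|tables"):
            run_permutation(toy5, set_a, set_b, cands,
                            PermutationConfig(mode="disease_id", seed=0))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PermutationConfig(iterations=0)
        with pytest.raises(ValueError):
            PermutationConfig(alpha=0.0)
        with pytest.raises(ValueError):
            PermutationConfig(mode="bogus")


class TestSignificantDrivers:
    def _setup(self):
        net = GeneNetwork.from_edges(
            [("d1", "c1"), ("o1", "c1"), ("d1", "c2"), ("o1", "c2")]
        )
        set_a, set_b = GeneSet("a", ["d1"]), GeneSet("b", ["o1"])
        return net, find_primary_candidates(net, set_a, set_b)

    def test_all_insignificant(self):
        from nicd.permutation import PermutationResult

        _, cands = self._setup()
        res = PermutationResult(genes=cands.genes(),
                                x={g: 100 for g in cands.genes()},
                                p={g: 1.0 for g in cands.genes()},
                                q={g: 1.0 for g in cands.genes()},
                                iterations=100, seed=0, mode="gene")
        assert len(significant_drivers(res, cands, alpha=0.05)) == 0

    def test_threshold_filters_and_orders_by_p(self):
        from nicd.permutation import PermutationResult

        _, cands = self._setup()
        genes = cands.genes()  # ["C1", "C2"]
        res = PermutationResult(genes=genes, x={"C1": 1, "C2": 20},
                                p={"C1": 0.01, "C2": 0.20},
                                q={"C1": 0.01, "C2": 0.20},
                                iterations=100, seed=0, mode="gene")
        out = significant_drivers(res, cands, alpha=0.05)
        assert [r.gene for r in out.records] == ["C1"]

    def test_result_must_cover_candidates(self):
        from nicd.permutation import PermutationResult

        _, cands = self._setup()
        res = PermutationResult(genes=["C1"], x={"C1": 0}, p={"C1": 0.0},
                                q={"C1": 0.0}, iterations=10, seed=0, mode="gene")
        with pytest.raises(ValueError, match="cover"):
            significant_drivers(res, cands, alpha=0.05)
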