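"""Enrichment score, permutation null, FDR, candidates, overlap, ORA."""

import numpy as np
import pandas as pd
import pytest

from brainsig import enrich
from brainsig.enrich import (EnrichmentReport, candidate_ranking,
                             enrichment_score, leading_edge, ora,
                             overlap_analysis, permutation_null,
                             round_half_up_pct, score_gene_sets)

from conftest import make_ranked
from oracles import brute_force_es, brute_force_ks


class TestEnrichmentScore:
    def test_worked_five_gene_example(self):
        """Weights (5,4,3,2,1), set {rank1, rank4}: ES = 5/7 at rank 1."""
        ranked = make_ranked([0.5, 0.4, 0.3, 0.2, 0.1])
        prof = enrichment_score(ranked, {"g1", "g4"}, p=1.0)
        assert np.allclose(prof.running, [5 / 7, 5 / 7 - 1 / 3,
                                          5 / 7 - 2 / 3, 1 / 3, 0.0])
        assert prof.es == pytest.approx(5 / 7, abs=1e-12)
        assert prof.peak_rank == 1
        assert leading_edge(prof, ranked) == ["g1"]

    def test_set_at_top_is_maximally_enriched(self):
        ranked = make_ranked([0.5, 0.4, 0.3, 0.2, 0.1])
        prof = enrichment_score(ranked, {"g1", "g2"})
        assert prof.es == pytest.approx(1.0)
        assert leading_edge(prof, ranked) == ["g1", "g2"]

    def test_bottom_gene_is_maximally_depleted(self):
        ranked = make_ranked([0.5, 0.4, 0.3, 0.2, 0.1])
        prof = enrichment_score(ranked, {"g5"})
        assert prof.es == pytest.approx(-1.0)
        assert leading_edge(prof, ranked) == ["g5"]

    def test_negative_mirror_of_worked_example(self):
        """Reversed weights, set {rank2, rank5}: ES = -5/7, edge = {rank5}."""
        ranked = make_ranked([-0.1, -0.2, -0.3, -0.4, -0.5])
        prof = enrichment_score(ranked, {"g2", "g5"}, p=1.0)
        assert prof.es == pytest.approx(-5 / 7, abs=1e-12)
        assert leading_edge(prof, ranked) == ["g5"]

    def test_degenerate_weights_error(self):
        ranked = make_ranked([0.5, 0.0, 0.0, -0.1])
        with pytest.raises(ValueError, match="degenerate"):
            enrichment_score(ranked, {"g2", "g3"}, p=1.0)

    def test_empty_or_full_set_error(self):
        ranked = make_ranked([0.5, 0.4, 0.3])
        with pytest.raises(ValueError):
            enrichment_score(ranked, set())
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"g1", "g2", "g3"})

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            N = int(rng.integers(5, 51))
            scores = np.sort(rng.normal(0, 0.3, N))[::-1]
            k = int(rng.integers(1, N))
            hits = np.zeros(N, bool)
            hits[rng.choice(N, k, replace=False)] = True
            p = float(rng.choice([0.0, 0.5, 1.0, 2.0]))
            if np.abs(scores[hits]).sum() == 0:
                continue
            ranked = make_ranked(scores)
            prof = enrichment_score(ranked, set(np.array(ranked.genes)[hits]),
                                    p=p)
            es_o, run_o = brute_force_es(scores, hits, p)
            assert prof.es == pytest.approx(es_o, abs=1e-12)
            assert np.allclose(prof.running, run_o, atol=1e-12)
            # conservation and bounds
            assert abs(prof.running[-1]) < 1e-9
            assert abs(prof.es) <= 1.0 + 1e-12

    def test_p_zero_reduces_to_ks_statistic(self, rng):
        for _ in range(50):
            N = int(rng.integers(6, 40))
            scores = np.sort(rng.normal(0, 0.3, N))[::-1]
            k = int(rng.integers(1, N))
            hits = np.zeros(N, bool)
            hits[rng.choice(N, k, replace=False)] = True
            ranked = make_ranked(scores)
            prof = enrichment_score(ranked, set(np.array(ranked.genes)[hits]),
                                    p=0.0)
            ks = brute_force_ks(list(np.flatnonzero(hits) + 1),
                                list(np.flatnonzero(~hits) + 1))
            assert abs(prof.es) == pytest.approx(ks, abs=1e-12)

    def test_invariant_to_positive_weight_rescaling(self):
        ranked_a = make_ranked([0.5, 0.4, 0.3, 0.2, 0.1])
        ranked_b = make_ranked([5.0, 4.0, 3.0, 2.0, 1.0])
        for members in ({"g1", "g4"}, {"g2"}, {"g3", "g5"}):
            assert enrichment_score(ranked_a, members).es == pytest.approx(
                enrichment_score(ranked_b, members).es, abs=1e-12)


class TestPermutationNull:
    def test_same_seed_reproduces_the_sample(self, rng):
        ranked = make_ranked(np.sort(rng.normal(0, 0.3, 100))[::-1])
        a = permutation_null(ranked, 10, 200, np.random.default_rng(3))
        b = permutation_null(ranked, 10, 200, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_zero_permutations_is_an_error(self, rng):
        ranked = make_ranked(np.sort(rng.normal(size=50))[::-1])
        with pytest.raises(ValueError, match="n_perm"):
            permutation_null(ranked, 5, 0, rng)

    def test_set_size_must_be_below_universe(self, rng):
        ranked = make_ranked(np.sort(rng.normal(size=20))[::-1])
        with pytest.raises(ValueError, match="set_size"):
            permutation_null(ranked, 20, 10, rng)

    def test_fast_path_agrees_with_per_set_scoring(self, rng):
        """Monte-Carlo self-consistency: batched null ES equals the mean ES
        of independently drawn random sets scored one at a time."""
        scores = np.sort(rng.normal(0, 0.3, 150))[::-1]
        ranked = make_ranked(scores)
        k = 12
        nulls = permutation_null(ranked, k, 400, np.random.default_rng(5))
        singles = []
        r2 = np.random.default_rng(6)
        for _ in range(400):
            members = set(np.array(ranked.genes)[
                r2.choice(len(scores), k, replace=False)])
            singles.append(enrichment_score(ranked, members).es)
        singles = np.array(singles)
        se = np.sqrt(nulls.var() / len(nulls) + singles.var() / len(singles))
        assert abs(nulls.mean() - singles.mean()) <= 3 * se


class TestNormalizeAndFdr:
    def test_zero_es_gets_nes_zero_and_p_one(self):
        nes, p, floored = enrich._same_sign_stats(0.0, np.array([0.1, -0.1]),
                                                  100)
        assert nes == 0.0 and p == 1.0 and not floored

    def test_missing_same_sign_nulls_floors_p(self):
        nes, p, floored = enrich._same_sign_stats(0.5, np.array([-0.2, -0.3]),
                                                  100)
        assert floored and p == pytest.approx(1 / 101)

    def test_nes_is_es_over_same_signed_null_mean(self):
        nulls = np.array([0.2, 0.4, -0.5, -0.1])
        nes, _, _ = enrich._same_sign_stats(0.6, nulls, 100)
        assert nes == pytest.approx(0.6 / 0.3)
        nes, _, _ = enrich._same_sign_stats(-0.6, nulls, 100)
        assert nes == pytest.approx(-0.6 / 0.3)


class TestCandidateRanking:
    def _report(self, edges, qs=None):
        rows = []
        for i, edge in enumerate(edges):
            rows.append({"set_id": f"S{i}", "size": len(edge), "es": 0.5,
                         "nes": 1.5, "nominal_p": 0.001, "p_floored": False,
                         "peak_rank": 10, "members": list(edge),
                         "leading_edge": list(edge),
                         "fdr_q": 0.01 if qs is None else qs[i]})
        return EnrichmentReport(results=pd.DataFrame(rows))

    def test_membership_count_beats_mean_r_magnitude(self):
        """A gene in more leading edges ranks first despite a smaller |r|."""
        ranked = make_ranked([0.51, 0.26], genes=["strong_r", "frequent"])
        report = self._report([["frequent", "strong_r"], ["frequent",
                                                          "strong_r"],
                               ["frequent"]])
        cl = candidate_ranking(report, ranked, +1)
        assert list(cl["gene_id"]) == ["frequent", "strong_r"]
        assert list(cl["n_leading_edge_sets"]) == [3, 2]

    def test_count_tie_breaks_to_larger_r_magnitude(self):
        """At equal counts, mean_r -0.18 precedes -0.17."""
        ranked = make_ranked([-0.17, -0.18], genes=["weak", "extreme"])
        report = self._report([["weak", "extreme"], ["weak", "extreme"]])
        report.results["es"] = -0.5
        report.results["nes"] = -1.5
        cl = candidate_ranking(report, ranked, -1)
        assert list(cl["gene_id"]) == ["extreme", "weak"]

    def test_single_significant_set_yields_its_leading_edge(self):
        genes = [f"g{i}" for i in range(12)]
        ranked = make_ranked(np.linspace(0.6, 0.1, 12), genes=genes)
        report = self._report([genes])
        cl = candidate_ranking(report, ranked, +1)
        assert len(cl) == 10
        assert list(cl["gene_id"]) == genes[:10]   # ordered by |mean_r|

    def test_no_significant_sets_yields_no_list(self):
        ranked = make_ranked([0.5, 0.1])
        report = self._report([["g1"]], qs=[0.5])
        assert candidate_ranking(report, ranked, +1) is None

    def test_ranking_is_deterministic(self):
        ranked = make_ranked(np.linspace(0.5, -0.5, 20))
        report = self._report([list(ranked.genes[2:8]),
                               list(ranked.genes[4:12])])
        a = candidate_ranking(report, ranked, +1)
        b = candidate_ranking(report, ranked, +1)
        pd.testing.assert_frame_equal(a, b)


class TestOverlap:
    def test_printed_set_overlap_percentage(self):
        assert round_half_up_pct(3, 118) == 2.5

    def test_printed_gene_overlap_percentage(self):
        assert round_half_up_pct(135, 1397) == 9.7
        assert abs(round_half_up_pct(135, 1397) - 9.6) <= 0.1 + 1e-12

    def test_disjoint_and_identical_inputs(self):
        ov = overlap_analysis(["a"], ["b"], ["s1"], ["s2"])
        assert ov.shared_genes == [] and ov.gene_pct == 0.0
        ov = overlap_analysis(["a", "b"], ["a", "b"], ["s"], ["s"])
        assert len(ov.shared_genes) == 2 and ov.gene_pct == 100.0

    def test_counts_partition_the_union(self):
        ov = overlap_analysis(["a", "b", "c"], ["b", "c", "d"],
                              ["s1", "s2"], ["s2", "s3"])
        assert len(ov.shared_genes) + len(ov.genes_only_a) + \
            len(ov.genes_only_b) == 4
        assert len(ov.shared_sets) + len(ov.sets_only_a) + \
            len(ov.sets_only_b) == 3


class TestOra:
    def test_zero_overlap_gives_p_one(self):
        res = ora(["a"], {"S": ["b", "c"]}, ["a", "b", "c", "d"])
        assert res["p"].iloc[0] == 1.0

    def test_complete_overlap_exact_enumeration(self):
        """5-of-5 from a 20-gene universe: p = 1/C(20,5) = 1/15504."""
        universe = [f"g{i}" for i in range(20)]
        res = ora(universe[:5], {"S": universe[:5]}, universe)
        assert res["p"].iloc[0] == pytest.approx(1 / 15504, rel=1e-9)

    def test_p_decreases_with_overlap(self):
        universe = [f"g{i}" for i in range(40)]
        ps = []
        for k in range(1, 6):
            lst = universe[:5]
            members = universe[:k] + universe[20:20 + (5 - k)]
            ps.append(ora(lst, {"S": members}, universe)["p"].iloc[0])
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_list_outside_universe_is_an_error(self):
        with pytest.raises(ValueError, match="subset"):
            ora(["x"], {"S": ["a"]}, ["a", "b"])


class TestAgainstReferenceImplementation:
    def test_es_matches_gseapy_prerank(self, rng):
        gseapy = pytest.importorskip("gseapy")
        genes = [f"G{i:03d}" for i in range(300)]
        scores = np.sort(rng.normal(0, 0.3, 300))[::-1]
        ranked = make_ranked(scores, genes=genes)
        sets = {f"S{j}": list(rng.choice(genes, 25, replace=False))
                for j in range(5)}
        res = gseapy.prerank(rnk=pd.DataFrame({"gene": genes,
                                               "score": scores}),
                             gene_sets=sets, permutation_num=10,
                             min_size=5, max_size=100, seed=1, outdir=None,
                             weight=1.0, threads=1)
        for row in res.res2d.itertuples():
            mine = enrichment_score(ranked, sets[row.Term]).es
            assert mine == pytest.approx(float(row.ES), abs=1e-9)


def test_score_gene_sets_respects_size_bounds(rng):
    scores = np.sort(rng.normal(0, 0.3, 100))[::-1]
    ranked = make_ranked(scores)
    sets = {"tiny": list(ranked.genes[:3]), "ok": list(ranked.genes[:20])}
    report = score_gene_sets(ranked, sets, n_perm=100, seed=1,
                             size_bounds=(15, 500))
    assert list(report.results["set_id"]) == ["ok"]


def test_network_table_edges_use_jaccard(rng):
    scores = np.sort(rng.normal(0, 0.3, 60))[::-1]
    ranked = make_ranked(scores)
    genes = list(ranked.genes)
    sets = {"A": genes[:20], "B": genes[:18] + genes[30:32], "C": genes[40:58]}
    report = score_gene_sets(ranked, sets, n_perm=200, seed=2,
                             size_bounds=(5, 500), fdr_threshold=1.1)
    nodes, edges = enrich.network_table(report, jaccard_threshold=0.5)
    assert set(nodes["set_id"]) == {"A", "B", "C"}
    assert list(edges.itertuples(index=False))[0][:2] == ("A", "B")
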