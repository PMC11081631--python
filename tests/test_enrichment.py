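"""Preranked enrichment: GMT I/O, running-sum ES against a brute-force
oracle, permutation null calibration, BH adjustment, and intersections."""

import numpy as np
import pandas as pd
import pytest

from pigcorr.correlation import RankedGeneList
from pigcorr.enrichment import (
    GeneSet,
    GeneSetCollection,
    adjust_fdr,
    enrichment_score,
    intersect_lineages,
    partition_by_nes,
    permutation_null,
    read_gmt,
    run_gsea,
    write_gmt,
)


def make_ranking(stats, genes=None):
    stats = np.asarray(stats, dtype=float)
    genes = np.array(
        genes or [f"g{i}" for i in range(len(stats))], dtype=object
    )
    return RankedGeneList(genes=genes, stats=stats, r=stats.copy())


def brute_force_es(ranking, members, p=1.0):
    """Step-by-step running sum walked gene by gene (independent oracle)."""
    members = set(members)
    hits = [i for i, g in enumerate(ranking.genes) if g in members]
    total = sum(abs(ranking.stats[i]) ** p for i in hits)
    n, k = len(ranking), len(hits)
    value, best = 0.0, 0.0
    for i, g in enumerate(ranking.genes):
        if g in members:
            value += abs(ranking.stats[i]) ** p / total
        else:
            value -= 1.0 / (n - k)
        if abs(value) > abs(best) or (abs(value) == abs(best) and value > best):
            best = value
    return best


class TestGmtIO:
    def test_parse_line(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("SETA\tdesc\tg1\tg2\n")
        col = read_gmt(str(path))
        assert len(col) == 1
        assert col["SETA"].genes == ("g1", "g2")

    def test_roundtrip(self, tmp_path):
        col = GeneSetCollection()
        col.add(GeneSet("A", "first", ("g1", "g2", "g3")))
        col.add(GeneSet("B", "second", ("g9",)))
        path = str(tmp_path / "out.gmt")
        write_gmt(col, path)
        back = read_gmt(path)
        assert back.names() == ["A", "B"]
        assert all(back[n].genes == col[n].genes for n in col.names())

    def test_duplicate_members_deduplicated_with_warning(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("S\td\tg1\tg1\n")
        with pytest.warns(UserWarning, match="duplicate members"):
            col = read_gmt(str(path))
        assert col["S"].genes == ("g1",)

    def test_short_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("S\tdesc\n")
        with pytest.raises(ValueError, match=">=3"):
            read_gmt(str(path))

    def test_duplicate_set_name_rejected(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("S\td\tg1\tg2\nS\td\tg3\tg4\n")
        with pytest.raises(ValueError, match="duplicate gene-set name"):
            read_gmt(str(path))


class TestEnrichmentScore:
    def test_top_gene_reaches_one(self):
        rk = make_ranking([4, 3, 2, 1], list("abcd"))
        res = enrichment_score(rk, ["a"])
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == ["a"]

    def test_bottom_gene_reaches_minus_one(self):
        rk = make_ranking([4, 3, 2, 1], list("abcd"))
        res = enrichment_score(rk, ["d"])
        assert res.es == pytest.approx(-1.0)
        assert res.leading_edge == ["d"]

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(20, 200))
            stats = np.sort(rng.random(n))[::-1]
            rk = make_ranking(stats)
            k = int(rng.integers(1, max(2, n // 3)))
            members = list(rng.choice(rk.genes, size=k, replace=False))
            res = enrichment_score(rk, members)
            assert res.es == pytest.approx(brute_force_es(rk, members), abs=1e-12)

    def test_es_bounded(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            stats = np.sort(rng.random(60))[::-1]
            rk = make_ranking(stats)
            members = rng.choice(rk.genes, size=10, replace=False)
            assert -1.0 <= enrichment_score(rk, members).es <= 1.0

    def test_complement_mirrors_with_unweighted_statistic(self):
        """With p=0 (classic KS) the complement set's walk is the negation."""
        rng = np.random.default_rng(10)
        stats = np.sort(rng.random(40))[::-1]
        rk = make_ranking(stats)
        members = list(rng.choice(rk.genes, size=12, replace=False))
        complement = [g for g in rk.genes if g not in members]
        run_a = enrichment_score(rk, members, weight_exponent=0.0).running_sum
        run_b = enrichment_score(rk, complement, weight_exponent=0.0).running_sum
        np.testing.assert_allclose(run_a, -run_b, atol=1e-12)

    def test_empty_intersection_rejected(self):
        rk = make_ranking([3, 2, 1], list("abc"))
        with pytest.raises(ValueError, match="no members"):
            enrichment_score(rk, ["zzz"])

    def test_zero_weight_hits_rejected(self):
        rk = make_ranking([1.0, 0.5, 0.0, 0.0], list("abcd"))
        with pytest.raises(ValueError, match="zero total hit weight"):
            enrichment_score(rk, ["c", "d"])

    def test_leading_edge_is_subset_of_members(self):
        rng = np.random.default_rng(11)
        stats = np.sort(rng.random(80))[::-1]
        rk = make_ranking(stats)
        members = list(rng.choice(rk.genes, size=15, replace=False))
        res = enrichment_score(rk, members)
        assert set(res.leading_edge) <= set(members)


class TestPermutationNull:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        rk = make_ranking(np.sort(rng.random(100))[::-1])
        members = list(rk.genes[:10])
        a = permutation_null(rk, members, n_perm=200, seed=5)
        b = permutation_null(rk, members, n_perm=200, seed=5)
        assert a.pval == b.pval and a.nes == b.nes

    def test_min_permutations_enforced(self):
        rk = make_ranking([3, 2, 1], list("abc"))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_null(rk, ["a"], n_perm=10)

    def test_planted_top_loaded_set_is_significant(self):
        rng = np.random.default_rng(13)
        stats = np.sort(rng.random(2000))[::-1]
        rk = make_ranking(stats)
        members = list(rk.genes[:30])  # all in the top decile and beyond
        res = permutation_null(rk, members, n_perm=1000, seed=1)
        assert res.pval <= 0.01
        assert res.nes > 0

    def test_random_set_pvalues_approximately_uniform(self):
        """Exchangeability: a random set's p-value fraction below 0.1 stays
        inside the binomial band over 200 replicates."""
        rng = np.random.default_rng(14)
        stats = np.sort(rng.gamma(1.0, 0.1, size=400))[::-1]
        rk = make_ranking(stats)
        below = 0
        n_rep = 200
        for i in range(n_rep):
            members = list(rng.choice(rk.genes, size=20, replace=False))
            res = permutation_null(rk, members, n_perm=199, seed=1000 + i)
            below += res.pval < 0.1
        assert 0.05 <= below / n_rep <= 0.17


class TestAdjustFdr:
    def test_hand_worked_bh(self):
        np.testing.assert_allclose(
            adjust_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_pvalue_unchanged(self):
        assert adjust_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(15)
        p = rng.uniform(0.001, 1.0, size=50)
        assert (adjust_fdr(p) >= p - 1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.0, 0.5])


class TestPartitionAndIntersection:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["set_name", "nes", "padj"])

    def test_partition_by_nes(self):
        tab = self.frame(
            [("up", 2.1, 0.01), ("down", -1.8, 0.01), ("ns", 2.5, 0.2)]
        )
        pos, neg = partition_by_nes(tab)
        assert pos == ["up"] and neg == ["down"]

    def test_intersection_common_sets(self):
        summary = intersect_lineages(
            {
                "A": (["L", "C"], []),
                "B": (["L", "C", "X"], []),
                "C": (["L", "C"], []),
            }
        )
        assert summary.intersection_positive == ["C", "L"]
        assert summary.intersection_negative == []

    def test_empty_lineage_empties_intersection(self):
        summary = intersect_lineages({"A": (["L"], []), "B": ([], [])})
        assert summary.intersection_positive == []

    def test_adding_lineage_never_grows_intersection(self):
        base = {"A": (["x", "y", "z"], []), "B": (["x", "y"], [])}
        small = set(intersect_lineages(base).intersection_positive)
        base["C"] = (["y"], [])
        bigger = set(intersect_lineages(base).intersection_positive)
        assert bigger <= small

    def test_fewer_than_two_lineages_rejected(self):
        with pytest.raises(ValueError, match="two lineages"):
            intersect_lineages({"A": (["x"], [])})


class TestRunGsea:
    def make_inputs(self):
        rng = np.random.default_rng(16)
        stats = np.sort(rng.random(300))[::-1]
        rk = make_ranking(stats)
        col = GeneSetCollection()
        col.add(GeneSet("TOP", "planted", tuple(rk.genes[:20])))
        for i in range(5):
            members = tuple(rng.choice(rk.genes, size=25, replace=False))
            col.add(GeneSet(f"D{i}", "decoy", members))
        col.add(GeneSet("TINY", "below gate", tuple(rk.genes[:3])))
        return rk, col

    def test_size_gate_skips_with_warning(self):
        rk, col = self.make_inputs()
        with pytest.warns(UserWarning, match="TINY"):
            tab = run_gsea(rk, col, n_perm=100, seed=0)
        assert "TINY" not in set(tab["set_name"])
        assert len(tab) == 6

    def test_results_independent_of_collection_order(self):
        rk, col = self.make_inputs()
        reversed_col = GeneSetCollection()
        for name in reversed(col.names()):
            reversed_col.add(col[name])
        with pytest.warns(UserWarning):
            a = run_gsea(rk, col, n_perm=100, seed=0).set_index("set_name")
            b = run_gsea(rk, reversed_col, n_perm=100, seed=0).set_index("set_name")
        for name in a.index:
            assert a.loc[name, "pval"] == b.loc[name, "pval"]
            assert a.loc[name, "es"] == b.loc[name, "es"]

    def test_planted_set_leads_the_table(self):
        rk, col = self.make_inputs()
        with pytest.warns(UserWarning):
            tab = run_gsea(rk, col, n_perm=500, seed=0)
        best = tab.sort_values("pval").iloc[0]
        assert best["set_name"] == "TOP"
        assert best["nes"] > 0
        assert best["padj"] >= best["pval"]
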