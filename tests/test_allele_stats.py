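import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from poolfit.allele_stats import (
    AlleleFilter,
    ContingencyTable2xK,
    bh_fdr,
    build_gene_table,
    exact_test_2xk,
    gene_screen_results,
    go_enrichment,
    high_confidence_relationships,
    median_gene_phenotype,
    set_enrichment_2x2,
)
from poolfit.phenotype_core import ScreenPhenotypes
from tests.conftest import GA_BARCODES, make_annotation

# ---------------------------------------------------------------------------
# independent oracle: exact rational enumeration of the conditional null


def _compositions(j, remaining, caps):
    if j == len(caps) - 1:
        if remaining <= caps[j]:
            yield (remaining,)
        return
    for v in range(min(remaining, caps[j]) + 1):
        for rest in _compositions(j + 1, remaining - v, caps):
            yield (v,) + rest


def oracle_exact_p(gene_row, background_row):
    """Freeman-Halton p by full enumeration in exact rational arithmetic."""
    c = [int(g) + int(b) for g, b in zip(gene_row, background_row)]
    n = int(sum(gene_row))
    N = sum(c)
    denom = math.comb(N, n)

    def prob(x):
        num = 1
        for xi, ci in zip(x, c):
            num *= math.comb(ci, xi)
        return Fraction(num, denom)

    p_obs = prob(gene_row)
    return float(sum(p for x in _compositions(0, n, c) if (p := prob(x)) <= p_obs))


def random_table(rng, max_n=8, max_k=9, max_bg=30):
    k = int(rng.integers(2, max_k + 1))
    n = int(rng.integers(1, max_n + 1))
    gene = rng.multinomial(n, np.ones(k) / k)
    bg = rng.integers(0, max_bg + 1, size=k)
    return ContingencyTable2xK(gene, bg)


class TestExactTest2xk:
    def test_tea_tasting_2x2(self):
        p = exact_test_2xk(ContingencyTable2xK([3, 1], [1, 3]))
        assert p == pytest.approx(0.4857142857, abs=1e-9)

    def test_balanced_table_gives_p_one(self):
        assert exact_test_2xk(ContingencyTable2xK([1, 1], [9, 9])) == pytest.approx(1.0)

    def test_single_feasible_table_gives_p_one(self):
        # all mass in one bin for gene and background alike
        p = exact_test_2xk(ContingencyTable2xK([3, 0, 0], [10, 0, 0]))
        assert p == pytest.approx(1.0)

    def test_matches_rational_oracle_on_random_tables(self, rng):
        for _ in range(30):
            t = random_table(rng)
            assert exact_test_2xk(t) == pytest.approx(
                oracle_exact_p(t.gene_row, t.background_row), abs=1e-9
            )

    def test_2x2_matches_classical_fisher(self, rng):
        for _ in range(30):
            t = random_table(rng, max_k=2)
            expected = fisher_exact(np.vstack([t.gene_row, t.background_row]))[1]
            assert exact_test_2xk(t) == pytest.approx(expected, abs=1e-9)

    def test_monte_carlo_within_3se_of_enumeration(self, rng):
        n_mc = 20_000
        for _ in range(50):
            t = random_table(rng, max_n=10, max_k=9)
            p_exact = exact_test_2xk(t)
            p_mc, method, se = exact_test_2xk(
                t, mc_threshold=0, n_mc=n_mc, seed=rng, full=True
            )
            assert method == "monte_carlo"
            tol = 3 * math.sqrt(max(p_exact * (1 - p_exact), 1e-12) / n_mc) + 2 / n_mc
            assert abs(p_mc - p_exact) <= tol

    def test_invariant_under_joint_column_permutation(self, rng):
        for _ in range(10):
            t = random_table(rng)
            p0 = exact_test_2xk(t)
            perm = rng.permutation(len(t.gene_row))
            p1 = exact_test_2xk(ContingencyTable2xK(t.gene_row[perm], t.background_row[perm]))
            assert p1 == pytest.approx(p0, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            exact_test_2xk(ContingencyTable2xK([0, 0], [1, 1]))  # empty gene row
        with pytest.raises(ValueError):
            exact_test_2xk(ContingencyTable2xK([1], [1]))  # k < 2
        with pytest.raises(ValueError):
            ContingencyTable2xK([1, -1], [1, 1])


class TestBhFdr:
    def test_small_examples_match_stepup_formula(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_fdr([0.5]) == pytest.approx([0.5])
        assert bh_fdr([0.05, 1.0]) == pytest.approx([0.10, 1.0])

    def test_matches_direct_stepup_on_random_vectors(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 40))
            p = rng.uniform(1e-6, 1.0, size=m)
            order = np.argsort(p)
            q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q_sorted, 1.0)
            assert bh_fdr(p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [float("nan")]])
    def test_out_of_range_pvalues_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_fdr(bad)

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_adjusted_values_monotone_along_sorted_p(self, pvals):
        q = bh_fdr(pvals)
        order = np.argsort(pvals)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1.0).all() and (q >= np.asarray(pvals) / len(pvals) - 1e-12).all()


class TestBuildGeneTable:
    def test_bins_gene_and_background_rows(self, toy_screen):
        screen, anns = toy_screen
        t = build_gene_table("GA", screen, anns)
        assert list(t.gene_row) == [3, 0, 0, 0, 0, 0, 0, 0, 0]
        assert t.background_row.sum() == 65  # all passing alleles, self included
        assert list(t.background_row[:1]) == [3]

    def test_stated_phenotype_binning_example(self):
        screen = ScreenPhenotypes(
            "s", phi={"AAAA": 0.03, "CCCC": 0.05, "GGGG": 1.0},
            control_raw={"AAAA": 100, "CCCC": 100, "GGGG": 100},
        )
        anns = [make_annotation(b, "G1") for b in ("AAAA", "CCCC", "GGGG")]
        t = build_gene_table("G1", screen, anns, exclude_self=True)
        assert list(t.gene_row) == [2, 0, 0, 0, 1, 0, 0, 0, 0]

    def test_low_confidence_and_3utr_alleles_excluded(self, toy_screen):
        screen, anns = toy_screen
        anns = anns + [
            make_annotation("TTTTAAAA", "GA", "CDS", confidence=5),
            make_annotation("TTTTCCCC", "GA", "3UTR", confidence=1),
        ]
        screen.phi.update({"TTTTAAAA": 0.01, "TTTTCCCC": 0.01})
        screen.control_raw.update({"TTTTAAAA": 100, "TTTTCCCC": 100})
        t = build_gene_table("GA", screen, anns)
        assert t.gene_row.sum() == 3

    def test_low_control_reads_exclude_allele(self, toy_screen):
        screen, anns = toy_screen
        screen.control_raw[GA_BARCODES[2]] = 50  # floor is strict ">"
        t = build_gene_table("GA", screen, anns)
        assert t.gene_row.sum() == 2

    def test_gene_without_passing_alleles_skipped(self, toy_screen):
        screen, anns = toy_screen
        assert build_gene_table("NOPE", screen, anns) is None

    def test_exclude_self_subtracts_gene_row(self, toy_screen):
        screen, anns = toy_screen
        t_in = build_gene_table("GA", screen, anns)
        t_ex = build_gene_table("GA", screen, anns, exclude_self=True)
        assert (t_in.background_row - t_ex.background_row == t_in.gene_row).all()


class TestMedianGenePhenotype:
    @pytest.mark.parametrize(
        "phis,expected", [([0.1, 0.2, 0.9], 0.2), ([0.1, 0.3], 0.2), ([1.0], 1.0)]
    )
    def test_median(self, phis, expected):
        assert median_gene_phenotype(phis) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_gene_phenotype([])


class TestGeneScreenResults:
    def test_dropout_gene_attains_minimal_p_and_passes_fdr(self, toy_screen):
        screen, anns = toy_screen
        res = gene_screen_results([screen], anns)
        res = res.set_index("gene_id")
        assert res.loc["GA", "p"] == res["p"].min()
        assert res.loc["GA", "fdr"] < 0.3
        assert res.loc["GA", "median_phenotype"] == pytest.approx(0.03)

    def test_genes_with_two_or_fewer_alleles_get_no_fdr(self, toy_screen):
        screen, anns = toy_screen
        res = gene_screen_results([screen], anns).set_index("gene_id")
        assert math.isnan(res.loc["GB", "fdr"])
        assert not math.isnan(res.loc["GB", "p"])

    def test_high_confidence_selection(self, toy_screen):
        screen, anns = toy_screen
        res = gene_screen_results([screen], anns)
        hc = high_confidence_relationships(res, 0.3)
        assert list(hc["gene_id"]) == ["GA"]

    def test_per_screen_vs_global_fdr_scope(self, toy_screen):
        screen, anns = toy_screen
        import copy
        screen2 = copy.deepcopy(screen)
        screen2.screen_id = "S2"
        per = gene_screen_results([screen, screen2], anns, fdr_scope="per_screen")
        glo = gene_screen_results([screen, screen2], anns, fdr_scope="global")
        # global BH pools twice the tests, so adjusted values can only grow
        eligible = per["n_alleles"] > 2
        assert (glo.loc[eligible, "fdr"] >= per.loc[eligible, "fdr"] - 1e-12).all()


class TestSetEnrichment2x2:
    def test_closed_form_example(self):
        universe = set(range(20))
        hits = set(range(4))
        annotated = set(range(10))
        expected = math.comb(10, 4) / math.comb(20, 4)
        assert set_enrichment_2x2(hits, annotated, universe) == pytest.approx(expected)

    def test_zero_overlap_gives_p_one(self):
        assert set_enrichment_2x2({1}, {2}, {1, 2, 3}) == pytest.approx(1.0)

    def test_everything_overlapping_gives_p_one(self):
        u = {1, 2, 3}
        assert set_enrichment_2x2(u, u, u) == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            set_enrichment_2x2(set(), set(), set())


class TestGoEnrichment:
    def test_shared_mutant_counted_in_both_terms_and_twice_in_background(self):
        screen = ScreenPhenotypes(
            "s", phi={"AAAA": 1.0, "CCCC": 0.01},
            control_raw={"AAAA": 100, "CCCC": 100},
        )
        anns = [make_annotation("AAAA", "G1"), make_annotation("CCCC", "G2")]
        gene2go = {"G1": ["T1", "T2"], "G2": ["T1"]}
        res = go_enrichment([screen], anns, gene2go).set_index("go_term")
        assert res.loc["T1", "n_insertions"] == 2
        assert res.loc["T2", "n_insertions"] == 1
        # background pools term rows (G1's allele twice): bin0=1, bin4=2
        t2_row = [0, 0, 0, 0, 1, 0, 0, 0, 0]
        bg = [1, 0, 0, 0, 2, 0, 0, 0, 0]
        assert res.loc["T2", "p"] == pytest.approx(oracle_exact_p(t2_row, bg), abs=1e-9)

    def test_single_term_degenerate_p_one(self):
        screen = ScreenPhenotypes("s", phi={"AAAA": 0.01}, control_raw={"AAAA": 100})
        res = go_enrichment([screen], [make_annotation("AAAA", "G1")], {"G1": ["T1"]})
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_dropout_term_attains_minimal_p(self, toy_screen):
        screen, anns = toy_screen
        gene2go = {"GA": ["TDROP"], "GB": ["TNEUT"]}
        gene2go.update({f"G{i:03d}": ["TNEUT"] for i in range(60)})
        res = go_enrichment([screen], anns, gene2go).set_index("go_term")
        assert res.loc["TDROP", "p"] == res["p"].min()
        assert res.loc["TDROP", "fdr"] < 0.05
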