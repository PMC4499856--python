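"""Gene-level categories, Fisher/hypergeometric oracles, overlap, exclusion."""

import itertools

import numpy as np
import pytest

from isub import (
    GeneSet,
    PermutationConfig,
    build_gene_burden_table,
    compute_isub,
    differentially_hit_genes,
    exclude_gene_set_rerun,
    fisher_exact_one_sided,
    gene_category_counts,
    gene_count_difference_test,
    overlap_test,
    select_set_unique,
)
from isub.gene_burden import GeneDesign, exclude_gene_set, gene_count_statistic

from conftest import (
    make_cohort,
    oracle_fisher_greater,
    oracle_hypergeom_tail,
    oracle_set_unique,
    random_instance,
    scored_table,
)


def _one_gene_cohort(rows, dosage, phenotype):
    return make_cohort(dosage, phenotype), scored_table(rows)


class TestDoubleHit:
    def _rows(self, scores_flags):
        return [
            {"variant_id": f"v{j}", "gene": "G1",
             "functional_class": "nonsynonymous",
             "condel_score": s, "deleterious_flag": f}
            for j, (s, f) in enumerate(scores_flags)
        ]

    def test_deleterious_plus_benign_in_one_individual_counts(self):
        g, scored = _one_gene_cohort(
            self._rows([(0.9, True), (0.2, False)]),
            [[1, 1], [0, 0]], ["case", "control"],
        )
        counts = gene_category_counts(g, scored).set_index(["category", "side"])
        assert counts.loc[("double_hit", "case"), "n_genes"] == 1

    def test_two_benign_variants_do_not_count(self):
        g, scored = _one_gene_cohort(
            self._rows([(0.2, False), (0.3, False)]),
            [[1, 1], [0, 0]], ["case", "control"],
        )
        counts = gene_category_counts(g, scored).set_index(["category", "side"])
        assert counts.loc[("double_hit", "case"), "n_genes"] == 0

    def test_two_deleterious_in_different_genes_do_not_count(self):
        rows = self._rows([(0.9, True), (0.8, True)])
        rows[1]["gene"] = "G2"
        g, scored = _one_gene_cohort(rows, [[1, 1], [0, 0]],
                                     ["case", "control"])
        counts = gene_category_counts(g, scored).set_index(["category", "side"])
        assert counts.loc[("double_hit", "case"), "n_genes"] == 0

    def test_two_deleterious_spread_over_two_individuals_do_not_count(self):
        g, scored = _one_gene_cohort(
            self._rows([(0.9, True), (0.8, True)]),
            [[1, 0], [0, 1], [0, 0]], ["case", "case", "control"],
        )
        counts = gene_category_counts(g, scored).set_index(["category", "side"])
        assert counts.loc[("double_hit", "case"), "n_genes"] == 0


class TestGeneCounts:
    def test_categories_match_partition_derived_sets(self, enriched_cohort):
        g, scored, _ = enriched_cohort
        part = select_set_unique(g, scored)
        counts = gene_category_counts(g, scored).set_index(["category", "side"])
        sv = scored.drop_duplicates("variant_id").set_index("variant_id")
        for side in ("case", "control"):
            del_genes = {
                sv.at[v, "gene"]
                for v in part.categories[side]["DEL"]
                if isinstance(sv.at[v, "gene"], str)
            }
            assert counts.loc[("deleterious", side), "n_genes"] == len(del_genes)

    def test_statistic_sign_flips_under_label_swap(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            g, scored = random_instance(rng, n_samples=8, n_variants=15)
            stat = gene_count_statistic(g, scored, "deleterious")
            is_case = g.is_case
            assert stat(is_case) == -stat(~is_case)

    def test_exhaustive_difference_test_matches_enumeration_oracle(self):
        g = make_cohort(
            [[1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, 0]],
            ["case", "case", "control", "control"],
        )
        scored = scored_table(
            [{"variant_id": f"v{j}", "gene": gene,
              "functional_class": "nonsynonymous",
              "condel_score": 0.9, "deleterious_flag": True}
             for j, gene in enumerate(["G1", "G2", "G1"])]
        )
        cfg = PermutationConfig(B=1, exhaustive=True)
        res = gene_count_difference_test(g, scored, "deleterious", cfg)

        sv = scored.set_index("variant_id")

        def oracle(is_case):
            cu, ku = oracle_set_unique(g, scored, is_case)
            del_case = {sv.at[v, "gene"] for v in cu}
            del_ctrl = {sv.at[v, "gene"] for v in ku}
            return len(del_case) - len(del_ctrl)

        obs = oracle(g.is_case)
        draws = []
        for case_idx in itertools.combinations(range(4), 2):
            lab = np.zeros(4, dtype=bool)
            lab[list(case_idx)] = True
            draws.append(oracle(lab))
        assert res.p_empirical == pytest.approx(
            sum(d >= obs for d in draws) / len(draws)
        )


class TestFisher:
    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(31)
        for _ in range(400):
            a, b, c, d = rng.integers(0, 25, size=4)
            assert fisher_exact_one_sided(a, b, c, d) == pytest.approx(
                oracle_fisher_greater(a, b, c, d), rel=1e-9
            )

    def test_case_enrichment_example(self):
        p = fisher_exact_one_sided(3, 0, 999, 931)
        assert p == pytest.approx(oracle_fisher_greater(3, 0, 999, 931))
        assert p < 0.15

    def test_equal_proportions_not_significant(self):
        assert fisher_exact_one_sided(10, 10, 90, 90) >= 0.5

    def test_empty_carrier_rows_give_one(self):
        assert fisher_exact_one_sided(0, 0, 50, 40) == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            fisher_exact_one_sided(-1, 0, 1, 1)


class TestDifferentiallyHit:
    def _table(self, row_defs, n_cases=10, n_controls=10):
        """row_defs: list of (gene, case_carriers, control_carriers)."""
        import pandas as pd

        rows = []
        for gene, a, b in row_defs:
            rows.append(
                {
                    "gene": gene,
                    "case_n_del_variants": a, "case_n_carriers_del": a,
                    "control_n_del_variants": b, "control_n_carriers_del": b,
                    "fisher_p_case": fisher_exact_one_sided(
                        a, b, n_cases - a, n_controls - b),
                    "fisher_p_control": fisher_exact_one_sided(
                        b, a, n_controls - b, n_cases - a),
                }
            )
        df = pd.DataFrame(rows)
        df.attrs["n_cases"] = n_cases
        df.attrs["n_controls"] = n_controls
        return df

    def test_one_or_two_carriers_vs_zero_go_to_secondary(self):
        table = self._table([("G1", 2, 0), ("G2", 1, 0)])
        hits = differentially_hit_genes(table, "case")
        assert hits.primary == frozenset()
        assert hits.secondary == {"G1", "G2"}

    def test_no_increase_excluded(self):
        table = self._table([("G1", 5, 5)])
        hits = differentially_hit_genes(table, "case")
        assert hits.primary == frozenset()

    def test_three_vs_zero_included_iff_fisher_below_half(self):
        table = self._table([("G1", 3, 0)])
        expected_p = oracle_fisher_greater(3, 0, 7, 10)
        hits = differentially_hit_genes(table, "case")
        assert ("G1" in hits.primary) == (expected_p < 0.5)

    def test_sides_are_disjoint(self, enriched_cohort):
        g, scored, _ = enriched_cohort
        table = build_gene_burden_table(g, scored)
        case_hits = differentially_hit_genes(table, "case").primary
        control_hits = differentially_hit_genes(table, "control").primary
        assert not (case_hits & control_hits)
        assert case_hits  # the enriched generator produces some


class TestOverlap:
    def test_disjoint_lists_give_p_one(self):
        uni = GeneSet("U", frozenset(f"g{i}" for i in range(20)))
        a = GeneSet("A", frozenset(["g1", "g2"]))
        b = GeneSet("B", frozenset(["g3", "g4"]))
        res = overlap_test(a, b, uni)
        assert res.overlap == 0
        assert res.p_hypergeometric == 1.0

    def test_matches_enumeration_oracle(self):
        uni = GeneSet("U", frozenset(f"g{i}" for i in range(100)))
        a = GeneSet("A", frozenset(f"g{i}" for i in range(10)))
        b = GeneSet("B", frozenset(f"g{i}" for i in range(5, 25)))
        res = overlap_test(a, b, uni)
        assert res.overlap == 5
        assert res.p_hypergeometric == pytest.approx(
            oracle_hypergeom_tail(5, 100, 20, 10), rel=1e-9
        )

    def test_full_containment_gives_minimal_tail(self):
        uni = GeneSet("U", frozenset(f"g{i}" for i in range(30)))
        a = GeneSet("A", frozenset(["g0", "g1", "g2"]))
        b = GeneSet("B", frozenset(f"g{i}" for i in range(10)))
        res = overlap_test(a, b, uni)
        assert res.p_hypergeometric == pytest.approx(
            oracle_hypergeom_tail(3, 30, 10, 3), rel=1e-9
        )

    def test_member_outside_universe_rejected(self):
        uni = GeneSet("U", frozenset(["g1"]))
        a = GeneSet("A", frozenset(["g1", "alien"]))
        with pytest.raises(ValueError, match="alien"):
            overlap_test(a, a, uni)


class TestExclusion:
    def test_no_exclusion_reproduces_baseline(self, null_cohort):
        g, scored, _ = null_cohort
        cfg = PermutationConfig(B=50, seed=77)
        base = exclude_gene_set_rerun(g, scored, None, cfg)
        again = exclude_gene_set_rerun(g, scored, None, cfg)
        assert base.p_empirical == again.p_empirical
        np.testing.assert_array_equal(base.null_draws, again.null_draws)

    def test_excluding_all_case_unique_genes_zeroes_case_scores(self,
                                                                null_cohort):
        g, scored, _ = null_cohort
        part = select_set_unique(g, scored)
        sv = scored.drop_duplicates("variant_id").set_index("variant_id")
        genes = {
            sv.at[v, "gene"] for v in part.case_unique
            if isinstance(sv.at[v, "gene"], str)
        }
        filtered = exclude_gene_set(scored, GeneSet("excl", frozenset(genes)))
        prof = compute_isub(g, filtered, "NS")
        assert (prof.loc[prof.phenotype == "case", "isub"] == 0).all()

    def test_signal_confined_to_excluded_genes_disappears(self):
        rng = np.random.default_rng(56)
        # enrich cases only within genes G0/G1 by direct construction
        n_case, n_ctrl, m = 60, 60, 300
        dosage = (rng.random((120, m)) < 0.01).astype(np.int8)
        hot = slice(0, 60)  # first 60 variants, all in the hot gene
        dosage[:n_case, hot] |= (rng.random((n_case, 60)) < 0.06).astype(np.int8)
        rows = [
            {"variant_id": f"v{j}",
             "gene": "HOT1" if j < 60 else f"G{j % 40}",
             "functional_class": "nonsynonymous",
             "condel_score": 0.9, "deleterious_flag": True}
            for j in range(m)
        ]
        g = make_cohort(dosage, ["case"] * n_case + ["control"] * n_ctrl)
        scored = scored_table(rows)
        cfg = PermutationConfig(B=200, seed=4)
        from isub import isub_statistic, permute_pvalue

        with_hot = permute_pvalue(g.phenotype,
                                  isub_statistic(g, scored, "DEL"), cfg)
        filtered = exclude_gene_set(scored, GeneSet("x", frozenset(["HOT1"])))
        without = permute_pvalue(g.phenotype,
                                 isub_statistic(g, filtered, "DEL"), cfg)
        assert with_hot.p_empirical < 0.05
        assert without.p_empirical > 0.05

    def test_excluding_everything_rejected(self, null_cohort):
        g, scored, _ = null_cohort
        all_genes = GeneSet("all",
                            frozenset(scored["gene"].dropna().unique()))
        with pytest.raises(ValueError, match="every in-scope"):
            exclude_gene_set(scored, all_genes)


class TestMonotonicity:
    def test_gene_counts_monotone_under_variant_removal(self, enriched_cohort):
        g, scored, _ = enriched_cohort
        before = gene_category_counts(g, scored).set_index(
            ["category", "side"])["n_genes"]
        some_genes = frozenset(list(scored["gene"].dropna().unique())[:50])
        filtered = exclude_gene_set(scored, GeneSet("some", some_genes))
        after = gene_category_counts(g, filtered).set_index(
            ["category", "side"])["n_genes"]
        assert (after <= before).all()
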