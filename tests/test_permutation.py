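"""Permutation machinery: statistics, exact enumeration, minP, calibration."""

import itertools

import numpy as np
import pytest
from scipy import stats

from isub import (
    PermutationConfig,
    SyntheticConfig,
    apply_condel_augmentation,
    generate_cohort,
    isub_statistic,
    minp_adjust,
    permute_family,
    permute_pvalue,
    wilcoxon_statistic,
)
from isub._design import CohortDesign
from isub.permutation import ranksum

from conftest import make_cohort, oracle_isub, oracle_ranksum, scored_table


class TestWilcoxon:
    def test_hand_enumerated_ranksum(self):
        assert wilcoxon_statistic([3, 4], [1, 2]) == 7.0

    def test_all_equal_gives_tie_value(self):
        n_case, n = 3, 8
        assert wilcoxon_statistic([5] * n_case, [5] * (n - n_case)) == pytest.approx(
            n_case * (n + 1) / 2
        )

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            x = rng.integers(0, 6, size=rng.integers(1, 12)).astype(float)
            y = rng.integers(0, 6, size=rng.integers(1, 12)).astype(float)
            assert wilcoxon_statistic(x, y) == pytest.approx(oracle_ranksum(x, y))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_statistic([], [1.0])


class TestPermutePvalue:
    def test_observed_above_all_null_gives_floor(self):
        # strongly separated data: the observed labelling maximises the
        # rank-sum, so every sampled draw is below it
        values = np.array([10.0, 11, 12, 13, 14, 0, 1, 2, 3, 4])
        labels = np.array(["case"] * 5 + ["control"] * 5, dtype=object)

        def stat(is_case):
            return ranksum(values, is_case)

        B = 400
        res = permute_pvalue(labels, stat, PermutationConfig(B=B, seed=1))
        # only a redraw of the identity labelling (prob 1/252) can tie
        assert res.p_empirical <= (1 + 8) / (B + 1)
        assert res.p_empirical >= 1 / (B + 1)

    def test_exhaustive_matches_full_pipeline_enumeration_oracle(self):
        # 2 cases vs 2 controls: all C(4,2)=6 labellings enumerated, with the
        # set-unique sets and burden scores re-derived per labelling by an
        # independent loop oracle
        g = make_cohort(
            [[1, 0, 0], [1, 1, 0], [0, 0, 1], [0, 0, 0]],
            ["case", "case", "control", "control"],
        )
        scored = scored_table(
            [{"variant_id": f"v{j}", "functional_class": "nonsynonymous",
              "condel_score": s, "deleterious_flag": s > 0.5}
             for j, s in enumerate([0.9, 0.6, 0.8])]
        )
        cfg = PermutationConfig(B=1, exhaustive=True)
        res = permute_pvalue(g.phenotype, isub_statistic(g, scored, "DEL"), cfg)

        def oracle_stat(is_case):
            scores, _ = oracle_isub(g, scored, is_case, "DEL")
            return oracle_ranksum(scores[is_case], scores[~is_case])

        obs = oracle_stat(g.is_case)
        draws = []
        for case_idx in itertools.combinations(range(4), 2):
            lab = np.zeros(4, dtype=bool)
            lab[list(case_idx)] = True
            draws.append(oracle_stat(lab))
        expected_p = sum(d >= obs for d in draws) / len(draws)
        assert res.p_empirical == pytest.approx(expected_p)
        assert res.n_permutations == 6

    def test_reproducible_given_seed(self, null_cohort):
        g, scored, _ = null_cohort
        cfg = PermutationConfig(B=50, seed=99)
        r1 = permute_pvalue(g.phenotype, isub_statistic(g, scored, "DEL"), cfg)
        r2 = permute_pvalue(g.phenotype, isub_statistic(g, scored, "DEL"), cfg)
        assert r1.p_empirical == r2.p_empirical
        np.testing.assert_array_equal(r1.null_draws, r2.null_draws)

    def test_seed_required_and_b_positive(self):
        with pytest.raises(ValueError, match="seed"):
            PermutationConfig(B=10)
        with pytest.raises(ValueError, match="B"):
            PermutationConfig(B=0, seed=1)

    def test_stratified_permutation_preserves_within_stratum_counts(self):
        labels = np.array(["case"] * 4 + ["control"] * 4, dtype=object)
        strata = np.array(["a", "a", "b", "b"] * 2, dtype=object)
        seen = []

        def stat(is_case):
            seen.append(is_case.copy())
            return 0.0

        permute_pvalue(labels, stat, PermutationConfig(B=30, seed=2),
                       strata=strata)
        observed_is_case = labels == "case"
        for lab in seen[1:]:  # first call is the observed labelling
            for s in ("a", "b"):
                m = strata == s
                assert lab[m].sum() == observed_is_case[m].sum()


class TestMinP:
    @staticmethod
    def _family_from_vectors(vectors, B=2000, seed=5):
        data = np.column_stack(vectors)
        labels = np.array(
            ["case"] * (len(data) // 2)
            + ["control"] * (len(data) - len(data) // 2),
            dtype=object,
        )

        def stat(is_case):
            return np.array([ranksum(data[:, t], is_case)
                             for t in range(data.shape[1])])

        names = [f"t{t}" for t in range(data.shape[1])]
        return permute_family(labels, stat, names,
                              PermutationConfig(B=B, seed=seed))

    def test_single_test_family_adjusted_equals_raw(self):
        rng = np.random.default_rng(8)
        res = minp_adjust(self._family_from_vectors([rng.normal(size=20)]))
        assert res[0].p_minp_adjusted == pytest.approx(res[0].p_empirical)

    def test_adjusted_at_least_raw_and_at_most_one(self):
        rng = np.random.default_rng(9)
        fam = self._family_from_vectors(
            [rng.normal(size=24) for _ in range(3)], B=400
        )
        for r in minp_adjust(fam):
            assert r.p_empirical <= r.p_minp_adjusted <= 1.0

    def test_two_independent_nulls_match_sidak_limit(self):
        rng = np.random.default_rng(10)
        fam = self._family_from_vectors(
            [rng.normal(size=40), rng.normal(size=40)], B=4000
        )
        for r in minp_adjust(fam):
            expected = 1 - (1 - r.p_empirical) ** 2
            assert r.p_minp_adjusted == pytest.approx(expected, abs=0.05)

    def test_p_equal_one_stays_one(self):
        values = np.array([0.0, 1.0, 10.0, 11.0])  # cases far below controls
        labels = np.array(["case", "case", "control", "control"], dtype=object)

        def stat(is_case):
            return np.array([ranksum(values, is_case)])

        fam = permute_family(labels, stat, ["low"],
                             PermutationConfig(B=200, seed=3))
        assert minp_adjust(fam)[0].p_minp_adjusted == 1.0

    def test_mismatched_streams_rejected(self):
        rng = np.random.default_rng(12)
        a = self._family_from_vectors([rng.normal(size=20)], seed=1)
        b = self._family_from_vectors([rng.normal(size=20)], seed=2)
        with pytest.raises(ValueError, match="stream"):
            minp_adjust([a[0], b[0]])


class TestFrozenPartitionRegression:
    def test_freezing_the_observed_partition_breaks_calibration(self):
        """A null-generator p-value distribution must be uniform when the
        set-unique sets are re-derived per permuted labelling; an
        implementation that freezes the observed partition and permutes
        only the frozen per-individual scores is detectably miscalibrated
        (group sizes unequal, so frozen scores are not exchangeable)."""
        correct_ps, frozen_ps = [], []
        for r in range(50):
            cfg = SyntheticConfig(n_cases=100, n_controls=300,
                                  n_variants=2000, seed=5000 + r)
            g, ann, _ = generate_cohort(cfg)
            scored = apply_condel_augmentation(ann)
            pc = PermutationConfig(B=100, seed=5000 + r)

            correct_ps.append(
                permute_pvalue(g.phenotype, isub_statistic(g, scored, "DEL"),
                               pc).p_empirical
            )

            frozen_scores, _ = CohortDesign(g, scored).isub_scores(
                g.is_case, "DEL"
            )
            frozen_ps.append(
                permute_pvalue(
                    g.phenotype,
                    lambda lab, v=frozen_scores: ranksum(v, lab),
                    pc,
                ).p_empirical
            )
        assert stats.kstest(correct_ps, "uniform").pvalue > 0.01
        assert stats.kstest(frozen_ps, "uniform").pvalue < 1e-6
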