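"""Cohort statistics: summaries, Friedman, Spearman, external exchange, cardiologists."""

import numpy as np
import pytest
from scipy import stats as sps

from teamnets import (
    Cohort,
    Condition,
    NetworkMetrics,
    cardiologist_summary,
    condition_summary,
    external_exchange_table,
    friedman_test,
    spearman_correlation,
)
from teamnets.roster import Member, OccupationalGroup, PracticeRoster, Role
from teamnets.stats import summary_table

from oracles import friedman_oracle, spearman_oracle


def nm(pid, density=1.0, n_edges=0, centralization=0.0, reciprocity=1.0, condition=Condition.DM):
    return NetworkMetrics(
        practice_id=pid,
        condition=condition,
        n_nodes=4,
        n_edges=n_edges,
        density=density,
        centralization=centralization,
        reciprocity=reciprocity,
    )


class TestConditionSummary:
    def test_mean_and_median_of_densities(self):
        ms = [nm("A", 1.0), nm("B", 1.0), nm("C", 0.4)]
        s = condition_summary(ms, Condition.DM)
        assert s.metrics["density"].mean == pytest.approx(0.8)
        assert s.metrics["density"].median == pytest.approx(1.0)

    def test_total_connections_sums_edges(self):
        ms = [nm(f"P{i}", n_edges=e) for i, e in enumerate([9, 8, 8] + [8] * 22)]
        s = condition_summary(ms, Condition.DM)
        assert s.n_networks == 25
        assert s.total_connections == 201

    def test_single_network_has_missing_sd(self):
        s = condition_summary([nm("A", 0.5)], Condition.DM)
        assert s.metrics["density"].sd is None

    def test_undefined_reciprocity_skipped_with_effective_n(self):
        ms = [nm("A", reciprocity=1.0), nm("B", reciprocity=None), nm("C", reciprocity=0.5)]
        s = condition_summary(ms, Condition.DM)
        assert s.metrics["reciprocity"].n == 2
        assert s.metrics["reciprocity"].mean == pytest.approx(0.75)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            condition_summary([], Condition.CHF)

    def test_summary_table_has_row_per_metric(self):
        ms = [nm("A", 0.5, n_edges=3), nm("B", 0.7, n_edges=4)]
        table = summary_table([condition_summary(ms, Condition.DM)])
        assert set(table["metric"]) == {"reciprocity", "n_edges", "density", "centralization"}


class TestFriedman:
    def test_perfectly_ordered_three_by_three(self):
        values = [[3, 2, 1], [30, 20, 10], [0.9, 0.5, 0.1]]
        res = friedman_test(values)
        assert res.statistic == pytest.approx(6.0)
        assert res.df == 2
        assert res.n_blocks == 3
        assert not res.tie_corrected

    def test_identical_rows_give_zero_statistic_p_one(self):
        res = friedman_test([[1.0, 1.0, 1.0]] * 5)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(99)
        x = rng.standard_normal((12, 3))
        res = friedman_test(x)
        stat, p = sps.friedmanchisquare(x[:, 0], x[:, 1], x[:, 2])
        assert res.statistic == pytest.approx(stat, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            x = rng.integers(0, 3, size=(10, 3)).astype(float)  # heavy ties
            if np.all([len(np.unique(r)) == 1 for r in x]):
                continue
            res = friedman_test(x)
            assert res.statistic == pytest.approx(friedman_oracle(x), abs=1e-9)
            assert res.tie_corrected

    def test_half_swapped_rows_match_oracle(self):
        rng = np.random.default_rng(17)
        base = np.sort(rng.standard_normal((8, 3)), axis=1)
        x = base.copy()
        x[::2, [0, 1]] = x[::2, [1, 0]]  # swap two conditions in half the rows
        assert friedman_test(x).statistic == pytest.approx(friedman_oracle(x), abs=1e-9)

    def test_invariant_under_row_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.random((15, 3))
        assert friedman_test(x).statistic == pytest.approx(
            friedman_test(np.exp(3 * x)).statistic, abs=1e-9
        )

    def test_rows_with_missing_values_dropped_with_warning(self):
        x = np.array([[1.0, 2.0, 3.0], [np.nan, 1.0, 2.0], [2.0, 3.0, 1.0]])
        with pytest.warns(UserWarning, match="dropping 1"):
            res = friedman_test(x)
        assert res.n_blocks == 2

    def test_fewer_than_two_complete_rows_is_an_error(self):
        with pytest.raises(ValueError):
            friedman_test([[1.0, 2.0, 3.0]])

    def test_null_rejection_rate_near_alpha(self):
        # exchangeable rows: rejection at alpha=0.05 should be close to nominal
        rng = np.random.default_rng(12345)
        rejections = 0
        n_reps = 2000
        for _ in range(n_reps):
            x = rng.standard_normal((25, 3))
            if friedman_test(x).p_value <= 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_reps <= 0.07


class TestSpearman:
    def test_perfect_monotone_relations(self):
        x = [0.1, 0.4, 0.2, 0.9, 0.7]
        assert spearman_correlation(x, x)[0] == pytest.approx(1.0)
        assert spearman_correlation(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_matches_rank_oracle_on_random_pairs(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            x = rng.random(10)
            y = rng.integers(0, 4, 10).astype(float)  # ties in y
            rho, _ = spearman_correlation(x, y)
            assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])


def external_cohort(n_respondents, n_marking, n_nonrespondents=0):
    """One big practice; first ``n_marking`` respondents mark pharmacists for DM."""
    members = []
    for i in range(n_respondents):
        groups = {Condition.DM: {OccupationalGroup.PHARMACISTS}} if i < n_marking else {}
        members.append(
            Member(
                member_id=f"M{i}",
                role=Role.PRACTICE_ASSISTANT,
                responded=True,
                external_groups=groups,
            )
        )
    members += [
        Member(member_id=f"N{i}", role=Role.PRACTICE_ASSISTANT, responded=False)
        for i in range(n_nonrespondents)
    ]
    return Cohort(practices=[PracticeRoster(practice_id="P", members=members)])


class TestExternalExchange:
    def test_about_half_marking_pharmacists(self):
        table = external_exchange_table(external_cohort(153, 77))
        row = table[
            (table.group == "pharmacists")
            & (table.condition == "DM")
            & (table.stratum == "overall")
        ].iloc[0]
        assert (row["n"], row["denominator"], row["pct"]) == (77, 153, 50.3)

    def test_unmarked_group_reported_as_zero(self):
        table = external_exchange_table(external_cohort(10, 5))
        row = table[
            (table.group == "occupational_health_physicians") & (table.stratum == "overall")
        ].iloc[0]
        assert (row["n"], row["pct"]) == (0, 0.0)

    def test_nonrespondents_excluded_from_denominator(self):
        table = external_exchange_table(external_cohort(10, 5, n_nonrespondents=4))
        assert (table[table.stratum == "overall"]["denominator"] == 10).all()

    def test_counts_never_exceed_stratum_size(self):
        from teamnets import GeneratorConfig, generate_cohort

        table = external_exchange_table(generate_cohort(GeneratorConfig(n_practices=10, seed=4)))
        assert (table["n"] <= table["denominator"]).all()


def cardio_cohort(counts_by_practice, roles=None):
    practices = []
    for pi, counts in enumerate(counts_by_practice):
        members = []
        for mi, count in enumerate(counts):
            role = (roles or {}).get((pi, mi), Role.PRACTICE_ASSISTANT)
            members.append(
                Member(
                    member_id=f"M{mi}",
                    role=role,
                    responded=True,
                    cardiologists_monthly={Condition.CHD: count},
                )
            )
        practices.append(PracticeRoster(practice_id=f"P{pi}", members=members))
    return Cohort(practices=practices)


class TestCardiologists:
    def test_practice_mean_of_member_counts(self):
        s = cardiologist_summary(cardio_cohort([[4, 2, 2]]), Condition.CHD)
        assert s.practice_mean == pytest.approx(2.67, abs=0.005)

    def test_role_stratified_means(self):
        cohort = cardio_cohort([[5, 4, 2], [3, 2, 1]], roles={(0, 0): Role.PHYSICIAN, (1, 0): Role.PHYSICIAN})
        s = cardiologist_summary(cohort, Condition.CHD)
        assert s.by_role["physician"].mean == pytest.approx(4.0)
        assert s.by_role["non_physician"].mean == pytest.approx(2.25)

    def test_all_missing_practice_excluded(self):
        s = cardiologist_summary(cardio_cohort([[3, 3], [None, None]]), Condition.CHD)
        assert s.n_practices == 1
        assert s.practice_mean == pytest.approx(3.0)

    def test_no_data_is_an_error(self):
        with pytest.raises(ValueError, match="no cardiologist counts"):
            cardiologist_summary(cardio_cohort([[None, None]]), Condition.CHD)

    def test_dm_not_a_cardiologist_condition(self):
        with pytest.raises(ValueError):
            cardiologist_summary(cardio_cohort([[1]]), Condition.DM)
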