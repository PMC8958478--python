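"""Roster data model, validation, I/O round-trips and the characteristics summary."""

import json

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from teamnets import (
    Cohort,
    CohortValidationError,
    Condition,
    GeneratorConfig,
    Member,
    PracticeRoster,
    generate_cohort,
    read_cohort,
    summarize_practice_characteristics,
    write_cohort,
)
from teamnets.roster import format_characteristics

from conftest import make_member, make_practice


def _one_practice_json(tmp_path, members):
    data = {
        "provenance": "test",
        "practices": [{"practice_id": "P1", "members": members}],
    }
    path = tmp_path / "cohort.json"
    path.write_text(json.dumps(data))
    return path


def _member_record(mid, dm=()):
    return {
        "member_id": mid,
        "role": "practice_assistant",
        "responded": True,
        "nominations": {"DM": list(dm), "CHD": [], "CHF": []},
    }


class TestValidation:
    def test_reads_triangle_with_six_dm_ties(self, tmp_path):
        path = _one_practice_json(
            tmp_path,
            [
                _member_record("A", dm=["B", "C"]),
                _member_record("B", dm=["A", "C"]),
                _member_record("C", dm=["A", "B"]),
            ],
        )
        cohort = read_cohort(path)
        assert cohort.n_practices == 1
        ties = sum(len(m.nominations[Condition.DM]) for m in cohort.practices[0].members)
        assert ties == 6

    def test_rejects_self_tie(self, tmp_path):
        path = _one_practice_json(
            tmp_path, [_member_record("PA2", dm=["PA2"]), _member_record("B")]
        )
        with pytest.raises(CohortValidationError, match="self-tie"):
            read_cohort(path)

    def test_rejects_dangling_nomination(self, tmp_path):
        path = _one_practice_json(
            tmp_path, [_member_record("A", dm=["P9"]), _member_record("B")]
        )
        with pytest.raises(CohortValidationError, match="dangling"):
            read_cohort(path)

    def test_rejects_unknown_role_and_group(self):
        with pytest.raises(ValueError):
            Member(member_id="A", role="nurse", responded=True)
        with pytest.raises(ValueError):
            Member(
                member_id="A",
                role="physician",
                responded=True,
                external_groups={Condition.DM: {"astrologists"}},
            )

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate member_id"):
            PracticeRoster(
                practice_id="P", members=[make_member("A"), make_member("A")]
            )
        with pytest.raises(ValueError, match="duplicate practice_id"):
            Cohort(practices=[make_practice("P", 3), make_practice("P", 3)])

    def test_nonrespondent_must_carry_no_data(self):
        with pytest.raises(ValueError, match="non-respondent"):
            make_member("A", responded=False, dm={"B"})
        with pytest.raises(ValueError, match="non-respondent"):
            Member(
                member_id="A",
                role="physician",
                responded=False,
                cardiologists_monthly={Condition.CHD: 3},
            )

    def test_malformed_json_is_a_parse_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(CohortValidationError, match="malformed"):
            read_cohort(path)


class TestRoundTrip:
    @settings(max_examples=15, deadline=None, suppress_health_check=[HealthCheck.too_slow])
    @given(seed=st.integers(0, 10_000), fmt=st.sampled_from(["json", "csv"]))
    def test_read_write_identity_on_generated_cohorts(self, tmp_path_factory, seed, fmt):
        cohort = generate_cohort(GeneratorConfig(n_practices=3, seed=seed))
        tmp = tmp_path_factory.mktemp("rt")
        target = tmp / ("c.json" if fmt == "json" else "c_csv")
        write_cohort(cohort, target, format=fmt)
        assert read_cohort(target, format=fmt) == cohort

    def test_nonrespondent_flags_survive_round_trip(self, tmp_path):
        cohort = Cohort(
            practices=[make_practice("P1", 4, n_nonrespondents=1, complete=True)],
            provenance="with non-respondent",
        )
        for fmt, target in [("json", tmp_path / "c.json"), ("csv", tmp_path / "csv")]:
            write_cohort(cohort, target, format=fmt)
            back = read_cohort(target, format=fmt)
            assert back == cohort
            assert [m.responded for m in back.practices[0].members] == [False, True, True, True]

    def test_metadata_and_extras_round_trip(self, tmp_path):
        member = Member(
            member_id="A",
            role="physician",
            responded=True,
            nominations={Condition.DM: {"B"}},
            external_groups={Condition.CHD: {"pharmacists", "internists"}},
            cardiologists_monthly={Condition.CHD: 4, Condition.CHF: None},
        )
        cohort = Cohort(
            practices=[
                PracticeRoster(
                    practice_id="P1",
                    members=[member, make_member("B")],
                    practice_type="single_handed",
                    cases_band="500-1000",
                    documentation="both",
                    case_manager=True,
                    meetings_per_quarter=2,
                ),
                make_practice("P2", 3),  # all metadata missing
            ],
            provenance="metadata fixture",
        )
        for fmt, target in [("json", tmp_path / "c.json"), ("csv", tmp_path / "csv")]:
            write_cohort(cohort, target, format=fmt)
            assert read_cohort(target, format=fmt) == cohort

    def test_write_to_unwritable_path_raises(self, tmp_path):
        cohort = Cohort(practices=[make_practice("P1", 3)])
        with pytest.raises(OSError):
            write_cohort(cohort, tmp_path / "no" / "such" / "dir" / "c.json", format="json")


class TestCharacteristicsSummary:
    def test_mean_and_range_of_practice_size(self):
        cohort = Cohort(practices=[make_practice("A", 3), make_practice("B", 7)])
        s = summarize_practice_characteristics(cohort)
        row = s["size"].loc["health_workers"]
        assert row["mean"] == 5.0
        assert (row["min"], row["max"]) == (3, 7)

    def test_single_handed_share_eighty_percent(self):
        practices = [
            make_practice(f"P{i}", 3, practice_type="single_handed") for i in range(32)
        ] + [make_practice(f"G{i}", 3, practice_type="group") for i in range(8)]
        s = summarize_practice_characteristics(Cohort(practices=practices))
        cat = s["categorical"]
        row = cat[(cat.variable == "practice_type") & (cat.level == "single_handed")].iloc[0]
        assert row["n"] == 32
        assert row["pct"] == 80.0

    def test_missing_metadata_excluded_from_denominator(self):
        practices = [
            make_practice("A", 3, cases_band="<500"),
            make_practice("B", 3),  # missing cases_band
        ]
        s = summarize_practice_characteristics(Cohort(practices=practices))
        cat = s["categorical"]
        sub = cat[cat.variable == "cases_band"]
        assert (sub["denominator"] == 1).all()
        assert sub["pct"].sum() == pytest.approx(100.0)

    def test_percentages_sum_to_hundred_per_item(self):
        cohort = generate_cohort(GeneratorConfig(n_practices=30, seed=11))
        s = summarize_practice_characteristics(cohort)
        cat = s["categorical"]
        for variable, sub in cat.groupby("variable"):
            if sub["denominator"].iloc[0] > 0:
                assert sub["pct"].sum() == pytest.approx(100.0, abs=0.3), variable

    def test_formatter_mentions_response_rate(self):
        cohort = Cohort(practices=[make_practice("A", 4, n_nonrespondents=1)])
        text = format_characteristics(summarize_practice_characteristics(cohort))
        assert "75.0%" in text
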