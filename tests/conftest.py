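"""Shared fixtures: hand-built practices and programmatic fixture cohorts."""

from __future__ import annotations

import pytest

from teamnets import (
    CONDITIONS,
    Cohort,
    Condition,
    Member,
    PracticeRoster,
    Role,
)


def make_member(
    member_id: str,
    role: Role = Role.PRACTICE_ASSISTANT,
    responded: bool = True,
    dm: set[str] | None = None,
    chd: set[str] | None = None,
    chf: set[str] | None = None,
    **kwargs,
) -> Member:
    return Member(
        member_id=member_id,
        role=role,
        responded=responded,
        nominations={
            Condition.DM: dm or set(),
            Condition.CHD: chd or set(),
            Condition.CHF: chf or set(),
        },
        **kwargs,
    )


def make_practice(
    practice_id: str,
    n_members: int,
    n_nonrespondents: int = 0,
    complete: bool = False,
    n_physicians: int = 1,
    **metadata,
) -> PracticeRoster:
    """A practice of generic members; ``complete=True`` makes every respondent
    nominate every colleague for every condition."""
    ids = [f"M{i + 1}" for i in range(n_members)]
    members = []
    for i, mid in enumerate(ids):
        responded = i >= n_nonrespondents
        noms = {c: set() for c in CONDITIONS}
        if responded and complete:
            noms = {c: set(ids) - {mid} for c in CONDITIONS}
        members.append(
            Member(
                member_id=mid,
                role=Role.PHYSICIAN if i < n_physicians else Role.PRACTICE_ASSISTANT,
                responded=responded,
                nominations=noms,
            )
        )
    return PracticeRoster(practice_id=practice_id, members=members, **metadata)


@pytest.fixture
def triangle_practice() -> PracticeRoster:
    """Three respondents, each nominating both others for every condition."""
    return make_practice("T1", 3, complete=True)


@pytest.fixture
def filter_fixture_cohort() -> Cohort:
    """40 practices: 6 with fewer than 3 members, 9 (disjoint) with 2+
    non-respondents, 25 eligible — mirroring the study's exclusion counts."""
    practices = [make_practice(f"SMALL{i}", 2) for i in range(6)]
    practices += [make_practice(f"MISS{i}", 5, n_nonrespondents=2) for i in range(9)]
    practices += [
        make_practice(f"OK{i}", 3 + i % 5, n_nonrespondents=i % 2, complete=True)
        for i in range(25)
    ]
    return Cohort(practices=practices, provenance="fixture: study exclusion counts")
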