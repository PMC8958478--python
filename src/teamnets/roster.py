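"""Cohort data model and roster-questionnaire I/O.

The unit of observation is a primary-care practice whose members (physicians
and practice assistants) filled in a sociometric roster questionnaire: each
respondent marks, separately for type 2 diabetes (DM), coronary heart disease
(CHD) and chronic heart failure (CHF), the colleagues with whom they exchange
patient information at least once a week, the occupational groups outside the
practice they exchange with, and the number of cardiologists contacted
monthly. Practice-level metadata (practice type, case load, documentation
mode, case management, team meetings) comes from a separate practice
questionnaire.

Two on-disk formats are supported and round-trip exactly:

* a canonical JSON document (practices -> members -> nominations), and
* a CSV pair: ``members.csv`` (one row per member, with practice metadata
  repeated) plus ``nominations.csv`` (practice_id, source_id, target_id,
  condition).
"""

from __future__ import annotations

import csv
import json
import math
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "Condition",
    "CONDITIONS",
    "Role",
    "OccupationalGroup",
    "PracticeType",
    "CasesBand",
    "Documentation",
    "Member",
    "PracticeRoster",
    "Cohort",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "summarize_practice_characteristics",
    "format_characteristics",
]


class CohortValidationError(ValueError):
    """Raised when roster data violates the cohort schema or its invariants."""


class Condition(str, Enum):
    """Chronic condition for which information exchange was surveyed."""

    DM = "DM"
    CHD = "CHD"
    CHF = "CHF"


#: Fixed tabulation order: DM, then CHD, then CHF.
CONDITIONS: tuple[Condition, ...] = (Condition.DM, Condition.CHD, Condition.CHF)

#: Conditions for which monthly cardiologist contact counts were collected.
CARDIOLOGIST_CONDITIONS: tuple[Condition, ...] = (Condition.CHD, Condition.CHF)


class Role(str, Enum):
    PHYSICIAN = "physician"
    PRACTICE_ASSISTANT = "practice_assistant"


class OccupationalGroup(str, Enum):
    """Closed vocabulary of occupational groups outside the practice."""

    PHARMACISTS = "pharmacists"
    NUTRITIONISTS = "nutritionists"
    PHYSIOTHERAPISTS = "physiotherapists"
    NURSING_HOME_NURSES = "nursing_home_nurses"
    AMBULATORY_NURSING_SERVICE_NURSES = "ambulatory_nursing_service_nurses"
    REHABILITATION_EXERCISE_CLASSES = "rehabilitation_exercise_classes"
    CARDIOLOGY_EXERCISE_CLASSES = "cardiology_exercise_classes"
    REHABILITATION_CENTRES = "rehabilitation_centres"
    EXTERNAL_PHYSICIAN_ASSISTANTS = "external_physician_assistants"
    PSYCHOLOGISTS = "psychologists"
    RESPIRATORY_PHYSICIANS = "respiratory_physicians"
    INTERNISTS = "internists"
    OCCUPATIONAL_HEALTH_PHYSICIANS = "occupational_health_physicians"


class PracticeType(str, Enum):
    SINGLE_HANDED = "single_handed"
    GROUP = "group"
    SHARED = "shared"
    AMBULATORY_HEALTH_CARE_CENTRE = "ambulatory_health_care_centre"


class CasesBand(str, Enum):
    LT_500 = "<500"
    B500_1000 = "500-1000"
    B1001_1500 = "1001-1500"
    GT_1500 = ">1500"


class Documentation(str, Enum):
    DIGITAL = "digital"
    PAPER = "paper"
    BOTH = "both"


class Member(BaseModel):
    """One practice member and their questionnaire answers.

    A non-respondent carries no outgoing information: nomination sets and
    external-group sets must be empty and cardiologist counts missing.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=False)

    member_id: str = Field(min_length=1)
    role: Role
    responded: bool
    nominations: dict[Condition, set[str]] = Field(default_factory=dict)
    external_groups: dict[Condition, set[OccupationalGroup]] = Field(default_factory=dict)
    cardiologists_monthly: dict[Condition, Optional[int]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_member(self) -> "Member":
        for c in CONDITIONS:
            self.nominations.setdefault(c, set())
            self.external_groups.setdefault(c, set())
        for c, targets in self.nominations.items():
            if self.member_id in targets:
                raise ValueError(
                    f"self-tie: member {self.member_id!r} nominates itself for {c.value}"
                )
        for c in self.cardiologists_monthly:
            if c not in CARDIOLOGIST_CONDITIONS:
                raise ValueError(
                    f"cardiologist counts are collected for CHD and CHF only, got {c.value}"
                )
        for c in CARDIOLOGIST_CONDITIONS:
            self.cardiologists_monthly.setdefault(c, None)
        for c, v in self.cardiologists_monthly.items():
            if v is not None and v < 0:
                raise ValueError(f"negative cardiologist count for {c.value}")
        if not self.responded:
            if any(self.nominations.values()) or any(self.external_groups.values()):
                raise ValueError(
                    f"non-respondent {self.member_id!r} must have empty nominations "
                    "and external groups"
                )
            if any(v is not None for v in self.cardiologists_monthly.values()):
                raise ValueError(
                    f"non-respondent {self.member_id!r} must have missing cardiologist counts"
                )
        return self


class PracticeRoster(BaseModel):
    """One practice: its members plus practice-questionnaire metadata.

    Metadata fields are optional because the practice questionnaire has
    item-level non-response; summaries exclude missing items from their
    denominators.
    """

    model_config = ConfigDict(extra="forbid")

    practice_id: str = Field(min_length=1)
    members: list[Member] = Field(min_length=1)
    practice_type: Optional[PracticeType] = None
    cases_band: Optional[CasesBand] = None
    documentation: Optional[Documentation] = None
    case_manager: Optional[bool] = None
    meetings_per_quarter: Optional[int] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _check_roster(self) -> "PracticeRoster":
        ids = [m.member_id for m in self.members]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(
                f"duplicate member_id in practice {self.practice_id!r}: {dupes}"
            )
        known = set(ids)
        for m in self.members:
            for c, targets in m.nominations.items():
                unknown = targets - known
                if unknown:
                    raise ValueError(
                        f"dangling nomination in practice {self.practice_id!r}: "
                        f"member {m.member_id!r} nominates unknown {sorted(unknown)} "
                        f"for {c.value}"
                    )
        return self

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_respondents(self) -> int:
        return sum(m.responded for m in self.members)

    @property
    def n_nonrespondents(self) -> int:
        return self.n_members - self.n_respondents

    @property
    def n_physicians(self) -> int:
        return sum(m.role is Role.PHYSICIAN for m in self.members)

    @property
    def n_assistants(self) -> int:
        return sum(m.role is Role.PRACTICE_ASSISTANT for m in self.members)


class Cohort(BaseModel):
    """A collection of practices analysed together."""

    model_config = ConfigDict(extra="forbid")

    practices: list[PracticeRoster]
    provenance: str = ""

    @model_validator(mode="after")
    def _check_cohort(self) -> "Cohort":
        ids = [p.practice_id for p in self.practices]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate practice_id in cohort: {dupes}")
        return self

    @property
    def n_practices(self) -> int:
        return len(self.practices)

    @property
    def n_members(self) -> int:
        return sum(p.n_members for p in self.practices)

    @property
    def n_respondents(self) -> int:
        return sum(p.n_respondents for p in self.practices)

    def practice(self, practice_id: str) -> PracticeRoster:
        for p in self.practices:
            if p.practice_id == practice_id:
                return p
        raise KeyError(practice_id)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _member_to_dict(m: Member) -> dict:
    return {
        "member_id": m.member_id,
        "role": m.role.value,
        "responded": m.responded,
        "nominations": {c.value: sorted(m.nominations[c]) for c in CONDITIONS},
        "external_groups": {
            c.value: sorted(g.value for g in m.external_groups[c]) for c in CONDITIONS
        },
        "cardiologists_monthly": {
            c.value: m.cardiologists_monthly[c] for c in CARDIOLOGIST_CONDITIONS
        },
    }


def _practice_to_dict(p: PracticeRoster) -> dict:
    return {
        "practice_id": p.practice_id,
        "practice_type": None if p.practice_type is None else p.practice_type.value,
        "cases_band": None if p.cases_band is None else p.cases_band.value,
        "documentation": None if p.documentation is None else p.documentation.value,
        "case_manager": p.case_manager,
        "meetings_per_quarter": p.meetings_per_quarter,
        "members": [_member_to_dict(m) for m in p.members],
    }


def cohort_to_dict(cohort: Cohort) -> dict:
    """Canonical (sorted, JSON-ready) dictionary form of a cohort."""
    return {
        "provenance": cohort.provenance,
        "practices": [_practice_to_dict(p) for p in cohort.practices],
    }


def cohort_from_dict(data: dict) -> Cohort:
    try:
        return Cohort.model_validate(data)
    except ValidationError as exc:
        raise CohortValidationError(str(exc)) from exc


_MEMBER_COLUMNS = [
    "practice_id",
    "member_id",
    "role",
    "responded",
    "practice_type",
    "cases_band",
    "documentation",
    "case_manager",
    "meetings_per_quarter",
    "ext_DM",
    "ext_CHD",
    "ext_CHF",
    "cardiologists_CHD",
    "cardiologists_CHF",
]
_NOMINATION_COLUMNS = ["practice_id", "source_id", "target_id", "condition"]


def _opt(value) -> str:
    return "" if value is None else str(value)


def write_cohort(cohort: Cohort, path: str | Path, format: str = "json") -> None:
    """Write a cohort to ``path``.

    ``format="json"`` writes one canonical JSON file. ``format="csv"`` treats
    ``path`` as a directory and writes ``members.csv`` and ``nominations.csv``
    into it; the cohort provenance goes into a leading ``#`` comment line of
    ``members.csv``.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(cohort_to_dict(cohort), indent=1), encoding="utf-8")
    elif format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "members.csv", "w", newline="", encoding="utf-8") as fh:
            fh.write(f"# provenance: {cohort.provenance}\n")
            writer = csv.writer(fh)
            writer.writerow(_MEMBER_COLUMNS)
            for p in cohort.practices:
                for m in p.members:
                    writer.writerow(
                        [
                            p.practice_id,
                            m.member_id,
                            m.role.value,
                            str(m.responded).lower(),
                            _opt(None if p.practice_type is None else p.practice_type.value),
                            _opt(None if p.cases_band is None else p.cases_band.value),
                            _opt(None if p.documentation is None else p.documentation.value),
                            _opt(None if p.case_manager is None else str(p.case_manager).lower()),
                            _opt(p.meetings_per_quarter),
                            ";".join(sorted(g.value for g in m.external_groups[Condition.DM])),
                            ";".join(sorted(g.value for g in m.external_groups[Condition.CHD])),
                            ";".join(sorted(g.value for g in m.external_groups[Condition.CHF])),
                            _opt(m.cardiologists_monthly[Condition.CHD]),
                            _opt(m.cardiologists_monthly[Condition.CHF]),
                        ]
                    )
        with open(path / "nominations.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(_NOMINATION_COLUMNS)
            for p in cohort.practices:
                for m in p.members:
                    for c in CONDITIONS:
                        for target in sorted(m.nominations[c]):
                            writer.writerow([p.practice_id, m.member_id, target, c.value])
    else:
        raise ValueError(f"unknown format {format!r}; expected 'json' or 'csv'")


def _parse_bool(text: str, context: str) -> bool:
    if text == "true":
        return True
    if text == "false":
        return False
    raise CohortValidationError(f"cannot parse boolean {text!r} in {context}")


def read_cohort(path: str | Path, format: str | None = None) -> Cohort:
    """Read and validate a cohort from JSON or a CSV directory.

    ``format`` is inferred from the path when omitted (directory -> csv,
    otherwise json). Validation failures raise :class:`CohortValidationError`
    naming the offending practice and member.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.is_dir() else "json"
    if format == "json":
        try:
            data = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise CohortValidationError(f"malformed JSON in {path}: {exc}") from exc
        return cohort_from_dict(data)
    if format != "csv":
        raise ValueError(f"unknown format {format!r}; expected 'json' or 'csv'")

    members_path = path / "members.csv"
    nominations_path = path / "nominations.csv"
    for p in (members_path, nominations_path):
        if not p.exists():
            raise CohortValidationError(f"missing input file: {p}")

    provenance = ""
    with open(members_path, newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# provenance:"):
            provenance = first[len("# provenance:") :].strip()
        else:
            fh.seek(0)
        rows = list(csv.DictReader(fh))

    with open(nominations_path, newline="", encoding="utf-8") as fh:
        nom_rows = list(csv.DictReader(fh))

    practices: dict[str, dict] = {}
    members: dict[tuple[str, str], dict] = {}
    order: list[str] = []
    for row in rows:
        missing = [c for c in _MEMBER_COLUMNS if c not in row or row[c] is None]
        if missing:
            raise CohortValidationError(f"members.csv row missing columns {missing}")
        pid = row["practice_id"]
        if pid not in practices:
            order.append(pid)
            practices[pid] = {
                "practice_id": pid,
                "practice_type": row["practice_type"] or None,
                "cases_band": row["cases_band"] or None,
                "documentation": row["documentation"] or None,
                "case_manager": (
                    None
                    if row["case_manager"] == ""
                    else _parse_bool(row["case_manager"], f"practice {pid!r}")
                ),
                "meetings_per_quarter": (
                    None if row["meetings_per_quarter"] == "" else int(row["meetings_per_quarter"])
                ),
                "members": [],
            }
        mid = row["member_id"]
        member = {
            "member_id": mid,
            "role": row["role"],
            "responded": _parse_bool(row["responded"], f"member {mid!r} of practice {pid!r}"),
            "nominations": {c.value: [] for c in CONDITIONS},
            "external_groups": {
                c.value: [g for g in row[f"ext_{c.value}"].split(";") if g] for c in CONDITIONS
            },
            "cardiologists_monthly": {
                "CHD": None if row["cardiologists_CHD"] == "" else int(row["cardiologists_CHD"]),
                "CHF": None if row["cardiologists_CHF"] == "" else int(row["cardiologists_CHF"]),
            },
        }
        practices[pid]["members"].append(member)
        members[(pid, mid)] = member

    for row in nom_rows:
        missing = [c for c in _NOMINATION_COLUMNS if c not in row or row[c] is None]
        if missing:
            raise CohortValidationError(f"nominations.csv row missing columns {missing}")
        key = (row["practice_id"], row["source_id"])
        if key not in members:
            raise CohortValidationError(
                f"nominations.csv names unknown source {row['source_id']!r} "
                f"in practice {row['practice_id']!r}"
            )
        if row["condition"] not in {c.value for c in CONDITIONS}:
            raise CohortValidationError(
                f"nominations.csv has unknown condition {row['condition']!r}"
            )
        members[key]["nominations"][row["condition"]].append(row["target_id"])

    return cohort_from_dict(
        {"provenance": provenance, "practices": [practices[pid] for pid in order]}
    )


# ---------------------------------------------------------------------------
# descriptive summary (practice characteristics table)
# ---------------------------------------------------------------------------

_MEETING_BANDS = ["0", "1", "2", "3", "4", ">4"]


def _meetings_band(n: int) -> str:
    return str(n) if n <= 4 else ">4"


def _size_row(values: Iterable[int]) -> dict:
    arr = np.asarray(list(values), dtype=float)
    return {
        "mean": round(float(arr.mean()), 2),
        "sd": round(float(arr.std(ddof=1)), 2) if arr.size > 1 else math.nan,
        "min": int(arr.min()),
        "max": int(arr.max()),
    }


def summarize_practice_characteristics(cohort: Cohort) -> dict:
    """Descriptive characteristics of a cohort, matching the study's table style.

    Returns a dict with scalar counts (``n_practices``, ``n_members``,
    ``n_respondents``, ``response_rate_pct``), a ``size`` DataFrame
    (mean/SD/range of health workers, physicians and assistants per practice)
    and a ``categorical`` DataFrame of per-item frequencies. Missing metadata
    is excluded item-wise from the denominators; percentages are reported to
    one decimal.
    """
    if not cohort.practices:
        raise ValueError("cohort is empty")

    size = pd.DataFrame(
        {
            "health_workers": _size_row(p.n_members for p in cohort.practices),
            "physicians": _size_row(p.n_physicians for p in cohort.practices),
            "assistants": _size_row(p.n_assistants for p in cohort.practices),
        }
    ).T

    def frequencies(variable: str, levels: list[str], observed: list[str | None]) -> list[dict]:
        present = [v for v in observed if v is not None]
        denom = len(present)
        rows = []
        for level in levels:
            n = present.count(level)
            pct = round(100.0 * n / denom, 1) if denom else math.nan
            rows.append(
                {"variable": variable, "level": level, "n": n, "pct": pct, "denominator": denom}
            )
        return rows

    cat_rows: list[dict] = []
    cat_rows += frequencies(
        "practice_type",
        [t.value for t in PracticeType],
        [None if p.practice_type is None else p.practice_type.value for p in cohort.practices],
    )
    cat_rows += frequencies(
        "cases_band",
        [b.value for b in CasesBand],
        [None if p.cases_band is None else p.cases_band.value for p in cohort.practices],
    )
    cat_rows += frequencies(
        "documentation",
        [d.value for d in Documentation],
        [None if p.documentation is None else p.documentation.value for p in cohort.practices],
    )
    cat_rows += frequencies(
        "case_manager",
        ["no", "yes"],
        [
            None if p.case_manager is None else ("yes" if p.case_manager else "no")
            for p in cohort.practices
        ],
    )
    cat_rows += frequencies(
        "meetings_per_quarter",
        _MEETING_BANDS,
        [
            None if p.meetings_per_quarter is None else _meetings_band(p.meetings_per_quarter)
            for p in cohort.practices
        ],
    )

    n_members = cohort.n_members
    n_respondents = cohort.n_respondents
    return {
        "n_practices": cohort.n_practices,
        "n_members": n_members,
        "n_respondents": n_respondents,
        "response_rate_pct": round(100.0 * n_respondents / n_members, 1),
        "size": size,
        "categorical": pd.DataFrame(cat_rows),
    }


def format_characteristics(summary: dict) -> str:
    """Pretty-print a characteristics summary as text."""
    lines = [
        f"Practices: {summary['n_practices']}",
        f"Health workers: {summary['n_members']} "
        f"({summary['n_respondents']} responded, {summary['response_rate_pct']}%)",
        "",
        "Per-practice counts (mean, SD, range):",
    ]
    for name, row in summary["size"].iterrows():
        sd = "-" if math.isnan(row["sd"]) else f"{row['sd']:.2f}"
        lines.append(
            f"  {name}: {row['mean']:.2f} ({sd}), range {int(row['min'])}-{int(row['max'])}"
        )
    lines.append("")
    current = None
    for _, row in summary["categorical"].iterrows():
        if row["variable"] != current:
            current = row["variable"]
            lines.append(f"{current} (n = {row['denominator']}):")
        lines.append(f"  {row['level']}: {row['n']} ({row['pct']})")
    return "\n".join(lines)
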