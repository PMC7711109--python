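"""Dual self-identified / standardized demographics reporting.

Participants describe each identity axis in their own words first; a
standardized category from a fixed vocabulary is recorded alongside for
scientific reporting. Summaries report counts and one-decimal percentages
of the full sample per axis, plus the derived composites used to
characterize sample diversity: the share of racial minorities (any
standardized race other than White alone), multi-racial participants,
sexual minorities (Lesbian/Gay/Homosexual, Bisexual/Pansexual, or
Asexual), and participants holding a Bachelor's degree or higher.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

NO_RESPONSE = "No response"

GENDER_CATEGORIES = (
    "Female",
    "Male",
    "Another identity such as transgender, intersex, and/or non-binary genders",
    NO_RESPONSE,
)
RACE_CATEGORIES = (
    "Black or African American",
    "American Indian or Alaska Native",
    "Asian",
    "Native Hawaiian or Other Pacific Islander",
    "White",
    "Multi-racial",
    NO_RESPONSE,
)
ETHNICITY_CATEGORIES = ("Hispanic or Latino", "Not Hispanic or Latino", NO_RESPONSE)
SEXUAL_ORIENTATION_CATEGORIES = (
    "Lesbian/Gay/Homosexual",
    "Bisexual/Pansexual",
    "Straight/Heterosexual",
    "Asexual",
    "Do Not Wish to Specify",
    NO_RESPONSE,
)
EDUCATION_CATEGORIES = (
    "Less than Bachelor's degree",
    "Bachelor's degree",
    "Some graduate work",
    "Master's degree",
    "Doctoral degree",
    NO_RESPONSE,
)
EMPLOYMENT_CATEGORIES = (
    "Working for pay",
    "Unemployed and looking for work",
    "Student",
    NO_RESPONSE,
)
INCOME_CATEGORIES = (
    "$0-$19,999",
    "$20,000-$49,999",
    "$50,000-$99,999",
    "Over $100,000",
    NO_RESPONSE,
)
LANGUAGE_CATEGORIES = ("English only", "English and other language(s)", NO_RESPONSE)

SEXUAL_MINORITY_CATEGORIES = frozenset(
    {"Lesbian/Gay/Homosexual", "Bisexual/Pansexual", "Asexual"}
)
BACHELORS_OR_HIGHER = frozenset(
    {"Bachelor's degree", "Some graduate work", "Master's degree", "Doctoral degree"}
)

_VOCABULARIES = {
    "gender": GENDER_CATEGORIES,
    "race": RACE_CATEGORIES,
    "ethnicity": ETHNICITY_CATEGORIES,
    "sexual_orientation": SEXUAL_ORIENTATION_CATEGORIES,
    "education": EDUCATION_CATEGORIES,
    "employment": EMPLOYMENT_CATEGORIES,
    "income": INCOME_CATEGORIES,
    "languages": LANGUAGE_CATEGORIES,
}


@dataclass
class ParticipantRecord:
    """One participant's demographics, self-identified + standardized."""

    gender: str
    race: str
    ethnicity: str
    sexual_orientation: str
    education: str
    employment: str
    income: str
    languages: str
    has_insurance: bool = True
    self_identified: dict[str, str] = field(default_factory=dict)
    pronouns: str = NO_RESPONSE

    def __post_init__(self) -> None:
        for axis, vocab in _VOCABULARIES.items():
            value = getattr(self, axis)
            if value not in vocab:
                raise ValueError(
                    f"{axis}={value!r} is not in the standardized vocabulary "
                    f"{vocab}"
                )


def study_cohort() -> list[ParticipantRecord]:
    """The 15-participant cohort reconstructed from its published marginals.

    Synthetic reconstruction: per-axis standardized counts match the
    published demographics tables exactly, but the pairing of categories
    across axes within a record is arbitrary (only marginal counts were
    published). Axis-level summaries and the derived composites are
    therefore exact; cross-axis summaries are not meaningful.
    """

    def expand(pairs: Sequence[tuple[str, int]]) -> list[str]:
        out: list[str] = []
        for cat, n in pairs:
            out.extend([cat] * n)
        return out

    gender = expand(
        [
            ("Female", 5),
            ("Male", 9),
            (
                "Another identity such as transgender, intersex, and/or non-binary genders",
                1,
            ),
        ]
    )
    race = expand(
        [
            ("Black or African American", 1),
            ("American Indian or Alaska Native", 1),
            ("Asian", 4),
            ("White", 3),
            ("Multi-racial", 6),
        ]
    )
    ethnicity = expand([("Hispanic or Latino", 4), ("Not Hispanic or Latino", 11)])
    orientation = expand(
        [
            ("Lesbian/Gay/Homosexual", 4),
            ("Bisexual/Pansexual", 2),
            ("Straight/Heterosexual", 7),
            ("Asexual", 1),
            ("Do Not Wish to Specify", 1),
        ]
    )
    education = expand(
        [
            ("Bachelor's degree", 3),
            ("Some graduate work", 2),
            ("Master's degree", 8),
            ("Doctoral degree", 2),
        ]
    )
    employment = expand(
        [
            ("Working for pay", 11),
            ("Unemployed and looking for work", 1),
            ("Student", 2),
            (NO_RESPONSE, 1),
        ]
    )
    income = expand(
        [
            ("$0-$19,999", 3),
            ("$20,000-$49,999", 4),
            ("$50,000-$99,999", 5),
            ("Over $100,000", 3),
        ]
    )
    languages = expand(
        [("English only", 8), ("English and other language(s)", 6), (NO_RESPONSE, 1)]
    )
    insurance = [True] * 12 + [False] * 3
    pronouns = expand(
        [
            ("He/Him/His", 8),
            ("She/Her/Hers", 5),
            ("They/Them/Theirs", 1),
            ("He/Him/They", 1),
        ]
    )
    return [
        ParticipantRecord(
            gender=gender[i],
            race=race[i],
            ethnicity=ethnicity[i],
            sexual_orientation=orientation[i],
            education=education[i],
            employment=employment[i],
            income=income[i],
            languages=languages[i],
            has_insurance=insurance[i],
            pronouns=pronouns[i],
        )
        for i in range(15)
    ]


def _pct(count: int, n: int) -> float:
    return round(100.0 * count / n, 1)


def summarize_demographics(records: Sequence[ParticipantRecord]) -> dict:
    """Counts and one-decimal percentages per axis, plus derived composites.

    Percentages are always of the full sample size; missing answers are
    counted under an explicit "No response" category rather than shrinking
    the denominator.
    """
    records = list(records)
    if not records:
        raise ValueError("no participant records supplied")
    n = len(records)
    axes: dict[str, dict[str, dict[str, float | int]]] = {}
    for axis, vocab in _VOCABULARIES.items():
        values = [getattr(r, axis) for r in records]
        axes[axis] = {
            cat: {"n": values.count(cat), "percent": _pct(values.count(cat), n)}
            for cat in vocab
            if values.count(cat) > 0
        }
    n_sexual_minority = sum(
        r.sexual_orientation in SEXUAL_MINORITY_CATEGORIES for r in records
    )
    n_racial_minority = sum(
        r.race not in ("White", NO_RESPONSE) for r in records
    )
    n_multiracial = sum(r.race == "Multi-racial" for r in records)
    n_bachelors = sum(r.education in BACHELORS_OR_HIGHER for r in records)
    n_insured = sum(r.has_insurance for r in records)
    return {
        "n": n,
        "axes": axes,
        "composites": {
            "sexual_minority": {"n": n_sexual_minority, "percent": _pct(n_sexual_minority, n)},
            "racial_minority": {"n": n_racial_minority, "percent": _pct(n_racial_minority, n)},
            "multi_racial": {"n": n_multiracial, "percent": _pct(n_multiracial, n)},
            "bachelors_or_higher": {"n": n_bachelors, "percent": _pct(n_bachelors, n)},
            "has_insurance": {"n": n_insured, "percent": _pct(n_insured, n)},
        },
    }


def records_from_csv(path) -> list[ParticipantRecord]:
    """Read participant records from a CSV with the standardized columns."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(
            ParticipantRecord(
                gender=row["gender"],
                race=row["race"],
                ethnicity=row["ethnicity"],
                sexual_orientation=row["sexual_orientation"],
                education=row["education"],
                employment=row["employment"],
                income=row["income"],
                languages=row["languages"],
                has_insurance=bool(row.get("has_insurance", True)),
            )
        )
    return records
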