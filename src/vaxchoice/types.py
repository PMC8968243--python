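"""Core domain objects for the vaccine choice experiment.

A stated-choice task presents two hypothetical vaccines, each described by
nine attributes, next to a "no vaccine" opt-out.  Respondents carry the
sociodemographic covariates that enter the opt-out index, the observed
preference-heterogeneity interactions, and latent-class membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

ORIGIN_LEVELS = ("Germany", "USA", "UK", "China")
RECOMMENDER_LEVELS = ("PCP", "CDC", "WHO", "Media")

#: Income threshold (US$/yr) above which the cost coefficient shifts.
HIGH_INCOME_THRESHOLD = 120_000.0


@dataclass(frozen=True)
class VaccineProfile:
    """Attribute bundle describing one hypothetical vaccine alternative.

    Units follow the choice cards: dollars out of pocket, percent
    effectiveness, days until antibodies develop, months of protection,
    mild side effects per 10 people, severe side effects per 1,000,000,
    and months since successful clinical trials.
    """

    cost: float
    effectiveness: float
    incubation_days: float
    protection_months: float
    mild_per10: float
    severe_per1e6: float
    recommender: str = "PCP"
    origin: str = "Germany"
    introduced_months: float = 6.0

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError(f"cost must be nonnegative, got {self.cost}")
        if not 0 <= self.effectiveness <= 100:
            raise ValueError(
                f"effectiveness must be in [0, 100], got {self.effectiveness}"
            )
        if not 0 <= self.mild_per10 <= 10:
            raise ValueError(f"mild_per10 must be in [0, 10], got {self.mild_per10}")
        if not 0 <= self.severe_per1e6 <= 1e6:
            raise ValueError(
                f"severe_per1e6 must be in [0, 1e6], got {self.severe_per1e6}"
            )
        if self.recommender not in RECOMMENDER_LEVELS:
            raise ValueError(
                f"recommender: unknown level {self.recommender!r}; "
                f"expected one of {RECOMMENDER_LEVELS}"
            )
        if self.origin not in ORIGIN_LEVELS:
            raise ValueError(
                f"origin: unknown level {self.origin!r}; "
                f"expected one of {ORIGIN_LEVELS}"
            )


_BINARY_FLAGS = (
    "male",
    "education_bsc",
    "education_postgrad",
    "black",
    "hispanic",
    "asian",
    "religion_extreme",
    "democrat",
    "republican",
    "tested_covid",
    "had_covid",
    "no_insurance",
    "flu_shot",
    "against_vaccination",
    "older65_household",
    "underlying_condition",
    "works_fulltime",
    "wave2",
)


@dataclass
class Respondent:
    """Sociodemographic covariate vector w_i of one survey respondent."""

    id: int
    male: int = 0
    household_income: float = 45_000.0
    education_bsc: int = 0
    education_postgrad: int = 0
    age: float = 42.0
    black: int = 0
    hispanic: int = 0
    asian: int = 0
    religion_extreme: int = 0
    democrat: int = 0
    republican: int = 0
    tested_covid: int = 0
    had_covid: int = 0
    no_insurance: int = 0
    flu_shot: int = 0
    against_vaccination: int = 0
    older65_household: int = 0
    bmi: float = 31.0
    underlying_condition: int = 0
    works_fulltime: int = 0
    wave2: int = 0

    def __post_init__(self) -> None:
        for name in _BINARY_FLAGS:
            value = getattr(self, name)
            if value not in (0, 1):
                raise ValueError(f"{name} must be 0/1, got {value!r}")
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.bmi <= 0:
            raise ValueError(f"bmi must be positive, got {self.bmi}")
        if self.democrat and self.republican:
            raise ValueError("democrat and republican cannot both be 1")

    @property
    def high_income(self) -> int:
        """Indicator for household income at or above $120,000/yr."""
        return int(self.household_income >= HIGH_INCOME_THRESHOLD)

    def covariate(self, name: str) -> float:
        """Look up a covariate by name, including the derived high_income."""
        if name == "high_income":
            return float(self.high_income)
        try:
            return float(getattr(self, name))
        except AttributeError:
            raise KeyError(f"unknown respondent covariate {name!r}") from None


CHOICE_LABELS = ("A", "B", "optout")


@dataclass
class ChoiceTask:
    """One choice card: two vaccine profiles and the observed choice."""

    respondent_id: int
    task_index: int
    alternative_A: VaccineProfile
    alternative_B: VaccineProfile
    chosen: str

    def __post_init__(self) -> None:
        if self.chosen not in CHOICE_LABELS:
            raise ValueError(
                f"chosen must be one of {CHOICE_LABELS}, got {self.chosen!r}"
            )

    @property
    def chosen_index(self) -> int:
        return CHOICE_LABELS.index(self.chosen)


def respondent_field_names() -> tuple[str, ...]:
    """All stored covariate field names of :class:`Respondent` except id."""
    return tuple(f.name for f in fields(Respondent) if f.name != "id")
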