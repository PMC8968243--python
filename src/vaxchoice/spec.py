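"""Model specification and design-matrix encoding.

The utility of vaccine j in task t for respondent i is

    u_ijt = x_ijt' (beta + Pi w_i) + e_ijt,

with x_ijt the encoded attribute vector (dummy coding with Germany and PCP
as base levels, an optional free-vaccine indicator on top of linear cost),
while the opt-out alternative carries an index of respondent covariates,

    u_iot = delta_io + w_i' gamma + e_iot,

with iid type-I extreme-value shocks e, so choice probabilities are
softmax over the three utilities.  Observed heterogeneity (the Pi block)
is implemented as attribute-by-covariate product columns appended to x.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .types import (
    ORIGIN_LEVELS,
    RECOMMENDER_LEVELS,
    ChoiceTask,
    Respondent,
    VaccineProfile,
)

#: Encoded attribute columns in fixed order (before interactions).  Origin
#: dummies omit the base level Germany; recommender dummies omit PCP.
BASE_ATTRIBUTE_COLUMNS = (
    "cost",
    "effectiveness",
    "protection",
    "incubation",
    "severe",
    "mild",
    "introduced",
    "origin_usa",
    "origin_uk",
    "origin_china",
    "rec_cdc",
    "rec_who",
    "rec_media",
)

#: Opt-out index covariates, in reporting order.  Income is entered in
#: units of $10,000; age in years; BMI in kg/m^2; the rest are 0/1.
OPTOUT_COVARIATES = (
    "male",
    "household_income_10k",
    "education_bsc",
    "education_postgrad",
    "age",
    "black",
    "hispanic",
    "asian",
    "religion_extreme",
    "democrat",
    "tested_covid",
    "had_covid",
    "no_insurance",
    "flu_shot",
    "against_vaccination",
    "older65_household",
    "bmi",
    "underlying_condition",
    "works_fulltime",
)

#: Latent-class membership covariates: the opt-out list without Hispanic.
CLASS_COVARIATES = tuple(c for c in OPTOUT_COVARIATES if c != "hispanic")

#: Default observed-heterogeneity interactions (attribute, covariate).
DEFAULT_INTERACTIONS = (
    ("cost", "high_income"),
    ("effectiveness", "wave2"),
    ("origin_china", "republican"),
)


def _covariate_value(respondent: Respondent, name: str) -> float:
    """Resolve a covariate name, applying the documented scalings."""
    if name == "household_income_10k":
        return respondent.household_income / 10_000.0
    return respondent.covariate(name)


@dataclass
class ModelSpec:
    """Declarative description of one model variant.

    Parameters
    ----------
    cost_mode
        ``"linear"`` enters cost in dollars only; ``"linear_plus_free"``
        adds a 1[cost == 0] indicator with its own coefficient on top of
        the linear term.
    interactions
        Observed-heterogeneity product columns, as (encoded attribute
        column, respondent covariate) pairs.
    optout_covariates
        Ordered covariate names of the opt-out index (gamma block).
    optout_random
        Whether the opt-out constant is a normal random effect shared
        across a respondent's tasks (panel mixed logit).
    n_classes
        Number of latent preference classes Q (1 = plain conditional
        logit structure).
    class_covariates
        Covariates of the multinomial-logit class-membership model; only
        used when ``n_classes > 1``.
    """

    cost_mode: str = "linear"
    interactions: tuple[tuple[str, str], ...] = DEFAULT_INTERACTIONS
    optout_covariates: tuple[str, ...] = OPTOUT_COVARIATES
    optout_random: bool = False
    n_classes: int = 1
    class_covariates: tuple[str, ...] = CLASS_COVARIATES

    def __post_init__(self) -> None:
        if self.cost_mode not in ("linear", "linear_plus_free"):
            raise ValueError(f"unknown cost_mode {self.cost_mode!r}")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        self.interactions = tuple((a, c) for a, c in self.interactions)
        self.optout_covariates = tuple(self.optout_covariates)
        self.class_covariates = tuple(self.class_covariates)
        base = self.base_columns()
        for attr, cov in self.interactions:
            if attr not in base:
                raise ValueError(f"interaction attribute {attr!r} not a design column")
            _probe_covariate(cov)
        for cov in self.optout_covariates:
            _probe_covariate(cov)
        for cov in self.class_covariates:
            _probe_covariate(cov)

    # -- column bookkeeping -------------------------------------------------

    def base_columns(self) -> tuple[str, ...]:
        if self.cost_mode == "linear_plus_free":
            return ("free",) + BASE_ATTRIBUTE_COLUMNS
        return BASE_ATTRIBUTE_COLUMNS

    def interaction_columns(self) -> tuple[str, ...]:
        return tuple(f"{a}:{c}" for a, c in self.interactions)

    def attribute_columns(self) -> tuple[str, ...]:
        """All encoded utility columns: base attributes then interactions."""
        return self.base_columns() + self.interaction_columns()

    @property
    def n_beta(self) -> int:
        return len(self.base_columns())

    @property
    def n_pi(self) -> int:
        return len(self.interactions)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "cost_mode": self.cost_mode,
            "interactions": [list(p) for p in self.interactions],
            "optout_covariates": list(self.optout_covariates),
            "optout_random": self.optout_random,
            "n_classes": self.n_classes,
            "class_covariates": list(self.class_covariates),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        kwargs = dict(d)
        if "interactions" in kwargs:
            kwargs["interactions"] = tuple(tuple(p) for p in kwargs["interactions"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _probe_covariate(name: str) -> None:
    """Raise KeyError naming the covariate if it cannot be resolved."""
    probe = Respondent(id=-1)
    if name == "household_income_10k":
        return
    probe.covariate(name)  # raises KeyError with the name


#: The four model variants reported in the study, plus the latent-class one.
def named_spec(name: str) -> ModelSpec:
    """Return a predefined model variant.

    ``cl1``/``rpl1`` use linear cost; ``cl2``/``rpl2`` add the free-vaccine
    indicator; ``lcl`` is the 3-class latent-class variant with the free
    indicator (class covariates drop Hispanic).
    """
    name = name.lower()
    table = {
        "cl1": dict(cost_mode="linear", optout_random=False),
        "cl2": dict(cost_mode="linear_plus_free", optout_random=False),
        "rpl1": dict(cost_mode="linear", optout_random=True),
        "rpl2": dict(cost_mode="linear_plus_free", optout_random=True),
        "lcl": dict(cost_mode="linear_plus_free", optout_random=False, n_classes=3),
    }
    if name not in table:
        raise KeyError(f"unknown model variant {name!r}; choose from {sorted(table)}")
    return ModelSpec(**table[name])


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class Parameters:
    """One full parameter point for the utility and opt-out equations.

    ``beta`` is aligned with ``spec.base_columns()``, ``pi`` with
    ``spec.interaction_columns()``, ``gamma`` with
    ``spec.optout_covariates``.  ``sigma_o`` is the standard deviation of
    the random opt-out constant (0 for fixed-constant models).
    """

    beta: np.ndarray
    pi: np.ndarray
    delta_o: float
    gamma: np.ndarray
    sigma_o: float = 0.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.sigma_o < 0:
            raise ValueError("sigma_o must be nonnegative")

    def validate(self, spec: ModelSpec) -> None:
        if self.beta.shape != (spec.n_beta,):
            raise ValueError(
                f"beta block has length {self.beta.size}, spec expects {spec.n_beta}"
            )
        if self.pi.shape != (spec.n_pi,):
            raise ValueError(
                f"pi block has length {self.pi.size}, spec expects {spec.n_pi}"
            )
        if self.gamma.shape != (len(spec.optout_covariates),):
            raise ValueError(
                f"gamma block has length {self.gamma.size}, spec expects "
                f"{len(spec.optout_covariates)}"
            )

    @property
    def utility(self) -> np.ndarray:
        """Coefficients over all encoded columns (beta then pi)."""
        return np.concatenate([self.beta, self.pi])

    @classmethod
    def from_dict(cls, spec: ModelSpec, values: dict) -> "Parameters":
        """Build from a flat {column/covariate name: value} mapping.

        Expects keys for every base column, interaction column, opt-out
        covariate, plus ``delta_o`` and optionally ``sigma_o``.
        """
        beta = np.array([values[c] for c in spec.base_columns()], dtype=float)
        pi = np.array([values[c] for c in spec.interaction_columns()], dtype=float)
        gamma = np.array([values[c] for c in spec.optout_covariates], dtype=float)
        return cls(
            beta=beta,
            pi=pi,
            delta_o=float(values["delta_o"]),
            gamma=gamma,
            sigma_o=float(values.get("sigma_o", 0.0)),
        )

    def to_dict(self, spec: ModelSpec) -> dict:
        out = dict(zip(spec.base_columns(), self.beta.tolist()))
        out.update(zip(spec.interaction_columns(), self.pi.tolist()))
        out["delta_o"] = self.delta_o
        out["sigma_o"] = self.sigma_o
        out.update(zip(spec.optout_covariates, self.gamma.tolist()))
        return out


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------


def encode_vaccine(
    profile: VaccineProfile, respondent: Respondent, spec: ModelSpec
) -> np.ndarray:
    """Encode one vaccine profile into the ordered design vector x_ijt.

    Base levels (Germany, PCP) produce all-zero dummies; interaction
    columns are the product of the encoded attribute and the respondent
    covariate.
    """
    base: dict[str, float] = {
        "cost": profile.cost,
        "effectiveness": profile.effectiveness,
        "protection": profile.protection_months,
        "incubation": profile.incubation_days,
        "severe": profile.severe_per1e6,
        "mild": profile.mild_per10,
        "introduced": profile.introduced_months,
    }
    for level in ORIGIN_LEVELS[1:]:
        base[f"origin_{level.lower()}"] = float(profile.origin == level)
    for level in RECOMMENDER_LEVELS[1:]:
        base[f"rec_{level.lower()}"] = float(profile.recommender == level)
    if spec.cost_mode == "linear_plus_free":
        base["free"] = float(profile.cost == 0)
    values = [base[c] for c in spec.base_columns()]
    for attr, cov in spec.interactions:
        values.append(base[attr] * _covariate_value(respondent, cov))
    return np.array(values, dtype=float)


def encode_optout(respondent: Respondent, spec: ModelSpec) -> np.ndarray:
    """Encode the opt-out covariate vector w_i in the spec's order."""
    return np.array(
        [_covariate_value(respondent, c) for c in spec.optout_covariates],
        dtype=float,
    )


def encode_class_covariates(respondent: Respondent, spec: ModelSpec) -> np.ndarray:
    """Covariates of the class-membership multinomial logit (no constant)."""
    return np.array(
        [_covariate_value(respondent, c) for c in spec.class_covariates],
        dtype=float,
    )


def task_utilities(
    params: Parameters,
    task: ChoiceTask,
    respondent: Respondent,
    spec: ModelSpec,
    delta_i: float | None = None,
) -> np.ndarray:
    """Deterministic utilities (u_A, u_B, u_opt) for one task.

    ``delta_i`` is the realized opt-out constant; defaults to the mean
    ``params.delta_o``.
    """
    coef = params.utility
    u_a = encode_vaccine(task.alternative_A, respondent, spec) @ coef
    u_b = encode_vaccine(task.alternative_B, respondent, spec) @ coef
    if delta_i is None:
        delta_i = params.delta_o
    u_o = delta_i + encode_optout(respondent, spec) @ params.gamma
    return np.array([u_a, u_b, u_o])


def choice_probabilities(
    params: Parameters,
    task: ChoiceTask,
    respondent: Respondent,
    spec: ModelSpec,
    delta_i: float | None = None,
) -> np.ndarray:
    """Logit choice probabilities over (A, B, opt-out) for one task.

    Overflow-safe: the maximum utility is subtracted before
    exponentiation.  Probabilities are strictly positive and sum to 1.
    """
    u = task_utilities(params, task, respondent, spec, delta_i=delta_i)
    if not np.all(np.isfinite(u)):
        raise ValueError(f"non-finite utility vector {u}")
    z = np.exp(u - u.max())
    return z / z.sum()
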