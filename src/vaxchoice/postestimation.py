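"""Post-estimation transforms of fitted choice models.

Willingness to pay is the marginal rate of substitution between an
attribute and out-of-pocket cost, w_k = -beta_k / beta_cost (with the
cost coefficient shifted by the high-income interaction for the high
income group, and the attribute coefficient shifted by its own
interaction where one exists).  Opt-out coefficients transform to odds
ratios exp(gamma); latent-class membership coefficients transform to
odds ratios of class assignment relative to class 1.  Scenario curves
integrate the probability triple over the random opt-out constant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .spec import ModelSpec, Parameters
from .types import Respondent, VaccineProfile

Z95 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# Willingness to pay
# ---------------------------------------------------------------------------


@dataclass
class WTPEntry:
    attribute: str
    income_group: str
    value: float
    se: float | None
    ci_low: float | None
    ci_high: float | None
    p: float | None


def _name_index(result, name: str) -> int:
    try:
        return result.names.index(name)
    except ValueError:
        raise KeyError(f"parameter {name!r} not in this model") from None


def wtp(
    result,
    attribute: str,
    income_group: str = "low",
    covariate: str | None = None,
) -> WTPEntry:
    """Willingness to pay for a marginal change in one attribute.

    ``covariate`` names an interaction partner whose coefficient is added
    to the attribute coefficient (e.g. effectiveness during wave 2, or
    the China dummy for republicans).  The effective cost coefficient of
    the high income group includes the cost x high-income interaction.
    SEs use the delta method on the ratio; they are omitted when the
    result carries no covariance.
    """
    if income_group not in ("low", "high"):
        raise ValueError("income_group must be 'low' or 'high'")
    theta = result.theta
    idx_num = [_name_index(result, attribute)]
    if covariate is not None:
        idx_num.append(_name_index(result, f"{attribute}:{covariate}"))
    idx_cost = [_name_index(result, "cost")]
    if income_group == "high":
        idx_cost.append(_name_index(result, "cost:high_income"))

    num = float(theta[idx_num].sum())
    den = float(theta[idx_cost].sum())
    if num != 0.0 and abs(den) < 1e-10:
        raise ZeroDivisionError(
            "effective cost coefficient is numerically zero; WTP undefined"
        )
    value = 0.0 if num == 0.0 else -num / den

    se = ci_low = ci_high = p = None
    if result.cov is not None and abs(den) >= 1e-10:
        g = np.zeros(theta.size)
        g[idx_num] = -1.0 / den
        g[idx_cost] = num / den**2
        var = float(g @ result.cov @ g)
        se = float(np.sqrt(max(var, 0.0)))
        ci_low, ci_high = value - Z95 * se, value + Z95 * se
        if se > 0:
            p = float(2 * stats.norm.sf(abs(value) / se))
    return WTPEntry(
        attribute=attribute if covariate is None else f"{attribute} x {covariate}",
        income_group=income_group,
        value=value,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        p=p,
    )


def wtp_table(result) -> pd.DataFrame:
    """WTP for every non-cost attribute, both income groups.

    Interaction rows (attribute for the flagged subgroup) are included
    after the corresponding main effects.  Non-significant entries are
    reported with their p-values rather than suppressed.
    """
    spec: ModelSpec = result.spec
    rows = []
    skip = {"cost", "free"}
    for group in ("low", "high"):
        for col in spec.base_columns():
            if col in skip:
                continue
            rows.append(wtp(result, col, income_group=group))
        for attr, cov in spec.interactions:
            if attr in skip or cov == "high_income":
                continue
            rows.append(wtp(result, attr, income_group=group, covariate=cov))
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


# ---------------------------------------------------------------------------
# Odds ratios
# ---------------------------------------------------------------------------


def _or_row(name, coef, se):
    or_val = float(np.exp(coef))
    if se is None or not np.isfinite(se):
        return dict(name=name, coef=float(coef), odds_ratio=or_val,
                    ci_low=np.nan, ci_high=np.nan, p=np.nan)
    return dict(
        name=name,
        coef=float(coef),
        odds_ratio=or_val,
        ci_low=float(np.exp(coef - Z95 * se)),
        ci_high=float(np.exp(coef + Z95 * se)),
        p=float(2 * stats.norm.sf(abs(coef / se))) if se > 0 else 0.0,
    )


def odds_ratios(result) -> pd.DataFrame:
    """Odds ratios of opting out: exp of the opt-out index coefficients.

    Includes the opt-out constant mean and, for mixed-logit results, the
    exp of its standard deviation.  Confidence intervals are
    exp(coef +/- 1.96 SE); significance is inherited from the underlying
    coefficient (interpret the OR against 1).
    """
    import warnings

    bse = result.bse
    if result.cov is None:
        warnings.warn("result has no covariance; OR confidence intervals omitted")
    rows = []
    for i, name in enumerate(result.names):
        if name == "delta_o":
            rows.append(_or_row("optout_constant_mean", result.theta[i], bse[i]))
        elif name == "sigma_o":
            rows.append(_or_row("optout_constant_sd", result.theta[i], bse[i]))
        elif name.startswith("optout:"):
            rows.append(_or_row(name.removeprefix("optout:"), result.theta[i], bse[i]))
    return pd.DataFrame(rows).set_index("name")


def class_assignment_odds(lcl_result, reference_class: int = 1) -> pd.DataFrame:
    """Odds ratios of class assignment relative to the reference class.

    Only reference class 1 is supported (the model's identification
    convention); one column block per non-reference class.
    """
    if reference_class != 1:
        raise ValueError("class 1 is the membership reference in this model")
    if lcl_result.Q < 2:
        raise ValueError("class assignment odds require Q >= 2")
    names = lcl_result.names
    bse = lcl_result.bse
    rows = []
    for i, name in enumerate(names):
        if not name.startswith("member"):
            continue
        cls, cov = name.split(":", 1)
        row = _or_row(cov, lcl_result.theta[i], bse[i])
        row["class"] = int(cls.removeprefix("member"))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Posterior class assignment
# ---------------------------------------------------------------------------


def posterior_class_probabilities(lcl_result, dataset=None) -> np.ndarray:
    """Posterior class probabilities given each observed choice sequence.

    Bayes' rule in log space: post_iq proportional to pi_iq * L_iq with
    L_iq the class-conditional likelihood of respondent i's sequence.
    With no ``dataset`` the training-sample responsibilities are
    returned; otherwise posteriors are evaluated on the new data with
    the fitted parameters.
    """
    if dataset is None:
        return lcl_result.responsibilities.copy()
    from .models.latent import LatentClassLogit

    spec = getattr(lcl_result, "spec", None)
    if spec is None:
        spec = lcl_result.model.spec
    model = LatentClassLogit(dataset, spec)
    R, _ = model._estep(
        np.asarray(lcl_result.class_thetas, float),
        np.asarray(lcl_result.membership, float),
    )
    return R


def assign_classes(lcl_result, seed: int, dataset=None):
    """Randomly assign respondents to classes from their posteriors.

    Returns (labels, realized_shares, expected_shares); labels are
    1-based, one draw per respondent with the given seed, so degenerate
    posteriors assign deterministically.
    """
    post = posterior_class_probabilities(lcl_result, dataset)
    rng = np.random.default_rng(seed)
    u = rng.random(post.shape[0])
    cum = np.cumsum(post, axis=1)
    labels = 1 + (u[:, None] > cum).sum(axis=1)
    Q = post.shape[1]
    realized = np.array([(labels == q + 1).mean() for q in range(Q)])
    return labels, realized, post.mean(axis=0)


# ---------------------------------------------------------------------------
# Scenario probability curves
# ---------------------------------------------------------------------------

_ATTR_FIELD = {
    "cost": "cost",
    "effectiveness": "effectiveness",
    "incubation": "incubation_days",
    "protection": "protection_months",
    "mild": "mild_per10",
    "severe": "severe_per1e6",
    "introduced": "introduced_months",
}

#: Representative individual of the scenario analyses: white male, aged 42,
#: BMI 31, household income $62,236 (sample means), wave 1.
def representative_individual(**overrides) -> Respondent:
    base = dict(id=0, male=1, age=42.0, bmi=31.0, household_income=62_236.0)
    base.update(overrides)
    return Respondent(**base)


@dataclass
class ScenarioCurve:
    """Probability triple along a grid of one attribute of vaccine A."""

    attribute: str
    grid: np.ndarray
    probabilities: np.ndarray  # (n_grid, 3): P(A), P(B), P(optout)
    integration: str
    integration_size: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.attribute: self.grid,
                "P_A": self.probabilities[:, 0],
                "P_B": self.probabilities[:, 1],
                "P_optout": self.probabilities[:, 2],
            }
        )

    def crossing(self, first: str = "A", second: str = "optout") -> float | None:
        """Grid value where the two series cross (linear interpolation)."""
        cols = {"A": 0, "B": 1, "optout": 2}
        d = self.probabilities[:, cols[first]] - self.probabilities[:, cols[second]]
        sign_change = np.where(np.diff(np.sign(d)) != 0)[0]
        if len(sign_change) == 0:
            return None
        i = sign_change[0]
        x0, x1 = self.grid[i], self.grid[i + 1]
        return float(x0 - d[i] * (x1 - x0) / (d[i + 1] - d[i]))

    def plot(self, path=None, ax=None):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4.5))
        for j, lab in enumerate(("vaccine A", "vaccine B", "no vaccine")):
            ax.plot(self.grid, self.probabilities[:, j], label=lab)
        ax.set_xlabel(self.attribute)
        ax.set_ylabel("choice probability")
        ax.set_ylim(0, 1)
        ax.legend()
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def scenario_curves(
    result,
    profile_A: VaccineProfile,
    profile_B: VaccineProfile,
    respondent: Respondent,
    varied_attribute: str,
    grid,
    integration: str = "gauss_hermite",
    n_nodes: int = 30,
    R: int = 10_000,
    seed: int = 0,
) -> ScenarioCurve:
    """Population-average probability triple while one attribute of A varies.

    For mixed-logit parameters the triple is E_delta[P(. | delta)] with
    delta ~ N(delta_o, sigma_o^2), integrated by Gauss-Hermite quadrature
    (default) or seeded Monte Carlo.  Grid values outside the attribute
    domain are rejected by the profile invariants.
    """
    if varied_attribute not in _ATTR_FIELD:
        raise KeyError(f"unknown varied attribute {varied_attribute!r}")
    params: Parameters = result.parameters
    spec: ModelSpec = result.spec
    from .spec import encode_optout, encode_vaccine

    grid = np.asarray(grid, dtype=float)
    sigma = params.sigma_o
    if sigma > 0:
        if integration == "gauss_hermite":
            x, w = np.polynomial.hermite.hermgauss(n_nodes)
            deltas = params.delta_o + sigma * np.sqrt(2.0) * x
            weights = w / np.sqrt(np.pi)
            size = n_nodes
        elif integration == "monte_carlo":
            # randomized-Halton (shifted low-discrepancy) normal deviates:
            # the integral is one-dimensional, where quasi-Monte Carlo error
            # decays ~1/R instead of 1/sqrt(R)
            from .models.mixed import van_der_corput

            rng = np.random.default_rng(seed)
            u = (van_der_corput(R) + rng.random()) % 1.0
            z = stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
            deltas = params.delta_o + sigma * z
            weights = np.full(R, 1.0 / R)
            size = R
        else:
            raise ValueError(f"unknown integration scheme {integration!r}")
    else:
        deltas = np.array([params.delta_o])
        weights = np.array([1.0])
        size = 1

    coef = params.utility
    u_b = float(encode_vaccine(profile_B, respondent, spec) @ coef)
    w_index = float(encode_optout(respondent, spec) @ params.gamma)
    u_o = w_index + deltas  # (size,)

    probs = np.empty((grid.size, 3))
    field_name = _ATTR_FIELD[varied_attribute]
    for gi, val in enumerate(grid):
        prof = replace(profile_A, **{field_name: val})
        u_a = float(encode_vaccine(prof, respondent, spec) @ coef)
        U = np.column_stack(
            [np.full(size, u_a), np.full(size, u_b), u_o]
        )  # (size, 3)
        m = U.max(axis=1, keepdims=True)
        E = np.exp(U - m)
        P = E / E.sum(axis=1, keepdims=True)
        probs[gi] = weights @ P
    return ScenarioCurve(
        attribute=varied_attribute,
        grid=grid,
        probabilities=probs,
        integration=integration if sigma > 0 else "none",
        integration_size=size,
        seed=seed if (sigma > 0 and integration == "monte_carlo") else None,
    )
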