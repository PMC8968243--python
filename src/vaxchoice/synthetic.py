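"""Synthetic choice-experiment generator.

Emulates the study conditions: a 24-scenario two-alternative design over
the nine vaccine attributes, a respondent population matching the
published sample marginals (2,723 respondents, wave 2 = 1,049/2,723),
random 7-of-24 task assignment, and choices drawn from the exact logit
probabilities of the requested data-generating process (fixed constant,
random constant, or latent classes).  Covariates are sampled
independently: the study reports marginals only, not joints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ATTRIBUTE_CSV_COLUMNS, ChoiceDataset
from .models.base import _covariate_series
from .spec import ModelSpec, Parameters
from .types import (
    ORIGIN_LEVELS,
    RECOMMENDER_LEVELS,
    Respondent,
    VaccineProfile,
    respondent_field_names,
)

DEFAULT_LEVELS = {
    "cost": (0.0, 50.0, 100.0, 175.0),
    "effectiveness": (20.0, 40.0, 60.0, 80.0),
    "incubation": (7.0, 14.0, 21.0),
    "protection": (3.0, 6.0, 12.0),
    "mild": (1.0, 3.0, 5.0),
    "severe": (1.0, 10.0, 100.0),
    "recommender": RECOMMENDER_LEVELS,
    "origin": ORIGIN_LEVELS,
    "introduced": (3.0, 6.0),
}

#: Published sample marginals used as generator defaults.
DEFAULT_MARGINALS = {
    "male": 0.4495,
    "education_bsc": 0.2229,
    "education_postgrad": 0.1774,  # master's + doctoral
    "black": 0.1351,
    "hispanic": 0.1245,
    "asian": 0.0419,
    "religion_extreme": 0.25,
    "tested_covid": 0.2233,
    "had_covid": 0.0411,
    "no_insurance": 0.1356,
    "flu_shot": 0.3452,
    "against_vaccination": 0.0540,
    "older65_household": 0.15,
    "underlying_condition": 0.30,
    "works_fulltime": 0.4837,
}

#: Political affiliation shares (mutually exclusive).
PARTY_SHARES = {"democrat": 0.4209, "republican": 0.2993}

#: Age-generation shares and year-of-birth bands (survey year 2020).
AGE_BANDS = (
    (0.4950, 24, 39),  # millennials
    (0.2868, 40, 55),  # generation X
    (0.1924, 56, 74),  # baby boomers
    (0.0257, 75, 90),  # older
)


@dataclass
class DesignConfig:
    levels: dict = field(default_factory=lambda: dict(DEFAULT_LEVELS))
    n_scenarios: int = 24
    tasks_per_respondent: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tasks_per_respondent > self.n_scenarios:
            raise ValueError("tasks_per_respondent cannot exceed n_scenarios")
        for name, lv in self.levels.items():
            if len(lv) < 2:
                raise ValueError(f"attribute {name!r} needs at least 2 levels")


@dataclass
class PopulationConfig:
    n_respondents: int = 2723
    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    party_shares: dict = field(default_factory=lambda: dict(PARTY_SHARES))
    wave2_share: float = 1049 / 2723
    age_bands: tuple = AGE_BANDS
    income_log_median: float = 45_000.0
    income_log_sigma: float = 0.9
    bmi_mean: float = 31.0
    bmi_sd: float = 6.0
    bmi_floor: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        for name, p in self.marginals.items():
            if not 0 <= p <= 1:
                raise ValueError(f"marginal for {name!r} outside [0, 1]")


def _balanced_column(levels, n, rng) -> np.ndarray:
    reps = int(np.ceil(n / len(levels)))
    col = np.tile(np.asarray(levels, dtype=object), reps)[:n]
    rng.shuffle(col)
    return col


def generate_design(config: DesignConfig) -> list[tuple[VaccineProfile, VaccineProfile]]:
    """Seeded, approximately level-balanced random design.

    Each of the ``n_scenarios`` cards pairs two independently composed
    profiles; every attribute column cycles through its level set before
    shuffling, so levels are balanced up to remainder.  Cards pairing two
    identical profiles are repaired by re-drawing one attribute.
    """
    rng = np.random.default_rng(config.seed)
    n_prof = 2 * config.n_scenarios
    cols = {
        name: _balanced_column(levels, n_prof, rng)
        for name, levels in config.levels.items()
    }
    profiles = []
    for i in range(n_prof):
        profiles.append(
            VaccineProfile(
                cost=float(cols["cost"][i]),
                effectiveness=float(cols["effectiveness"][i]),
                incubation_days=float(cols["incubation"][i]),
                protection_months=float(cols["protection"][i]),
                mild_per10=float(cols["mild"][i]),
                severe_per1e6=float(cols["severe"][i]),
                recommender=str(cols["recommender"][i]),
                origin=str(cols["origin"][i]),
                introduced_months=float(cols["introduced"][i]),
            )
        )
    cards = []
    for s in range(config.n_scenarios):
        a, b = profiles[2 * s], profiles[2 * s + 1]
        if a == b:  # repair a degenerate card by flipping one attribute
            other_costs = [c for c in config.levels["cost"] if c != b.cost]
            from dataclasses import replace

            b = replace(b, cost=float(rng.choice(other_costs)))
        cards.append((a, b))
    return cards


def sample_population(config: PopulationConfig) -> list[Respondent]:
    """Independent seeded draws per covariate with the published marginals."""
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents
    flags = {
        name: (rng.random(n) < p).astype(int)
        for name, p in config.marginals.items()
    }
    # mutually exclusive party affiliation
    u = rng.random(n)
    p_dem = config.party_shares.get("democrat", 0.0)
    p_rep = config.party_shares.get("republican", 0.0)
    democrat = (u < p_dem).astype(int)
    republican = ((u >= p_dem) & (u < p_dem + p_rep)).astype(int)
    # wave 2: last block of respondents, as in the survey timeline
    wave2 = np.zeros(n, dtype=int)
    wave2[int(round(n * (1 - config.wave2_share))) :] = 1
    # age: generation mixture, uniform within band
    shares = np.array([b[0] for b in config.age_bands], float)
    shares = shares / shares.sum()
    band = rng.choice(len(config.age_bands), size=n, p=shares)
    lo = np.array([b[1] for b in config.age_bands], float)[band]
    hi = np.array([b[2] for b in config.age_bands], float)[band]
    age = rng.uniform(lo, hi + 1.0)
    income = config.income_log_median * np.exp(
        config.income_log_sigma * rng.standard_normal(n)
    )
    bmi = np.maximum(
        config.bmi_mean + config.bmi_sd * rng.standard_normal(n), config.bmi_floor
    )
    out = []
    for i in range(n):
        out.append(
            Respondent(
                id=i,
                male=int(flags["male"][i]),
                household_income=float(income[i]),
                education_bsc=int(flags["education_bsc"][i]),
                education_postgrad=int(flags["education_postgrad"][i]),
                age=float(age[i]),
                black=int(flags["black"][i]),
                hispanic=int(flags["hispanic"][i]),
                asian=int(flags["asian"][i]),
                religion_extreme=int(flags["religion_extreme"][i]),
                democrat=int(democrat[i]),
                republican=int(republican[i]),
                tested_covid=int(flags["tested_covid"][i]),
                had_covid=int(flags["had_covid"][i]),
                no_insurance=int(flags["no_insurance"][i]),
                flu_shot=int(flags["flu_shot"][i]),
                against_vaccination=int(flags["against_vaccination"][i]),
                older65_household=int(flags["older65_household"][i]),
                bmi=float(bmi[i]),
                underlying_condition=int(flags["underlying_condition"][i]),
                works_fulltime=int(flags["works_fulltime"][i]),
                wave2=int(wave2[i]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Choice simulation
# ---------------------------------------------------------------------------


def _card_frame(cards) -> pd.DataFrame:
    """Attribute table with one row per card x alternative."""
    rows = []
    for s, (a, b) in enumerate(cards):
        for alt, p in (("A", a), ("B", b)):
            rows.append(
                dict(
                    card=s,
                    alt=alt,
                    cost=p.cost,
                    effectiveness=p.effectiveness,
                    incubation=p.incubation_days,
                    protection=p.protection_months,
                    mild=p.mild_per10,
                    severe=p.severe_per1e6,
                    recommender=p.recommender,
                    origin=p.origin,
                    introduced=p.introduced_months,
                )
            )
    return pd.DataFrame(rows)


def _respondent_frame(respondents) -> pd.DataFrame:
    cov_names = respondent_field_names()
    return pd.DataFrame(
        [{**{"resp_id": r.id}, **{c: getattr(r, c) for c in cov_names}} for r in respondents]
    )


def _encode_cards(card_df: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """(n_cards, 2, K_base) base-attribute encoding of the design."""
    base = {
        "cost": card_df["cost"].to_numpy(float),
        "effectiveness": card_df["effectiveness"].to_numpy(float),
        "protection": card_df["protection"].to_numpy(float),
        "incubation": card_df["incubation"].to_numpy(float),
        "severe": card_df["severe"].to_numpy(float),
        "mild": card_df["mild"].to_numpy(float),
        "introduced": card_df["introduced"].to_numpy(float),
    }
    origin = card_df["origin"].to_numpy()
    rec = card_df["recommender"].to_numpy()
    for level in ORIGIN_LEVELS[1:]:
        base[f"origin_{level.lower()}"] = (origin == level).astype(float)
    for level in RECOMMENDER_LEVELS[1:]:
        base[f"rec_{level.lower()}"] = (rec == level).astype(float)
    if spec.cost_mode == "linear_plus_free":
        base["free"] = (base["cost"] == 0).astype(float)
    X = np.column_stack([base[c] for c in spec.base_columns()])
    n_cards = len(card_df) // 2
    return X.reshape(n_cards, 2, -1), base


def simulate_choices(
    cards,
    respondents,
    params,
    spec: ModelSpec,
    seed: int = 0,
    tasks_per_respondent: int = 7,
):
    """Simulate a panel of observed choices from the exact logit kernel.

    ``params`` determines the data-generating process: a
    :class:`Parameters` with ``sigma_o == 0`` is a conditional logit;
    ``sigma_o > 0`` draws one opt-out constant per respondent (panel
    random effect); an object with ``class_results``/``membership``
    (latent-class parameters) draws one class per respondent from the
    membership logit.  Returns ``(ChoiceDataset, truth)`` where truth
    records the per-respondent realized constant or class label.

    Choices are sampled directly from the closed-form probability
    triple, which is distributionally identical to adding Gumbel shocks.
    """
    rng = np.random.default_rng(seed)
    n_resp = len(respondents)
    n_cards = len(cards)
    T = tasks_per_respondent
    if T > n_cards:
        raise ValueError("tasks_per_respondent exceeds number of cards")

    card_df = _card_frame(cards)
    resp_df = _respondent_frame(respondents)
    Xcards, base_cols = _encode_cards(card_df, spec)

    latent = hasattr(params, "membership")
    if latent:
        for q in range(1, params.Q + 1):
            params.class_results(q).parameters.validate(
                type(spec)(**{**spec.to_dict(), "optout_covariates": [],
                              "optout_random": False, "n_classes": 1})
            )
    else:
        params.validate(spec)

    # 7-of-24 random card subsets per respondent
    assign = np.empty((n_resp, T), dtype=int)
    for i in range(n_resp):
        assign[i] = rng.choice(n_cards, size=T, replace=False)

    # base utility pieces per (respondent, task, alternative)
    Xb = Xcards[assign]  # (n_resp, T, 2, Kb)
    inter_vals = []
    base_name_to_idx = {c: k for k, c in enumerate(spec.base_columns())}
    for attr, cov in spec.interactions:
        attr_col = Xb[..., base_name_to_idx[attr]]  # (n_resp, T, 2)
        cov_val = _covariate_series(resp_df, cov)  # (n_resp,)
        inter_vals.append(attr_col * cov_val[:, None, None])
    X_full = np.concatenate(
        [Xb] + [v[..., None] for v in inter_vals], axis=-1
    )  # (n_resp, T, 2, K)

    truth: dict = {}
    if latent:
        # class membership draw per respondent
        Wm = np.column_stack(
            [np.ones(n_resp)]
            + [_covariate_series(resp_df, c) for c in spec.class_covariates]
        )
        logits = np.zeros((n_resp, params.Q))
        logits[:, 1:] = Wm @ np.asarray(params.membership, float).T
        m = logits.max(axis=1, keepdims=True)
        pi = np.exp(logits - m)
        pi /= pi.sum(axis=1, keepdims=True)
        u = rng.random(n_resp)
        labels = (u[:, None] > np.cumsum(pi, axis=1)).sum(axis=1)  # 0-based
        coefs = np.stack(
            [
                np.asarray(params.class_results(q).parameters.utility)
                for q in range(1, params.Q + 1)
            ]
        )
        deltas = np.array(
            [params.class_results(q).parameters.delta_o for q in range(1, params.Q + 1)]
        )
        coef_i = coefs[labels]  # (n_resp, K)
        u_v = np.einsum("rtak,rk->rta", X_full, coef_i)
        u_o = deltas[labels][:, None]  # (n_resp, 1)
        truth["class_label"] = labels + 1
        truth["class_priors"] = pi
    else:
        coef = params.utility
        u_v = X_full @ coef  # (n_resp, T, 2)
        w_opt = np.column_stack(
            [_covariate_series(resp_df, c) for c in spec.optout_covariates]
        ) if spec.optout_covariates else np.zeros((n_resp, 0))
        delta_i = np.full(n_resp, params.delta_o)
        if params.sigma_o > 0:
            delta_i = delta_i + params.sigma_o * rng.standard_normal(n_resp)
            truth["delta_i"] = delta_i.copy()
        u_o = (delta_i + (w_opt @ params.gamma if w_opt.size else 0.0))[:, None]

    U = np.concatenate(
        [u_v, np.broadcast_to(u_o[..., None], (n_resp, T, 1))], axis=2
    )  # (n_resp, T, 3)
    m = U.max(axis=2, keepdims=True)
    E = np.exp(U - m)
    P = E / E.sum(axis=2, keepdims=True)
    u01 = rng.random((n_resp, T))
    chosen = (u01[..., None] > np.cumsum(P, axis=2)).sum(axis=2)  # 0,1,2

    truth["choice_probabilities"] = P
    truth["assignment"] = assign

    # assemble the long DataFrame (3 rows per task), vectorized
    resp_ids = np.repeat(resp_df["resp_id"].to_numpy(), T * 3)
    task_idx = np.tile(np.repeat(np.arange(1, T + 1), 3), n_resp)
    alts = np.tile(np.array(["A", "B", "optout"]), n_resp * T)
    chosen_flat = np.repeat(chosen.reshape(-1), 3)
    chosen_col = (
        chosen_flat == np.tile(np.array([0, 1, 2]), n_resp * T)
    ).astype(int)

    card_flat = np.repeat(assign.reshape(-1), 3)  # card per row
    alt_code = np.tile(np.array([0, 1, 2]), n_resp * T)
    card_row = card_flat * 2 + np.minimum(alt_code, 1)  # optout borrows A row

    data = {
        "resp_id": resp_ids,
        "task": task_idx,
        "alt": alts,
        "chosen": chosen_col,
    }
    card_cols = card_df.set_index(card_df.index)  # positional
    for col in ATTRIBUTE_CSV_COLUMNS:
        vals = card_cols[col].to_numpy()[card_row].astype(object)
        vals[alt_code == 2] = np.nan
        data[col] = vals
    for cov in respondent_field_names():
        data[cov] = np.repeat(resp_df[cov].to_numpy(), T * 3)
    df = pd.DataFrame(data)
    for col in ("cost", "effectiveness", "incubation", "protection", "mild",
                "severe", "introduced"):
        df[col] = pd.to_numeric(df[col])
    return ChoiceDataset(df), truth


# ---------------------------------------------------------------------------
# Recovery experiments
# ---------------------------------------------------------------------------


def recovery_experiment(
    design_config: DesignConfig,
    population_config: PopulationConfig,
    true_params: Parameters,
    spec: ModelSpec,
    n_replicates: int = 3,
    seed: int = 0,
    draws_R: int = 200,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Repeated simulate-and-refit audit of the CL or RPL estimator.

    Returns one row per parameter with the truth, mean estimate, bias,
    RMSE, empirical SE, mean reported SE, 95% CI coverage, and the
    largest |estimate - truth| / SE across replicates.  Estimator
    failures are recorded (column ``n_fail``), not fatal.
    """
    from .models.clogit import ConditionalLogit
    from .models.mixed import DrawSet, PanelMixedLogit

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    fit_kwargs = dict(fit_kwargs or {})
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3 * n_replicates)]

    cards = generate_design(design_config)
    estimates, ses = [], []
    names = None
    theta_true = None
    n_fail = 0
    for rep in range(n_replicates):
        s_pop, s_sim, s_draw = child_seeds[3 * rep : 3 * rep + 3]
        pop = sample_population(
            PopulationConfig(**{**population_config.__dict__, "seed": s_pop})
        )
        dataset, _ = simulate_choices(
            cards, pop, true_params, spec, seed=s_sim,
            tasks_per_respondent=design_config.tasks_per_respondent,
        )
        try:
            if spec.optout_random:
                model = PanelMixedLogit(
                    dataset,
                    spec,
                    draws=DrawSet.generate(len(pop), R=draws_R, seed=s_draw),
                )
                res = model.fit(**fit_kwargs)
                theta_true = model.pack_parameters(true_params)
            else:
                model = ConditionalLogit(dataset, spec)
                res = model.fit(**fit_kwargs)
                theta_true = model.pack_parameters(true_params)
            names = res.names
            estimates.append(res.theta)
            ses.append(res.bse)
        except Exception:
            n_fail += 1
    if not estimates:
        raise RuntimeError("all replicates failed")
    E = np.vstack(estimates)
    S = np.vstack(ses)
    bias = E.mean(axis=0) - theta_true
    rmse = np.sqrt(((E - theta_true) ** 2).mean(axis=0))
    cover = (
        (E - 1.96 * S <= theta_true) & (theta_true <= E + 1.96 * S)
    ).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        maxz = np.abs((E - theta_true) / S).max(axis=0)
    table = pd.DataFrame(
        {
            "parameter": names,
            "truth": theta_true,
            "mean_estimate": E.mean(axis=0),
            "bias": bias,
            "rmse": rmse,
            "empirical_se": E.std(axis=0, ddof=1) if len(E) > 1 else np.nan,
            "mean_se": S.mean(axis=0),
            "coverage_95": cover,
            "max_abs_z": maxz,
        }
    )
    table.attrs["n_fail"] = n_fail
    table.attrs["n_replicates"] = n_replicates
    return table
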