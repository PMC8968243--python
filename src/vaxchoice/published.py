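"""Published point estimates of the US COVID-19 vaccine choice study.

The microdata behind the study were never deposited, but its fitted
coefficients were printed to four decimals.  This module stores those
point estimates for the four reported model variants (conditional logit
and random-constant logit, each with and without the free-vaccine
indicator) and the selected 3-class latent-class model, so that
post-estimation transforms (odds ratios, willingness to pay, scenario
curves) and the synthetic data generator can be driven by realistic,
study-scale parameter values.  No covariance matrices were published, so
these parameter sets carry none.
"""

from __future__ import annotations

import numpy as np

from .spec import CLASS_COVARIATES, ModelSpec, Parameters, named_spec


class FixedParameters:
    """Parameters-only stand-in for an estimation result.

    Exposes the same surface post-estimation needs (``theta``, ``names``,
    ``cov``, ``parameters``, ``spec``) for a parameter point that was not
    estimated in this session, e.g. published coefficients.
    """

    def __init__(self, spec: ModelSpec, params: Parameters, cov=None):
        params.validate(spec)
        self.spec = spec
        self.parameters = params
        self.cov = cov
        self.names = list(spec.attribute_columns()) + ["delta_o"] + [
            f"optout:{c}" for c in spec.optout_covariates
        ]
        theta = np.concatenate([params.utility, [params.delta_o], params.gamma])
        if spec.optout_random:
            self.names.append("sigma_o")
            theta = np.concatenate([theta, [params.sigma_o]])
        self.theta = theta

    @property
    def bse(self):
        if self.cov is None:
            return np.full(self.theta.size, np.nan)
        return np.sqrt(np.clip(np.diag(self.cov), 0, None))


class PublishedLatentClass:
    """Published 3-class latent-class estimates (parameters only)."""

    model_kind = "LCL"

    def __init__(self, spec, class_params, membership, expected_size):
        self.spec = spec
        self._class_params = class_params  # list of Parameters (gamma empty)
        self.membership = np.asarray(membership, float)  # (Q-1, 1+Kc)
        self.expected_size = np.asarray(expected_size, float)
        self.cov = None

    @property
    def Q(self) -> int:
        return len(self._class_params)

    @property
    def class_thetas(self) -> np.ndarray:
        return np.stack(
            [np.concatenate([p.utility, [p.delta_o]]) for p in self._class_params]
        )

    @property
    def theta(self) -> np.ndarray:
        blocks = [
            np.concatenate([p.utility, [p.delta_o]]) for p in self._class_params
        ]
        return np.concatenate(blocks + [self.membership.ravel()])

    @property
    def names(self) -> list[str]:
        per_class = list(self.spec.attribute_columns()) + ["delta_o"]
        out = []
        for q in range(self.Q):
            out += [f"class{q + 1}:{n}" for n in per_class]
        member_names = ("const",) + self.spec.class_covariates
        for q in range(2, self.Q + 1):
            out += [f"member{q}:{n}" for n in member_names]
        return out

    @property
    def bse(self) -> np.ndarray:
        return np.full(self.theta.size, np.nan)

    def class_results(self, q: int) -> FixedParameters:
        class_spec = ModelSpec(
            **{
                **self.spec.to_dict(),
                "optout_covariates": [],
                "optout_random": False,
                "n_classes": 1,
            }
        )
        return FixedParameters(class_spec, self._class_params[q - 1])


_GAMMA_ORDER = (
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

# beta rows in the order: cost, effectiveness, protection, incubation,
# severe, mild, introduced, origin USA/UK/China, rec CDC/WHO/Media;
# models 2 prepend the free-vaccine indicator.
_PUBLISHED_RAW = {
    "cl1": dict(
        beta=dict(
            cost=-0.0043, effectiveness=0.0102, protection=0.0311,
            incubation=-0.0120, severe=-0.0024, mild=-0.0355, introduced=0.0340,
            origin_usa=0.2687, origin_uk=0.1587, origin_china=-0.3132,
            rec_cdc=-0.0286, rec_who=-0.0648, rec_media=-0.3864,
        ),
        pi=(0.0024, 0.0030, -0.1629),
        delta_o=1.0540,
        sigma_o=0.0,
        gamma=(
            -0.6604, -0.0172, -0.1492, -0.6764, 0.0257, 0.3006, -0.0123,
            0.0833, -0.1637, -0.5340, -0.1395, -0.3353, 0.1962, -0.5152,
            1.7706, -0.2380, -0.0095, -0.3240, -0.4177,
        ),
        loglik=-18425.00,
        bic=37205.10,
    ),
    "rpl1": dict(
        beta=dict(
            cost=-0.0047, effectiveness=0.0111, protection=0.0319,
            incubation=-0.0111, severe=-0.0027, mild=-0.0515, introduced=0.0282,
            origin_usa=0.4327, origin_uk=0.2527, origin_china=-0.3046,
            rec_cdc=-0.0415, rec_who=-0.2166, rec_media=-0.5599,
        ),
        pi=(0.0024, 0.0022, -0.2017),
        delta_o=0.6720,
        sigma_o=3.2605,
        gamma=(
            -1.4286, -0.0557, -0.3383, -1.5117, 0.0571, 0.7639, 0.0445,
            0.3388, -0.4939, -1.1452, -0.3627, -0.2013, 0.5062, -1.0224,
            4.1637, -0.4946, -0.0200, -0.6834, -0.9344,
        ),
        loglik=-15219.00,
        bic=30802.81,
    ),
    "cl2": dict(
        beta=dict(
            free=0.4116, cost=-0.0030, effectiveness=0.0110, protection=0.0319,
            incubation=-0.0078, severe=-0.0026, mild=-0.0486, introduced=0.0497,
            origin_usa=0.3105, origin_uk=0.1900, origin_china=-0.1938,
            rec_cdc=-0.0471, rec_who=-0.1401, rec_media=-0.4618,
        ),
        pi=(0.0024, 0.0030, -0.1628),
        delta_o=0.7983,
        sigma_o=0.0,
        gamma=(
            -0.6611, -0.0173, -0.1467, -0.6765, 0.0257, 0.3026, -0.0103,
            0.0797, -0.1631, -0.5356, -0.1394, -0.3394, 0.1989, -0.5164,
            1.7707, -0.2380, -0.0095, -0.3229, -0.4197,
        ),
        loglik=-18385.00,
        bic=37134.60,
    ),
    "rpl2": dict(
        beta=dict(
            free=0.5126, cost=-0.0030, effectiveness=0.0122, protection=0.0331,
            incubation=-0.0056, severe=-0.0029, mild=-0.0623, introduced=0.0459,
            origin_usa=0.4721, origin_uk=0.3350, origin_china=-0.1291,
            rec_cdc=-0.1476, rec_who=-0.3281, rec_media=-0.6660,
        ),
        pi=(0.0024, 0.0022, -0.2051),
        delta_o=0.3572,
        sigma_o=3.2693,
        gamma=(
            -1.4326, -0.0559, -0.3345, -1.5143, 0.0573, 0.7665, 0.0462,
            0.3339, -0.4938, -1.1516, -0.3637, -0.2049, 0.5111, -1.0262,
            4.1708, -0.4951, -0.0200, -0.6832, -0.9382,
        ),
        loglik=-15219.00,
        bic=30714.34,
    ),
}

# 3-class latent-class estimates; per class: beta dict, pi, delta_o.
_PUBLISHED_LCL = dict(
    expected_size=(0.2229, 0.2901, 0.4869),
    classes=(
        dict(
            beta=dict(
                free=0.6442, cost=-0.0032, effectiveness=0.0181, protection=0.1457,
                incubation=-0.0018, severe=-0.0063, mild=-0.0829, introduced=0.1063,
                origin_usa=0.6132, origin_uk=0.4724, origin_china=0.0906,
                rec_cdc=-0.5464, rec_who=-1.4917, rec_media=-0.6104,
            ),
            pi=(0.0045, 0.0073, -0.6470),
            delta_o=5.5959,
        ),
        dict(
            beta=dict(
                free=0.1848, cost=-0.0074, effectiveness=0.0217, protection=0.0587,
                incubation=-0.0173, severe=-0.0053, mild=-0.0761, introduced=0.0463,
                origin_usa=0.6284, origin_uk=0.2328, origin_china=-0.6744,
                rec_cdc=0.0455, rec_who=-0.1555, rec_media=-0.7302,
            ),
            pi=(0.0005, 0.0022, -0.3443),
            delta_o=1.6116,
        ),
        dict(
            beta=dict(
                free=0.6492, cost=-0.0011, effectiveness=0.0098, protection=0.0228,
                incubation=-0.0016, severe=-0.0020, mild=-0.0434, introduced=0.0504,
                origin_usa=0.2927, origin_uk=0.3436, origin_china=0.0478,
                rec_cdc=-0.1903, rec_who=-0.2911, rec_media=-0.5711,
            ),
            pi=(0.0025, 0.0013, -0.0612),
            delta_o=-2.8583,
        ),
    ),
    # membership coefficients, columns [const] + CLASS_COVARIATES,
    # rows: class 2 vs 1, class 3 vs 1
    membership=(
        (
            -0.3326, 0.5586, 0.0180, 0.1750, 0.4588, -0.0068, -0.0432,
            0.3971, -0.5129, 0.4294, 0.4021, 0.9076, -0.3106, 0.8060,
            -1.7113, 0.2735, 0.0045, 0.4914, 0.0959,
        ),
        (
            0.1184, 1.0934, 0.0398, 0.2049, 1.1254, -0.0408, -0.4359,
            0.0423, 0.1798, 0.8728, 0.3170, 0.9269, -0.2865, 0.9930,
            -2.4752, 0.3519, 0.0159, 0.6363, 0.6028,
        ),
    ),
    loglik=-15025.00,
    bic=30957.67,
)


def _params_from_raw(spec: ModelSpec, raw: dict, gamma_order=_GAMMA_ORDER) -> Parameters:
    beta = np.array([raw["beta"][c] for c in spec.base_columns()])
    gamma_map = dict(zip(gamma_order, raw["gamma"]))
    gamma = np.array([gamma_map[c] for c in spec.optout_covariates])
    return Parameters(
        beta=beta,
        pi=np.asarray(raw["pi"], float),
        delta_o=raw["delta_o"],
        gamma=gamma,
        sigma_o=raw.get("sigma_o", 0.0),
    )


def published_model(name: str):
    """Published parameter point for one model variant.

    ``name`` is one of ``cl1``, ``cl2``, ``rpl1``, ``rpl2`` (returning
    :class:`FixedParameters`) or ``lcl`` (returning
    :class:`PublishedLatentClass`).
    """
    name = name.lower()
    if name == "lcl":
        spec = named_spec("lcl")
        raw = _PUBLISHED_LCL
        class_params = [
            Parameters(
                beta=np.array([c["beta"][col] for col in spec.base_columns()]),
                pi=np.asarray(c["pi"], float),
                delta_o=c["delta_o"],
                gamma=np.zeros(0),
            )
            for c in raw["classes"]
        ]
        return PublishedLatentClass(
            spec=spec,
            class_params=class_params,
            membership=np.asarray(raw["membership"], float),
            expected_size=raw["expected_size"],
        )
    if name not in _PUBLISHED_RAW:
        raise KeyError(f"no published estimates for {name!r}")
    spec = named_spec(name)
    return FixedParameters(spec, _params_from_raw(spec, _PUBLISHED_RAW[name]))


def published_fit_statistics(name: str) -> dict:
    """Published log-likelihood and BIC for a model variant (as printed)."""
    src = _PUBLISHED_LCL if name.lower() == "lcl" else _PUBLISHED_RAW[name.lower()]
    return {"loglik": src["loglik"], "bic": src["bic"]}
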