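"""Small test utilities shared across modules."""

import numpy as np

import vaxchoice as vx
from vaxchoice.synthetic import DEFAULT_LEVELS
from vaxchoice.types import VaccineProfile


def random_profile(rng):
    """One random profile drawn from the study attribute levels."""
    return VaccineProfile(
        cost=float(rng.choice(DEFAULT_LEVELS["cost"])),
        effectiveness=float(rng.choice(DEFAULT_LEVELS["effectiveness"])),
        incubation_days=float(rng.choice(DEFAULT_LEVELS["incubation"])),
        protection_months=float(rng.choice(DEFAULT_LEVELS["protection"])),
        mild_per10=float(rng.choice(DEFAULT_LEVELS["mild"])),
        severe_per1e6=float(rng.choice(DEFAULT_LEVELS["severe"])),
        recommender=str(rng.choice(DEFAULT_LEVELS["recommender"])),
        origin=str(rng.choice(DEFAULT_LEVELS["origin"])),
        introduced_months=float(rng.choice(DEFAULT_LEVELS["introduced"])),
    )


def random_parameters(rng, spec, sigma_o=0.0):
    """A moderate random parameter point aligned with ``spec``."""
    return vx.Parameters(
        beta=rng.normal(0, 0.05, spec.n_beta),
        pi=rng.normal(0, 0.02, spec.n_pi),
        delta_o=float(rng.normal(0, 0.5)),
        gamma=rng.normal(0, 0.1, len(spec.optout_covariates)),
        sigma_o=sigma_o,
    )
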