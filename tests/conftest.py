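"""Shared fixtures: small simulated panels and published parameter points."""

import numpy as np
import pytest

import vaxchoice as vx
from vaxchoice.synthetic import DEFAULT_LEVELS
from vaxchoice.types import VaccineProfile


@pytest.fixture(scope="session")
def cards():
    return vx.generate_design(vx.DesignConfig(seed=101))


@pytest.fixture(scope="session")
def pop300():
    return vx.sample_population(vx.PopulationConfig(n_respondents=300, seed=102))


@pytest.fixture(scope="session")
def cl1_pub():
    return vx.published_model("cl1")


@pytest.fixture(scope="session")
def cl2_pub():
    return vx.published_model("cl2")


@pytest.fixture(scope="session")
def rpl1_pub():
    return vx.published_model("rpl1")


@pytest.fixture(scope="session")
def rpl2_pub():
    return vx.published_model("rpl2")


@pytest.fixture(scope="session")
def lcl_pub():
    return vx.published_model("lcl")


@pytest.fixture(scope="session")
def cl_data_small(cards, pop300, cl1_pub):
    """300-respondent panel simulated from the cl1 point (fixed constant)."""
    return vx.simulate_choices(cards, pop300, cl1_pub.parameters, cl1_pub.spec, seed=103)


@pytest.fixture(scope="session")
def rpl_data_small(cards, pop300, rpl2_pub):
    """300-respondent panel simulated from the rpl2 point (random constant)."""
    return vx.simulate_choices(
        cards, pop300, rpl2_pub.parameters, rpl2_pub.spec, seed=104
    )


@pytest.fixture(scope="session")
def base_profile():
    return VaccineProfile(
        cost=0.0,
        effectiveness=95.0,
        incubation_days=21.0,
        protection_months=12.0,
        mild_per10=4.0,
        severe_per1e6=10.0,
        recommender="PCP",
        origin="Germany",
        introduced_months=6.0,
    )
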