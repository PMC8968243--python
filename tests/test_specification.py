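"""Design-vector encoding and choice-probability kernel."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vaxchoice as vx
from vaxchoice.spec import (
    BASE_ATTRIBUTE_COLUMNS,
    OPTOUT_COVARIATES,
    ModelSpec,
    Parameters,
    choice_probabilities,
    encode_optout,
    encode_vaccine,
    named_spec,
    task_utilities,
)
from vaxchoice.types import ChoiceTask, Respondent, VaccineProfile

from helpers import random_parameters, random_profile


def _col(spec, name):
    return spec.attribute_columns().index(name)


class TestVaccineEncoding:
    def test_base_levels_encode_to_zero_dummies(self, base_profile):
        """Germany origin and PCP recommender are the omitted base levels."""
        spec = named_spec("cl2")
        r = Respondent(id=1)
        x = encode_vaccine(base_profile, r, spec)
        cols = spec.attribute_columns()
        for dummy in ("origin_usa", "origin_uk", "origin_china",
                      "rec_cdc", "rec_who", "rec_media"):
            assert x[cols.index(dummy)] == 0.0
        # free vaccine: cost 0 sets the indicator
        assert x[cols.index("free")] == 1.0
        assert x[cols.index("cost")] == 0.0
        assert x[cols.index("effectiveness")] == 95.0

    def test_linear_cost_mode_has_no_free_column(self, base_profile):
        spec = named_spec("cl1")
        assert "free" not in spec.attribute_columns()
        x = encode_vaccine(base_profile, Respondent(id=1), spec)
        assert x.size == len(spec.attribute_columns())

    def test_china_origin_interacts_with_republican(self, base_profile):
        from dataclasses import replace

        spec = named_spec("cl1")
        prof = replace(base_profile, origin="China")
        rep = Respondent(id=1, republican=1)
        dem = Respondent(id=2, democrat=1)
        x_rep = encode_vaccine(prof, rep, spec)
        x_dem = encode_vaccine(prof, dem, spec)
        assert x_rep[_col(spec, "origin_china")] == 1.0
        assert x_rep[_col(spec, "origin_china:republican")] == 1.0
        assert x_dem[_col(spec, "origin_china:republican")] == 0.0

    def test_cost_interacts_with_high_income_threshold(self, base_profile):
        """High income is household income at or above $120,000."""
        from dataclasses import replace

        spec = named_spec("cl1")
        prof = replace(base_profile, cost=175.0)
        rich = Respondent(id=1, household_income=120_000.0)
        poor = Respondent(id=2, household_income=119_999.0)
        assert encode_vaccine(prof, rich, spec)[_col(spec, "cost:high_income")] == 175.0
        assert encode_vaccine(prof, poor, spec)[_col(spec, "cost:high_income")] == 0.0

    def test_effectiveness_interacts_with_wave(self, base_profile):
        spec = named_spec("cl1")
        w2 = Respondent(id=1, wave2=1)
        w1 = Respondent(id=2, wave2=0)
        assert encode_vaccine(base_profile, w2, spec)[
            _col(spec, "effectiveness:wave2")
        ] == 95.0
        assert encode_vaccine(base_profile, w1, spec)[
            _col(spec, "effectiveness:wave2")
        ] == 0.0

    def test_column_order_is_stable(self):
        spec = named_spec("cl2")
        assert spec.attribute_columns()[: 1 + len(BASE_ATTRIBUTE_COLUMNS)] == (
            ("free",) + BASE_ATTRIBUTE_COLUMNS
        )
        assert spec.attribute_columns()[-3:] == (
            "cost:high_income",
            "effectiveness:wave2",
            "origin_china:republican",
        )

    def test_unknown_enum_level_rejected_with_field_name(self, base_profile):
        from dataclasses import replace

        with pytest.raises(ValueError, match="origin"):
            replace(base_profile, origin="France")
        with pytest.raises(ValueError, match="recommender"):
            replace(base_profile, recommender="Twitter")


class TestOptoutEncoding:
    def test_income_entered_in_ten_thousands(self):
        spec = named_spec("cl1")
        r = Respondent(id=1, household_income=120_000.0)
        w = encode_optout(r, spec)
        assert w[OPTOUT_COVARIATES.index("household_income_10k")] == pytest.approx(12.0)

    def test_binary_covariates_form_unit_coordinates(self):
        spec = ModelSpec(optout_covariates=("male", "against_vaccination", "flu_shot"))
        r = Respondent(id=1, against_vaccination=1)
        assert np.array_equal(encode_optout(r, spec), [0.0, 1.0, 0.0])

    def test_all_zero_flags_encode_to_zero_vector(self):
        spec = ModelSpec(optout_covariates=("male", "black", "democrat", "had_covid"))
        r = Respondent(id=1)
        assert np.array_equal(encode_optout(r, spec), np.zeros(4))

    def test_unknown_covariate_rejected_by_name(self):
        with pytest.raises(KeyError, match="astrology_sign"):
            ModelSpec(optout_covariates=("male", "astrology_sign"))
        with pytest.raises(KeyError, match="astrology_sign"):
            ModelSpec(interactions=(("cost", "astrology_sign"),))

    def test_unknown_interaction_attribute_rejected(self):
        with pytest.raises(ValueError, match="halo_effect"):
            ModelSpec(interactions=(("halo_effect", "male"),))


class TestChoiceProbabilities:
    def _task(self, rng):
        a, b = random_profile(rng), random_profile(rng)
        return ChoiceTask(respondent_id=0, task_index=1, alternative_A=a,
                          alternative_B=b, chosen="A")

    def test_zero_parameters_give_uniform_thirds(self, base_profile):
        spec = named_spec("cl1")
        params = Parameters(beta=np.zeros(spec.n_beta), pi=np.zeros(spec.n_pi),
                            delta_o=0.0, gamma=np.zeros(len(spec.optout_covariates)))
        task = ChoiceTask(0, 1, base_profile, base_profile, "optout")
        p = choice_probabilities(params, task, Respondent(id=0), spec)
        assert np.allclose(p, 1 / 3)

    def test_matches_bruteforce_softmax(self):
        """Probabilities equal exp(u)/sum(exp(u)) computed independently."""
        rng = np.random.default_rng(7)
        spec = named_spec("cl2")
        r = Respondent(id=0, male=1, household_income=150_000.0, wave2=1,
                       republican=1, bmi=28.0, age=50.0)
        for _ in range(25):
            params = random_parameters(rng, spec)
            task = self._task(rng)
            u = np.array([
                encode_vaccine(task.alternative_A, r, spec) @ params.utility,
                encode_vaccine(task.alternative_B, r, spec) @ params.utility,
                params.delta_o + encode_optout(r, spec) @ params.gamma,
            ])
            expected = np.exp(u) / np.exp(u).sum()
            got = choice_probabilities(params, task, r, spec)
            assert np.allclose(got, expected, atol=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        scale=st.floats(0.0, 5.0),
        delta=st.floats(-20.0, 20.0),
    )
    def test_probabilities_positive_and_normalized(self, seed, scale, delta):
        rng = np.random.default_rng(seed)
        spec = named_spec("cl1")
        params = Parameters(
            beta=rng.normal(0, 0.02 * (1 + scale), spec.n_beta),
            pi=rng.normal(0, 0.01, spec.n_pi),
            delta_o=delta,
            gamma=rng.normal(0, 0.1, len(spec.optout_covariates)),
        )
        task = self._task(rng)
        p = choice_probabilities(params, task, Respondent(id=0, age=40.0), spec)
        assert np.all(p > 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_swapping_alternatives_permutes_probabilities(self):
        rng = np.random.default_rng(11)
        spec = named_spec("cl1")
        params = random_parameters(rng, spec)
        r = Respondent(id=0, male=1)
        a, b = random_profile(rng), random_profile(rng)
        t1 = ChoiceTask(0, 1, a, b, "A")
        t2 = ChoiceTask(0, 1, b, a, "A")
        p1 = choice_probabilities(params, t1, r, spec)
        p2 = choice_probabilities(params, t2, r, spec)
        assert p1[0] == pytest.approx(p2[1], abs=1e-14)
        assert p1[1] == pytest.approx(p2[0], abs=1e-14)
        assert p1[2] == pytest.approx(p2[2], abs=1e-14)

    def test_identical_alternatives_are_equiprobable(self, base_profile):
        rng = np.random.default_rng(13)
        spec = named_spec("cl2")
        params = random_parameters(rng, spec)
        task = ChoiceTask(0, 1, base_profile, base_profile, "A")
        p = choice_probabilities(params, task, Respondent(id=0), spec)
        assert p[0] == pytest.approx(p[1], abs=1e-14)

    def test_extreme_utilities_do_not_overflow(self, base_profile):
        spec = named_spec("cl1")
        params = Parameters(beta=np.full(spec.n_beta, 50.0), pi=np.zeros(spec.n_pi),
                            delta_o=-500.0, gamma=np.zeros(len(spec.optout_covariates)))
        task = ChoiceTask(0, 1, base_profile, base_profile, "A")
        p = choice_probabilities(params, task, Respondent(id=0), spec)
        assert np.all(np.isfinite(p))
        assert p.sum() == pytest.approx(1.0)

    def test_realized_constant_overrides_mean(self, base_profile):
        rng = np.random.default_rng(17)
        spec = named_spec("cl1")
        params = random_parameters(rng, spec, sigma_o=2.0)
        task = ChoiceTask(0, 1, base_profile, base_profile, "A")
        r = Respondent(id=0)
        hi = choice_probabilities(params, task, r, spec, delta_i=4.0)
        lo = choice_probabilities(params, task, r, spec, delta_i=-4.0)
        assert hi[2] > lo[2]


class TestSpecSerialization:
    def test_yaml_round_trip(self, tmp_path):
        spec = named_spec("rpl2")
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        assert ModelSpec.from_yaml(path) == spec

    def test_dict_round_trip_all_variants(self):
        for name in ("cl1", "cl2", "rpl1", "rpl2", "lcl"):
            spec = named_spec(name)
            assert ModelSpec.from_dict(spec.to_dict()) == spec

    def test_parameters_dict_round_trip(self):
        rng = np.random.default_rng(19)
        spec = named_spec("rpl1")
        params = random_parameters(rng, spec, sigma_o=1.5)
        back = Parameters.from_dict(spec, params.to_dict(spec))
        assert np.allclose(back.utility, params.utility)
        assert np.allclose(back.gamma, params.gamma)
        assert back.delta_o == params.delta_o
        assert back.sigma_o == params.sigma_o

    def test_parameter_block_length_mismatch_named(self):
        spec = named_spec("cl1")
        bad = Parameters(beta=np.zeros(spec.n_beta - 1), pi=np.zeros(spec.n_pi),
                         delta_o=0.0, gamma=np.zeros(len(spec.optout_covariates)))
        with pytest.raises(ValueError, match="beta block"):
            bad.validate(spec)

    def test_unknown_variant_name_rejected(self):
        with pytest.raises(KeyError, match="unknown model variant"):
            named_spec("probit")

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma_o"):
            Parameters(beta=np.zeros(1), pi=np.zeros(0), delta_o=0.0,
                       gamma=np.zeros(0), sigma_o=-1.0)
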