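"""Survey domain types, categorical-answer samplers and file round-trips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pacem.survey import (
    AmountSpec,
    FrequencySpec,
    Person,
    SurveyValidationError,
    amount_interval_to_sampler,
    frequency_interval_to_sampler,
    prepare_diary,
    read_survey,
    weekly_frequency_to_daily_prob,
    write_survey,
)
from pacem.synthetic import SyntheticSurveyConfig, generate_survey

from .conftest import make_person, make_use


class TestIntervalSamplers:
    def test_draws_stay_inside_interval(self, rng):
        sampler = frequency_interval_to_sampler([1.0, 2.0])
        draws = sampler(rng, 100_000)
        assert draws.min() >= 1.0 and draws.max() <= 2.0

    def test_degenerate_interval_is_point(self, rng):
        sampler = frequency_interval_to_sampler([3.0, 3.0])
        assert sampler(rng) == 3.0
        assert np.all(sampler(rng, 10) == 3.0)

    def test_uniform_mean(self, rng):
        # Uniform(0,1): mean 0.5, SE = sqrt(1/12)/sqrt(n)
        n = 100_000
        draws = frequency_interval_to_sampler([0.0, 1.0])(rng, n)
        se = np.sqrt(1.0 / 12.0 / n)
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_amount_uniform_variance(self, rng):
        n = 100_000
        draws = amount_interval_to_sampler([2.0, 6.0])(rng, n)
        assert np.isclose(draws.var(), (6.0 - 2.0) ** 2 / 12.0, rtol=0.05)

    def test_zero_amount_interval(self, rng):
        assert amount_interval_to_sampler([0.0, 0.0])(rng) == 0.0

    @pytest.mark.parametrize("bad", [[-1.0, 2.0], [3.0, 1.0]])
    def test_invalid_intervals_rejected(self, bad):
        with pytest.raises(SurveyValidationError):
            frequency_interval_to_sampler(bad)
        with pytest.raises(SurveyValidationError):
            amount_interval_to_sampler(bad)


class TestDailyProbability:
    @pytest.mark.parametrize(
        "f,p", [(7.0, 1.0), (0.0, 0.0), (3.5, 0.5), (14.0, 1.0), (1.0, 1.0 / 7.0)]
    )
    def test_values(self, f, p):
        assert weekly_frequency_to_daily_prob(f) == pytest.approx(p)

    def test_negative_frequency_rejected(self):
        with pytest.raises(SurveyValidationError):
            weekly_frequency_to_daily_prob(-0.1)


class TestPrepareDiary:
    def test_fourteen_day_identity(self):
        raw = list(range(14))
        assert prepare_diary(raw).tolist() == raw

    def test_seven_day_tiling_doubles_use_days(self):
        raw = [1, 0, 1, 1, 0, 0, 1]
        out = prepare_diary(raw)
        assert out.tolist() == raw + raw
        assert out.sum() == 2 * sum(raw)

    def test_all_false_week(self):
        assert prepare_diary([0] * 7).sum() == 0

    @pytest.mark.parametrize("n", [0, 6, 10, 15])
    def test_bad_lengths_rejected(self, n):
        with pytest.raises(SurveyValidationError):
            prepare_diary([1] * n)

    @given(st.lists(st.integers(min_value=0, max_value=3), min_size=7, max_size=7))
    def test_weekly_count_conserved(self, week):
        out = prepare_diary(week)
        assert out[:7].tolist() == week and out[7:].tolist() == week


class TestValidation:
    def test_unknown_sex_rejected(self):
        with pytest.raises(SurveyValidationError):
            Person("p1", "other", "NL", 70.0, "dutch_pcp")

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(SurveyValidationError):
            Person("p1", "male", "NL", 0.0, "dutch_pcp")

    def test_negative_fixed_amount_rejected(self):
        with pytest.raises(SurveyValidationError):
            AmountSpec.from_fixed(-1.0)

    def test_diary_must_be_14_days(self):
        with pytest.raises(SurveyValidationError):
            FrequencySpec(mode="diary", diary=(1, 0, 1))


class TestRoundTrip:
    @pytest.mark.parametrize("ext", ["csv", "json"])
    def test_write_read_lossless(self, tmp_path, ext):
        survey = generate_survey(
            SyntheticSurveyConfig(survey_kind="dutch_pcp", n_persons=50, seed=9)
        )
        path = tmp_path / f"s.{ext}"
        write_survey(survey, path)
        back = read_survey(path)
        assert back.persons == survey.persons
        assert back.uses == survey.uses
        assert back.product_catalog == survey.product_catalog
        # second round trip is byte-identical
        path2 = tmp_path / f"s2.{ext}"
        write_survey(back, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_diary_survey_round_trip(self, tmp_path):
        survey = generate_survey(
            SyntheticSurveyConfig(survey_kind="eu_pcp", n_persons=20, seed=9)
        )
        path = tmp_path / "eu.csv"
        write_survey(survey, path)
        assert read_survey(path).uses == survey.uses

    def test_minimal_one_person_file(self, tmp_path):
        from pacem.survey import Survey

        survey = Survey(
            name="mini",
            persons=[make_person()],
            uses={"p1": [make_use()]},
            product_catalog={"prod": ("PCP", None)},
        )
        path = tmp_path / "mini.csv"
        write_survey(survey, path)
        back = read_survey(path)
        assert len(back.persons) == 1 and back.person_uses("p1") == survey.uses["p1"]

    def test_unknown_sex_token_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        good = make_person()
        from pacem.survey import Survey

        write_survey(
            Survey("x", [good], {"p1": [make_use()]}, {"prod": ("PCP", None)}), path
        )
        text = path.read_text().replace("female", "unknown_sex")
        path.write_text(text)
        with pytest.raises(SurveyValidationError, match="row 2"):
            read_survey(path)
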