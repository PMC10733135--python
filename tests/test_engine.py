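"""Person-oriented simulation: day realisation, replicate sampling, random
pairing, survey merging and the end-to-end model."""

import numpy as np
import pytest
from scipy import stats

from pacem.concentration import ConcentrationSpec, Distribution
from pacem.engine import (
    AggregateExposureModel,
    ConfigurationError,
    ExposureConfig,
    ProductParams,
    aggregate_daily,
    merge_surveys,
    run_assessment,
    simulate_person_product,
    simulate_use_days,
    summarize_person,
    tier1_additive,
)
from pacem.survey import Survey

from .conftest import make_person, make_use, point_params, single_product_config


class TestUseDays:
    def test_daily_use(self, rng):
        days = simulate_use_days(make_use(freq=(7.0, 7.0)), rng)
        assert days.tolist() == [1] * 14

    def test_never_used(self, rng):
        days = simulate_use_days(make_use(freq=(0.0, 0.0)), rng)
        assert days.sum() == 0

    def test_diary_copied_verbatim(self, rng):
        from pacem.survey import AmountSpec, FrequencySpec, ProductUse

        diary = (1, 0, 1, 0, 0, 0, 1, 1, 0, 1, 0, 0, 0, 1)
        use = ProductUse(
            "p", "PCP", FrequencySpec(mode="diary", diary=diary),
            AmountSpec.from_fixed(1.0), frozenset({"hands"}),
        )
        assert simulate_use_days(use, rng).tolist() == list(diary)

    def test_binomial_mean_at_half_saturation(self, rng):
        # f = 3.5/week -> p = 0.5 -> mean use days = 7 over 14
        use = make_use(freq=(3.5, 3.5))
        n = 10_000
        total = sum(simulate_use_days(use, rng).sum() for _ in range(n))
        mean = total / n
        se = np.sqrt(14 * 0.25 / n)
        assert abs(mean - 7.0) < 3 * se


class TestPersonProduct:
    def test_zero_occurrence_all_zero(self, rng):
        cfg = single_product_config(occurrence=0.0, n_product=8)
        person = make_person()
        out = simulate_person_product(
            person, make_use("cream"), cfg.product_params["cream"], cfg, rng
        )
        assert all(np.all(v == 0) for v in out.values())

    def test_deterministic_config_constant_rows(self, rng):
        cfg = single_product_config(conc=1e-3, n_product=3)
        out = simulate_person_product(
            make_person(), make_use("cream", freq=(7, 7), amount=1.0),
            cfg.product_params["cream"], cfg, rng,
        )["hands"]
        expected = 1.0 * 1e6 * 1e-3 * 1.0 / 1000.0
        assert out.shape == (3, 14)
        assert np.all(out == expected)

    def test_occurrence_at_replicate_level(self, rng):
        # with a point distribution, the fraction of all-zero replicate rows
        # estimates 1 - occurrence
        n = 10_000
        cfg = single_product_config(occurrence=0.5, n_product=n)
        out = simulate_person_product(
            make_person(), make_use("cream"), cfg.product_params["cream"], cfg, rng
        )["hands"]
        frac_zero = (out == 0).all(axis=1).mean()
        se = np.sqrt(0.25 / n)
        assert abs(frac_zero - 0.5) < 3 * se

    def test_concentration_fixed_within_replicate(self, rng):
        cfg = ExposureConfig(
            metric="systemic",
            product_params={
                "prod": ProductParams(
                    concentration=ConcentrationSpec(1.0, Distribution.uniform(1e-4, 1e-3)),
                    exposure_fractions={"dermal": 1.0},
                )
            },
            routes=("dermal",),
            absorption_fractions={"dermal": 1.0},
            n_product=50,
            product_groups=("PCP",),
        )
        out = simulate_person_product(
            make_person(), make_use("prod", freq=(7, 7), amount=2.0),
            cfg.product_params["prod"], cfg, rng,
        )
        # constant daily amount and fixed concentration -> each row constant,
        # rows differ across replicates
        assert np.allclose(out, out[:, :1])
        assert len(np.unique(out[:, 0])) > 1

    def test_missing_retention_names_product(self, rng):
        cfg = single_product_config()
        params = ProductParams(concentration=cfg.product_params["cream"].concentration)
        with pytest.raises(ConfigurationError, match="cream"):
            simulate_person_product(make_person(), make_use("cream"), params, cfg, rng)


class TestAggregateDaily:
    def test_single_product_identity_up_to_permutation(self, rng):
        mat = rng.random((10, 14))
        agg = aggregate_daily([mat], rng, metric="systemic")
        assert np.allclose(np.sort(agg, axis=0), np.sort(mat, axis=0))

    def test_deterministic_products_sum(self, rng):
        m1 = np.full((6, 14), 0.25)
        m2 = np.full((6, 14), 1.5)
        agg = aggregate_daily([m1, m2], rng, metric="systemic")
        assert np.all(agg == 1.75)

    def test_pairing_independence_binomial(self, rng):
        # two products each Bernoulli(0.5)-valued: the paired sum should be
        # Binomial(2, 0.5) by chi-square
        n = 10_000
        mats = [(rng.random((n, 1)) < 0.5).astype(float) for _ in range(2)]
        agg = aggregate_daily(mats, rng, metric="systemic").ravel()
        counts = np.array([(agg == k).sum() for k in (0, 1, 2)])
        expected = n * np.array([0.25, 0.5, 0.25])
        assert stats.chisquare(counts, expected).pvalue > 0.01

    def test_dermal_sums_within_part_before_max(self, rng):
        ones = np.ones((4, 14))
        p1 = {"hands": ones * 0.15}
        p2 = {"hands": ones * 0.05, "arms": ones * 0.18}
        agg = aggregate_daily([p1, p2], rng, metric="dermal_load")
        assert np.all(agg == 0.20)  # hands total beats arms

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            aggregate_daily([np.ones((3, 14)), np.ones((4, 14))], rng)


class TestSummaries:
    def test_constant_row(self):
        s = summarize_person(np.full((2, 14), 3.0))
        assert np.all(s["average_daily"] == 3.0)
        assert np.all(s["highest_daily"] == 3.0)

    def test_single_spike_day(self):
        mat = np.zeros((1, 14))
        mat[0, 4] = 7.0
        s = summarize_person(mat)
        assert s["average_daily"][0] == pytest.approx(0.5)
        assert s["highest_daily"][0] == 7.0

    def test_highest_at_least_average(self, rng):
        s = summarize_person(rng.random((100, 14)))
        assert np.all(s["highest_daily"] >= s["average_daily"])


class TestMergeSurveys:
    def _surveys(self, hcp_cell_size=1):
        pcp_persons = [make_person("a", "female", "NL"), make_person("b", "male", "NL")]
        pcp = Survey(
            "pcp", pcp_persons,
            {"a": [make_use("cream")], "b": [make_use("cream")]},
            {"cream": ("PCP", None)},
        )
        hcp_persons, uses = [], {}
        for i in range(hcp_cell_size):
            for sex in ("female", "male"):
                pid = f"h{sex}{i}"
                hcp_persons.append(make_person(pid, sex, "NL", source="eu_hcp"))
                uses[pid] = [make_use(f"cleaner{i}", group="HCP")]
        hcp = Survey(
            "hcp", hcp_persons, uses,
            {f"cleaner{i}": ("HCP", "liquid") for i in range(hcp_cell_size)},
        )
        return pcp, hcp

    def test_single_candidate_deterministic(self, rng):
        pcp, hcp = self._surveys(1)
        merged = merge_surveys(pcp, hcp, rng)
        assert len(merged.persons) == len(pcp.persons)
        groups = {u.product_group for u in merged.person_uses("a")}
        assert groups == {"PCP", "HCP"}

    def test_pcp_demographics_retained(self, rng):
        pcp, hcp = self._surveys(2)
        merged = merge_surveys(pcp, hcp, rng)
        assert merged.persons == pcp.persons

    def test_uncovered_cell_reported(self, rng):
        pcp, hcp = self._surveys(1)
        pcp.persons.append(make_person("c", "male", "DE"))
        with pytest.raises(ConfigurationError, match="DE"):
            merge_surveys(pcp, hcp, rng)

    def test_uniform_donor_choice(self, rng):
        pcp, hcp = self._surveys(4)
        chosen = {f"cleaner{i}": 0 for i in range(4)}
        for _ in range(10_000):
            merged = merge_surveys(pcp, hcp, rng)
            pid = next(
                u.product_id for u in merged.person_uses("a")
                if u.product_group == "HCP"
            )
            chosen[pid] += 1
        counts = np.array(list(chosen.values()))
        assert stats.chisquare(counts).pvalue > 0.001


class TestRunAssessment:
    def test_closed_form_degenerate_run(self, tiny_survey):
        # occurrence 1, point conc, fixed amount, daily use: every dermal
        # load value equals a * 1e6 * c * r / S exactly
        a, c, r, S = 1.0, 1e-3, 0.5, 1000.0
        cfg = single_product_config(conc=c, retention=r, area=S, n_product=4)
        result = run_assessment(cfg, pcp_survey=tiny_survey)
        expected = a * 1e6 * c * r / S
        assert np.all(result.daily["Total"] == expected)
        s = result.summaries("Total")
        assert np.all(s["average"] == expected) and np.all(s["highest"] == expected)
        assert np.percentile(result.values("Total", "highest"), 95) == expected

    def test_seed_reproducibility(self, tiny_survey):
        cfg = single_product_config(occurrence=0.6, seed=11)
        r1 = run_assessment(cfg, pcp_survey=tiny_survey)
        r2 = run_assessment(cfg, pcp_survey=tiny_survey)
        assert np.array_equal(r1.daily["Total"], r2.daily["Total"])

    def test_adding_product_does_not_perturb_existing_draws(self, tiny_survey):
        cfg1 = single_product_config(occurrence=0.5, seed=3)
        survey2 = Survey(
            "tiny2", tiny_survey.persons,
            {p.person_id: tiny_survey.person_uses(p.person_id)
             + [make_use("soap", body_parts=("hands",))]
             for p in tiny_survey.persons},
            {"cream": ("PCP", None), "soap": ("PCP", None)},
        )
        cfg2 = single_product_config(occurrence=0.5, seed=3)
        cfg2.product_params["soap"] = point_params(2e-3, 0.5)
        r1 = run_assessment(cfg1, pcp_survey=tiny_survey)
        r2 = run_assessment(cfg2, pcp_survey=survey2)
        assert "soap" in r2.product_values
        assert np.array_equal(
            r1.product_values["cream"]["highest"], r2.product_values["cream"]["highest"]
        )

    def test_mixed_pcp_sources_rejected(self, tiny_survey):
        persons = list(tiny_survey.persons) + [
            make_person("eu1", "male", "DE", source="eu_pcp")
        ]
        mixed = Survey("mixed", persons, dict(tiny_survey.uses),
                       dict(tiny_survey.product_catalog))
        with pytest.raises(ConfigurationError, match="cannot be combined"):
            AggregateExposureModel(single_product_config(), pcp_survey=mixed)

    def test_country_survey_consistency(self, tiny_survey):
        cfg = single_product_config(country="NL")
        AggregateExposureModel(cfg, pcp_survey=tiny_survey)  # ok
        eu = Survey(
            "eu",
            [make_person("e1", "male", "DE", source="eu_pcp")],
            {"e1": [make_use("cream")]},
            {"cream": ("PCP", None)},
        )
        with pytest.raises(ConfigurationError, match="Dutch"):
            AggregateExposureModel(cfg, pcp_survey=eu)

    def test_systemic_total_is_pcp_plus_hcp_pointwise(self):
        persons = [make_person("a", "female", "NL"), make_person("b", "male", "NL")]
        pcp = Survey("pcp", persons,
                     {"a": [make_use("cream", freq=(3, 5))],
                      "b": [make_use("cream", freq=(3, 5))]},
                     {"cream": ("PCP", None)})
        hpersons = [make_person("hf", "female", "NL", source="eu_hcp"),
                    make_person("hm", "male", "NL", source="eu_hcp")]
        hcp = Survey("hcp", hpersons,
                     {p.person_id: [make_use("cleaner", group="HCP", freq=(2, 6))]
                      for p in hpersons},
                     {"cleaner": ("HCP", "liquid")})
        ef = {"dermal": 0.5}
        cfg = ExposureConfig(
            metric="systemic",
            product_params={
                "cream": point_params(1e-3, 0.8, ef=ef),
                "cleaner": point_params(2e-3, 0.6, ef=ef),
            },
            routes=("dermal",),
            absorption_fractions={"dermal": 0.9},
            n_product=20,
            seed=5,
        )
        result = run_assessment(cfg, pcp_survey=pcp, hcp_survey=hcp)
        assert np.array_equal(
            result.daily["Total"], result.daily["PCP"] + result.daily["HCP"]
        )


class TestTier1:
    def test_single_product_equals_percentile(self, tiny_survey):
        cfg = single_product_config(occurrence=0.5, seed=2, n_product=50)
        result = run_assessment(cfg, pcp_survey=tiny_survey)
        vals = result.product_values["cream"]["highest"].ravel()
        assert tier1_additive(result, 95) == pytest.approx(np.percentile(vals, 95))

    def test_deterministic_products_add(self, tiny_survey):
        survey = Survey(
            "two", tiny_survey.persons,
            {p.person_id: [make_use("cream"), make_use("soap")]
             for p in tiny_survey.persons},
            {"cream": ("PCP", None), "soap": ("PCP", None)},
        )
        cfg = single_product_config(conc=1e-3, n_product=4)
        cfg.product_params["soap"] = point_params(2e-3)
        result = run_assessment(cfg, pcp_survey=survey)
        e1 = 1e6 * 1e-3 / 1000.0
        e2 = 1e6 * 2e-3 / 1000.0
        assert tier1_additive(result, 50) == pytest.approx(e1 + e2)
        # tier-1 dominates the aggregate percentile for any level
        agg = np.percentile(result.values("Total", "highest"), 95)
        assert tier1_additive(result, 95) >= agg - 1e-12
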