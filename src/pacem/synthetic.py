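"""Seeded generation of synthetic product-usage surveys.

The real usage surveys behind person-oriented aggregate exposure
assessments (a Dutch personal-care survey of 516 adults and 32 products, a
multi-country European PCP diary survey of 21 products, and a European
household-cleaning survey of 5 product types in several forms) are not
publicly distributable.  This module generates synthetic surveys with the
same statistical *structure* — categorical frequency/amount answers or
14-day diaries, per-product ownership, application body parts, sex and
nationality strata — so that every downstream stage can be exercised and
tested without the confidential data.  No attempt is made to match the
real surveys' marginal distributions.

Person-level co-use is induced by a latent "usage propensity" per person
that shifts the log-odds of owning each product: heavy users own many
products at once.  This correlation is what distinguishes person-oriented
aggregation from independently combining products, so the generator must
produce it for that contrast to be visible in the outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .survey import (
    COUNTRIES,
    DEFAULT_FREQUENCY_CATEGORIES,
    N_SIM_DAYS,
    AmountSpec,
    FrequencySpec,
    Person,
    ProductUse,
    Survey,
    SurveyValidationError,
    weekly_frequency_to_daily_prob,
)

__all__ = [
    "ProductDef",
    "SyntheticSurveyConfig",
    "default_catalog",
    "generate_survey",
    "generate_concentration_data",
]


@dataclass(frozen=True)
class ProductDef:
    """Catalog entry for one product in a synthetic survey."""

    product_id: str
    product_group: str  # PCP | HCP
    body_parts: tuple[str, ...]
    rinse_class: str = "leave_on"  # leave_on | rinse_off | hcp_hand_contact
    product_form: str | None = None
    ownership_prob: float = 0.5
    amount_scale_g: float = 1.0  # typical grams per event


# 32 generic personal care products: (id, body parts, rinse class,
# ownership, typical g/event).  Names are generic product types.
_DUTCH_PCP_PRODUCTS: list[tuple[str, tuple[str, ...], str, float, float]] = [
    ("shampoo", ("head",), "rinse_off", 0.95, 8.0),
    ("conditioner", ("head",), "rinse_off", 0.55, 8.0),
    ("shower_gel", ("trunk", "arms", "legs"), "rinse_off", 0.90, 8.0),
    ("bath_foam", ("trunk", "arms", "legs"), "rinse_off", 0.25, 15.0),
    ("hand_soap", ("hands",), "rinse_off", 0.90, 1.5),
    ("face_cleanser", ("head",), "rinse_off", 0.40, 2.0),
    ("face_scrub", ("head",), "rinse_off", 0.20, 2.0),
    ("shaving_cream", ("head",), "rinse_off", 0.35, 2.5),
    ("aftershave", ("head",), "leave_on", 0.30, 1.0),
    ("toothpaste", ("head",), "rinse_off", 0.98, 1.4),
    ("mouthwash", ("head",), "rinse_off", 0.30, 10.0),
    ("day_cream", ("head",), "leave_on", 0.55, 1.2),
    ("night_cream", ("head",), "leave_on", 0.35, 1.2),
    ("anti_wrinkle_cream", ("head",), "leave_on", 0.20, 1.0),
    ("eye_cream", ("head",), "leave_on", 0.15, 0.3),
    ("body_lotion", ("trunk", "arms", "legs"), "leave_on", 0.55, 7.0),
    ("hand_cream", ("hands",), "leave_on", 0.45, 1.0),
    ("foot_cream", ("feet",), "leave_on", 0.15, 1.5),
    ("sunscreen", ("head", "arms", "legs", "trunk"), "leave_on", 0.45, 8.0),
    ("deodorant_roller", ("trunk",), "leave_on", 0.55, 0.5),
    ("deodorant_spray", ("trunk",), "leave_on", 0.50, 1.0),
    ("perfume", ("trunk", "head"), "leave_on", 0.55, 0.3),
    ("hair_gel", ("head",), "leave_on", 0.25, 2.0),
    ("hair_spray", ("head",), "leave_on", 0.25, 3.0),
    ("hair_wax", ("head",), "leave_on", 0.15, 1.0),
    ("hair_dye", ("head",), "rinse_off", 0.10, 50.0),
    ("foundation", ("head",), "leave_on", 0.35, 0.6),
    ("face_powder", ("head",), "leave_on", 0.25, 0.3),
    ("eye_makeup", ("head",), "leave_on", 0.35, 0.1),
    ("lipstick", ("head",), "leave_on", 0.35, 0.05),
    ("lip_balm", ("head",), "leave_on", 0.35, 0.05),
    ("nail_polish", ("hands",), "leave_on", 0.25, 0.3),
]

# 5 household cleaning product types in several product forms.
_EU_HCP_PRODUCTS: list[tuple[str, str, float, float]] = [
    ("all_purpose_cleaner_liquid", "liquid", 0.80, 30.0),
    ("all_purpose_cleaner_spray", "spray", 0.50, 5.0),
    ("all_purpose_cleaner_wipes", "wipes", 0.25, 4.0),
    ("kitchen_cleaner_liquid", "liquid", 0.55, 25.0),
    ("kitchen_cleaner_spray", "spray", 0.45, 5.0),
    ("floor_cleaner_liquid", "liquid", 0.65, 40.0),
    ("glass_window_cleaner_spray", "spray", 0.50, 5.0),
    ("bathroom_cleaner_liquid", "liquid", 0.45, 25.0),
    ("bathroom_cleaner_spray", "spray", 0.45, 5.0),
]


def default_catalog(survey_kind: str) -> list[ProductDef]:
    """Default product catalog for each synthetic survey kind: 32 PCPs
    (dutch_pcp), the first 21 of them (eu_pcp), or 9 HCP type x form
    combinations (eu_hcp)."""
    if survey_kind in ("dutch_pcp", "eu_pcp"):
        rows = _DUTCH_PCP_PRODUCTS if survey_kind == "dutch_pcp" else _DUTCH_PCP_PRODUCTS[:21]
        return [
            ProductDef(pid, "PCP", parts, rinse, ownership_prob=own, amount_scale_g=amt)
            for pid, parts, rinse, own, amt in rows
        ]
    if survey_kind == "eu_hcp":
        return [
            ProductDef(
                pid, "HCP", ("hands",), "hcp_hand_contact",
                product_form=form, ownership_prob=own, amount_scale_g=amt,
            )
            for pid, form, own, amt in _EU_HCP_PRODUCTS
        ]
    raise SurveyValidationError(f"unknown survey kind {survey_kind!r}")


def _default_nationality_weights(kind: str) -> dict[str, float]:
    if kind == "dutch_pcp":
        return {"NL": 1.0}
    if kind == "eu_pcp":
        return {"DE": 0.25, "FR": 0.25, "UK": 0.25, "ES": 0.25}
    # HCP: include NL so the survey can be merged with the Dutch PCP survey
    return {c: 0.2 for c in COUNTRIES}


@dataclass
class SyntheticSurveyConfig:
    """Parameters of the synthetic survey generator.

    sex_ratio is the fraction of women.  Body weights are lognormal
    (median 74 kg, GSD 1.18 — a typical adult European distribution).
    propensity_sd scales the per-person latent usage propensity added to
    each product's ownership log-odds (0 = independent ownership).
    """

    survey_kind: str
    n_persons: int = 516
    sex_ratio: float = 0.5
    nationality_weights: Mapping[str, float] | None = None
    catalog: Sequence[ProductDef] | None = None
    ownership_prob: float | None = None  # overrides catalog values if set
    frequency_category_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "<1/week": 0.25, "1-2/week": 0.25, "3-4/week": 0.15,
            "5-6/week": 0.10, "1/day": 0.20, ">=2-3/day": 0.05,
        }
    )
    amount_category_weights: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.3, "mid": 0.5, "high": 0.2}
    )
    body_weight_median: float = 74.0
    body_weight_gsd: float = 1.18
    propensity_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.survey_kind not in ("dutch_pcp", "eu_pcp", "eu_hcp"):
            raise SurveyValidationError(f"unknown survey kind {self.survey_kind!r}")
        if self.n_persons <= 0:
            raise SurveyValidationError("n_persons must be positive")
        if not 0 <= self.sex_ratio <= 1:
            raise SurveyValidationError("sex_ratio must be in [0, 1]")
        if self.nationality_weights is None:
            self.nationality_weights = _default_nationality_weights(self.survey_kind)
        total = sum(self.nationality_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise SurveyValidationError(
                f"nationality weights must sum to 1, got {total}"
            )
        if any(w < 0 for w in self.nationality_weights.values()):
            raise SurveyValidationError("nationality weights must be >= 0")
        if self.catalog is None:
            self.catalog = default_catalog(self.survey_kind)
        if self.ownership_prob is not None:
            if not 0 <= self.ownership_prob <= 1:
                raise SurveyValidationError("ownership_prob must be in [0, 1]")
            self.catalog = [
                replace(p, ownership_prob=self.ownership_prob) for p in self.catalog
            ]


# amount categories as multiples of the product's typical amount; categorical
# survey answers become uniform-within-category intervals
_AMOUNT_CATEGORIES = {"low": (0.25, 0.75), "mid": (0.75, 1.5), "high": (1.5, 3.0)}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    eps = 1e-12
    p = min(max(p, eps), 1 - eps)
    return float(np.log(p / (1 - p)))


def generate_survey(config: SyntheticSurveyConfig) -> Survey:
    """Generate a synthetic survey; deterministic for a fixed seed.

    eu_pcp surveys record 14-day diaries (diary-mode frequencies, fixed
    mean amounts from product weighing); dutch_pcp and eu_hcp record
    categorical intervals for both frequency and amount.
    """
    rng = np.random.default_rng(config.seed)
    catalog = list(config.catalog)
    countries = sorted(config.nationality_weights)
    cweights = np.array([config.nationality_weights[c] for c in countries])
    cweights = cweights / cweights.sum()
    freq_labels = list(config.frequency_category_weights)
    fweights = np.array([config.frequency_category_weights[k] for k in freq_labels])
    fweights = fweights / fweights.sum()
    amt_labels = list(config.amount_category_weights)
    aweights = np.array([config.amount_category_weights[k] for k in amt_labels])
    aweights = aweights / aweights.sum()

    persons: list[Person] = []
    uses: dict[str, list[ProductUse]] = {}
    prefix = {"dutch_pcp": "nl", "eu_pcp": "eu", "eu_hcp": "hc"}[config.survey_kind]
    for i in range(config.n_persons):
        pid = f"{prefix}{i:05d}"
        sex = "female" if rng.random() < config.sex_ratio else "male"
        nat = countries[rng.choice(len(countries), p=cweights)]
        bw = float(rng.lognormal(np.log(config.body_weight_median),
                                 np.log(config.body_weight_gsd)))
        persons.append(Person(pid, sex, nat, bw, config.survey_kind))
        propensity = rng.normal(0.0, config.propensity_sd)
        own_p = _sigmoid(np.array([_logit(p.ownership_prob) for p in catalog])
                         + propensity)
        owned = rng.random(len(catalog)) < own_p
        person_uses: list[ProductUse] = []
        for j, pdef in enumerate(catalog):
            if not owned[j]:
                continue
            flabel = freq_labels[rng.choice(len(freq_labels), p=fweights)]
            f_interval = DEFAULT_FREQUENCY_CATEGORIES[flabel]
            alabel = amt_labels[rng.choice(len(amt_labels), p=aweights)]
            alo, ahi = _AMOUNT_CATEGORIES[alabel]
            alo *= pdef.amount_scale_g
            ahi *= pdef.amount_scale_g
            if config.survey_kind == "eu_pcp":
                # diary survey: a recorded 14-day usage pattern and a fixed
                # mean amount per event from product weighing
                f = rng.uniform(*f_interval)
                p_day = weekly_frequency_to_daily_prob(f)
                diary = (rng.random(N_SIM_DAYS) < p_day).astype(int)
                freq = FrequencySpec(mode="diary", diary=tuple(int(d) for d in diary))
                amount = AmountSpec.from_fixed(float(rng.uniform(alo, ahi)))
            else:
                freq = FrequencySpec.from_interval(*f_interval)
                amount = AmountSpec.from_interval(alo, ahi)
            person_uses.append(
                ProductUse(
                    product_id=pdef.product_id,
                    product_group=pdef.product_group,
                    product_form=pdef.product_form,
                    frequency=freq,
                    amount=amount,
                    body_parts=frozenset(pdef.body_parts),
                )
            )
        if person_uses:
            uses[pid] = person_uses
    return Survey(
        name=f"synthetic_{config.survey_kind}",
        persons=persons,
        uses=uses,
        product_catalog={
            p.product_id: (p.product_group, p.product_form) for p in catalog
        },
    )


def generate_concentration_data(
    products: Sequence[str] | int,
    positives_per_product: int | Sequence[int] | Mapping[str, int],
    n_total_sampled: int = 20,
    median: float = 1e-3,
    gsd: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic measured-concentration table for concentration fitting.

    Per product, ``positives_per_product`` positive samples are drawn from
    a lognormal(median, gsd) of mass fraction; products may have 0 or 1
    positives to exercise every fitting rule.  Returns a DataFrame with
    columns (product_id, sample_id, n_total_sampled, concentration_g_per_g),
    one row per positive sample (products with zero positives appear with a
    single row carrying an empty concentration).
    """
    if isinstance(products, int):
        products = [f"product{i:03d}" for i in range(products)]
    products = list(products)
    if isinstance(positives_per_product, int):
        counts = {p: positives_per_product for p in products}
    elif isinstance(positives_per_product, Mapping):
        counts = {p: int(positives_per_product.get(p, 0)) for p in products}
    else:
        counts = dict(zip(products, (int(k) for k in positives_per_product)))
    rng = np.random.default_rng(seed)
    rows = []
    for pid in products:
        k = counts[pid]
        if k > n_total_sampled:
            raise SurveyValidationError(
                f"product {pid!r}: positives ({k}) exceed n_total_sampled"
            )
        if k == 0:
            rows.append((pid, "", n_total_sampled, np.nan))
            continue
        conc = rng.lognormal(np.log(median), np.log(gsd), k)
        for s, c in enumerate(conc):
            rows.append((pid, f"s{s:03d}", n_total_sampled, float(c)))
    return pd.DataFrame(
        rows,
        columns=["product_id", "sample_id", "n_total_sampled", "concentration_g_per_g"],
    )
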