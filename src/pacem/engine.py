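"""Person-oriented 14-day aggregate exposure simulation.

Every individual in the survey population is simulated over a fixed 14-day
window:

1. the survey population is copied into the model population, retaining
   demographics and the per-person product-use profile;
2. per product, a 14-day use pattern is realised — diaries are copied
   verbatim, categorical frequencies are sampled once per person and turned
   into independent Bernoulli(p) day indicators with p = min(f/7, 1);
3. per product, N_product concentrations are drawn from the
   occurrence-weighted concentration distribution — one draw per replicate,
   held fixed across the 14 days (a replicate stands for the brand a person
   uses, which does not change day to day);
4. exposure per day is computed with the configured metric (dermal load or
   systemic dose), amounts re-sampled per use day;
5. per person, the per-product replicate samples are randomly paired
   (independent permutation of replicate indices per product) and summed
   across products per day — for dermal load summed within body part first,
   then the maximum body-part load taken;
6. per replicate, the average daily exposure over the 14 days and the
   highest daily exposure are derived;
7. population percentiles, histograms and CDFs are produced by the
   reporting layer.

PCP and HCP populations come from separate surveys and are joined by
sampling, for each PCP person, an HCP use profile from a random HCP person
of the same sex and nationality (product use across the two groups is
assumed uncorrelated).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .concentration import ConcentrationSpec, sample_concentration
from .metrics import (
    DEFAULT_SURFACE_AREA_CM2,
    ROUTES,
    RouteParams,
    max_body_part_load,
)
from .survey import (
    N_SIM_DAYS,
    Person,
    ProductUse,
    Survey,
    prepare_diary,
    weekly_frequency_to_daily_prob,
)

__all__ = [
    "ConfigurationError",
    "ProductParams",
    "ExposureConfig",
    "SimulationResult",
    "AggregateExposureModel",
    "simulate_use_days",
    "simulate_person_product",
    "aggregate_daily",
    "summarize_person",
    "merge_surveys",
    "run_assessment",
    "tier1_additive",
]

METRICS = ("dermal_load", "systemic")


class ConfigurationError(ValueError):
    """Inconsistent or incomplete assessment configuration."""


@dataclass(frozen=True)
class ProductParams:
    """Substance parameters for one product.

    ``retention``: retention factor for dermal load, either a single value
    for all application body parts or a mapping body part -> factor.
    ``exposure_fractions``: mapping route -> EF for systemic dose.
    """

    concentration: ConcentrationSpec
    retention: float | Mapping[str, float] | None = None
    exposure_fractions: Mapping[str, float] | None = None

    def retention_for(self, part: str, product_id: str) -> float:
        if self.retention is None:
            raise ConfigurationError(
                f"product {product_id!r}: no retention factor configured"
            )
        if isinstance(self.retention, Mapping):
            if part not in self.retention:
                raise ConfigurationError(
                    f"product {product_id!r}: no retention factor for body part {part!r}"
                )
            r = self.retention[part]
        else:
            r = self.retention
        if not 0 <= r <= 1:
            raise ConfigurationError(
                f"product {product_id!r}: retention must be in [0, 1], got {r}"
            )
        return float(r)


@dataclass
class ExposureConfig:
    """Assessment settings.

    metric: "dermal_load" (ug/cm2) or "systemic" (mg/kg bw/day).
    routes / absorption_fractions: routes included in the systemic sum and
    their substance-specific absorbed fractions.
    n_product: number of concentration replicates per person, representing
    brand-to-brand variation among people with the same use profile.
    country: restrict the population to one nationality (None = all).
    product_groups: which product groups enter the aggregate.
    """

    metric: str
    product_params: dict[str, ProductParams]
    n_product: int = 100
    seed: int = 0
    routes: tuple[str, ...] = ("dermal",)
    absorption_fractions: Mapping[str, float] = field(default_factory=dict)
    surface_areas: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SURFACE_AREA_CM2)
    )
    country: str | None = None
    product_groups: tuple[str, ...] = ("PCP", "HCP")
    keep_product_summaries: bool = True

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ConfigurationError(f"unknown metric {self.metric!r}")
        if self.n_product < 1:
            raise ConfigurationError("n_product must be >= 1")
        for r in self.routes:
            if r not in ROUTES:
                raise ConfigurationError(f"unknown route {r!r}")
        if self.metric == "systemic":
            if not self.routes:
                raise ConfigurationError("systemic metric requires >= 1 route")
            for r in self.routes:
                fabs = self.absorption_fractions.get(r)
                if fabs is None or not 0 <= fabs <= 1:
                    raise ConfigurationError(
                        f"route {r!r}: absorption fraction in [0, 1] required"
                    )
        for g in self.product_groups:
            if g not in ("PCP", "HCP"):
                raise ConfigurationError(f"unknown product group {g!r}")


# ---------------------------------------------------------------------------
# Hierarchical RNG streams: seed -> person -> product, so that adding a
# product or person does not perturb any other stream.

def _id_hash(name: str) -> int:
    return int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little")

_PAIRING_TAG = _id_hash("__pairing__")
_MERGE_TAG = _id_hash("__merge__")


def _stream(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


# ---------------------------------------------------------------------------
# Core steps

def simulate_use_days(use: ProductUse, rng: np.random.Generator) -> np.ndarray:
    """14-day event-count vector for one person x product.

    Diary mode copies the prepared diary verbatim; interval mode samples a
    habitual weekly frequency f once, converts to a daily probability
    p = min(f/7, 1) and draws 14 independent Bernoulli(p) day indicators.
    """
    f = use.frequency
    if f.mode == "diary":
        return prepare_diary(f.diary)
    lo, hi = f.interval
    fw = lo if lo == hi else rng.uniform(lo, hi)
    p = weekly_frequency_to_daily_prob(fw)
    return (rng.random(N_SIM_DAYS) < p).astype(int)


def _daily_amounts(use: ProductUse, days: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Total grams of product used per day (amounts drawn per event)."""
    amounts = np.zeros(N_SIM_DAYS)
    a = use.amount
    for d in np.nonzero(days)[0]:
        k = int(days[d])
        if a.mode == "fixed":
            amounts[d] = a.fixed * k
        else:
            lo, hi = a.interval
            amounts[d] = k * lo if lo == hi else rng.uniform(lo, hi, k).sum()
    return amounts


def simulate_person_product(
    person: Person,
    use: ProductUse,
    params: ProductParams,
    config: ExposureConfig,
    rng: np.random.Generator,
):
    """Exposure matrix for one person x product.

    Returns an [N_product x 14] array for the systemic metric, or a mapping
    body part -> [N_product x 14] array for dermal load.  One concentration
    draw per replicate, fixed across the 14 days; amounts drawn per use
    day; non-use days are 0.
    """
    days = simulate_use_days(use, rng)
    amounts = _daily_amounts(use, days, rng)  # g/day, length 14
    conc = np.asarray(
        sample_concentration(params.concentration, rng, size=config.n_product)
    )
    substance_g = conc[:, None] * amounts[None, :]  # [N, 14] g substance
    if config.metric == "systemic":
        if not params.exposure_fractions:
            raise ConfigurationError(
                f"product {use.product_id!r}: no exposure fractions configured"
            )
        factor = 0.0
        for route in config.routes:
            ef = params.exposure_fractions.get(route, 0.0)
            fabs = config.absorption_fractions[route]
            RouteParams(route, ef, fabs)  # validates ranges
            factor += ef * fabs
        return substance_g * 1e3 * factor / person.body_weight  # mg/kg bw
    # dermal load: the full event amount is applied to each listed body part
    if not use.body_parts:
        raise ConfigurationError(
            f"product {use.product_id!r}: dermal load requires application body parts"
        )
    out: dict[str, np.ndarray] = {}
    for part in sorted(use.body_parts):
        r = params.retention_for(part, use.product_id)
        area = config.surface_areas.get(part)
        if area is None or area <= 0:
            raise ConfigurationError(f"no positive surface area for body part {part!r}")
        out[part] = substance_g * 1e6 * r / area  # ug/cm2
    return out


def _permute(matrices, perm: np.ndarray):
    """Apply one replicate permutation to a product's exposure tensors."""
    if isinstance(matrices, dict):
        return {k: v[perm] for k, v in matrices.items()}
    return matrices[perm]


def aggregate_daily(
    per_product: Sequence, rng: np.random.Generator, metric: str = "systemic"
) -> np.ndarray:
    """Aggregate per-product exposure matrices for one person.

    Replicate indices of each product are independently permuted (random
    pairing of the per-product samples), then exposures are summed across
    products per day.  For dermal load the sum is taken within each body
    part first and the maximum body-part load returned.
    """
    if not per_product:
        raise ConfigurationError("no product matrices to aggregate")
    shapes = {
        (m[next(iter(m))].shape if isinstance(m, dict) else m.shape)
        for m in per_product
    }
    if len(shapes) != 1:
        raise ConfigurationError(f"shape mismatch across products: {shapes}")
    n = next(iter(shapes))[0]
    permuted = [_permute(m, rng.permutation(n)) for m in per_product]
    return _sum_products(permuted, metric)


def _sum_products(permuted: Sequence, metric: str) -> np.ndarray:
    if metric == "dermal_load":
        parts: dict[str, np.ndarray] = {}
        for m in permuted:
            for part, v in m.items():
                parts[part] = parts.get(part, 0) + v
        return np.asarray(max_body_part_load(parts))
    total = 0
    for m in permuted:
        total = total + m
    return np.asarray(total)


def summarize_person(aggregate: np.ndarray) -> dict[str, np.ndarray]:
    """Replicate-wise mean ('average daily') and max ('highest daily')
    exposure over the 14 days."""
    agg = np.asarray(aggregate)
    return {"average_daily": agg.mean(axis=1), "highest_daily": agg.max(axis=1)}


def merge_surveys(
    pcp_survey: Survey, hcp_survey: Survey, rng: np.random.Generator
) -> Survey:
    """Join PCP and HCP surveys into one model population.

    Each PCP person keeps their demographics and PCP use profile and gains
    the HCP use profile of a uniformly sampled (with replacement) HCP
    person of the same sex and nationality.
    """
    cells: dict[tuple[str, str], list[str]] = {}
    for p in hcp_survey.persons:
        cells.setdefault((p.sex, p.nationality), []).append(p.person_id)
    uses: dict[str, list[ProductUse]] = {}
    for p in pcp_survey.persons:
        candidates = cells.get((p.sex, p.nationality))
        if not candidates:
            raise ConfigurationError(
                f"no HCP survey person matches (sex={p.sex}, "
                f"nationality={p.nationality}) for PCP person {p.person_id!r}"
            )
        donor = candidates[int(rng.integers(len(candidates)))]
        merged = list(pcp_survey.person_uses(p.person_id)) + list(
            hcp_survey.person_uses(donor)
        )
        if merged:
            uses[p.person_id] = merged
    catalog = dict(pcp_survey.product_catalog)
    catalog.update(hcp_survey.product_catalog)
    return Survey(
        name=f"{pcp_survey.name}+{hcp_survey.name}",
        persons=list(pcp_survey.persons),
        uses=uses,
        product_catalog=catalog,
    )


# ---------------------------------------------------------------------------
# Results container

@dataclass
class SimulationResult:
    """Simulated aggregate exposure for a population.

    ``daily`` maps group ("PCP", "HCP", "Total") to an array of shape
    [n_persons, N_product, 14] of daily exposures in the run's metric
    units.  ``product_values`` maps product_id to replicate-level
    single-product summaries (arrays [n_persons, N_product]) used for
    tier-1 contrasts.
    """

    persons: pd.DataFrame
    metric: str
    n_product: int
    seed: int
    daily: dict[str, np.ndarray]
    product_values: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @property
    def units(self) -> str:
        return "ug/cm2" if self.metric == "dermal_load" else "mg/kg bw/day"

    @property
    def groups(self) -> list[str]:
        return list(self.daily)

    def summaries(self, group: str = "Total") -> dict[str, np.ndarray]:
        """Per person x replicate average/highest daily exposure arrays
        of shape [n_persons, N_product]."""
        d = self.daily[group]
        return {"average": d.mean(axis=2), "highest": d.max(axis=2)}

    def exposed_mask(self) -> np.ndarray:
        """Person-level 'exposed' indicator: any nonzero total exposure on
        any simulated day in any replicate."""
        return (self.daily["Total"] > 0).any(axis=(1, 2))

    def values(
        self,
        group: str = "Total",
        time_frame: str = "highest",
        sex: str = "both",
        exposed_only: bool = False,
    ) -> np.ndarray:
        """Pooled person x replicate exposure values after filtering."""
        if time_frame not in ("average", "highest"):
            raise ConfigurationError(f"unknown time frame {time_frame!r}")
        if sex not in ("men", "women", "both"):
            raise ConfigurationError(f"unknown sex filter {sex!r}")
        mask = np.ones(len(self.persons), dtype=bool)
        if sex != "both":
            want = "male" if sex == "men" else "female"
            mask &= (self.persons["sex"] == want).to_numpy()
        if exposed_only:
            mask &= self.exposed_mask()
        if not mask.any():
            raise ConfigurationError(
                f"no persons left after filtering (group={group}, sex={sex}, "
                f"exposed_only={exposed_only})"
            )
        return self.summaries(group)[time_frame][mask].ravel()

    def to_frame(self, group: str = "Total", time_frame: str = "highest") -> pd.DataFrame:
        """Long-format per person x replicate summary table."""
        s = self.summaries(group)[time_frame]
        n = self.n_product
        frame = self.persons.loc[self.persons.index.repeat(n)].reset_index(drop=True)
        frame["replicate"] = np.tile(np.arange(n), len(self.persons))
        frame[f"{time_frame}_daily"] = s.ravel()
        return frame

    def summary(self) -> str:
        """Plain-text overview of the run."""
        from .reporting import percentile_table

        lines = [
            "Aggregate exposure simulation",
            f"  metric: {self.metric} ({self.units})",
            f"  persons: {len(self.persons)}   replicates: {self.n_product}"
            f"   days: {N_SIM_DAYS}   seed: {self.seed}",
            f"  exposed persons: {int(self.exposed_mask().sum())}",
            "",
            "Highest-day exposure percentiles:",
            percentile_table(self, time_frame="highest").to_string(),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Model

class AggregateExposureModel:
    """Person-oriented aggregate exposure model for a survey population.

    Built from an :class:`ExposureConfig` plus a PCP and/or an HCP survey;
    ``run()`` executes the seeded Monte Carlo simulation and returns a
    :class:`SimulationResult`.
    """

    def __init__(
        self,
        config: ExposureConfig,
        pcp_survey: Survey | None = None,
        hcp_survey: Survey | None = None,
    ) -> None:
        self.config = config
        pcp_wanted = "PCP" in config.product_groups
        hcp_wanted = "HCP" in config.product_groups
        if pcp_wanted and pcp_survey is None:
            raise ConfigurationError("PCP product group selected but no PCP survey given")
        if hcp_wanted and hcp_survey is None:
            raise ConfigurationError("HCP product group selected but no HCP survey given")
        if pcp_survey is not None:
            sources = pcp_survey.sources & {"dutch_pcp", "eu_pcp"}
            if len(sources) > 1:
                raise ConfigurationError(
                    "the Dutch and European PCP surveys cover different products "
                    "and cannot be combined in one population"
                )
            if config.country == "NL" and sources == {"eu_pcp"}:
                raise ConfigurationError(
                    "country 'NL' requires the Dutch PCP survey, not the European one"
                )
            if config.country in ("DE", "FR", "UK", "ES") and sources == {"dutch_pcp"}:
                raise ConfigurationError(
                    f"country {config.country!r} requires the European PCP survey"
                )
        self.pcp_survey = pcp_survey if pcp_wanted else None
        self.hcp_survey = hcp_survey if hcp_wanted else None

    # -- population assembly ------------------------------------------------
    def _population(self) -> Survey:
        cfg = self.config
        if self.pcp_survey is not None and self.hcp_survey is not None:
            rng = _stream(cfg.seed, _MERGE_TAG)
            survey = merge_surveys(self.pcp_survey, self.hcp_survey, rng)
        else:
            survey = self.pcp_survey or self.hcp_survey
        if cfg.country is not None:
            persons = [p for p in survey.persons if p.nationality == cfg.country]
            if not persons:
                raise ConfigurationError(f"no persons with nationality {cfg.country!r}")
            ids = {p.person_id for p in persons}
            survey = Survey(
                name=survey.name,
                persons=persons,
                uses={pid: u for pid, u in survey.uses.items() if pid in ids},
                product_catalog=survey.product_catalog,
            )
        return survey

    def run(self) -> SimulationResult:
        """Execute the simulation; deterministic for a fixed config seed."""
        cfg = self.config
        survey = self._population()
        n_persons = len(survey.persons)
        n = cfg.n_product
        shape = (n_persons, n, N_SIM_DAYS)
        groups = [g for g in ("PCP", "HCP") if g in cfg.product_groups]
        daily = {g: np.zeros(shape) for g in [*groups, "Total"]}
        product_values: dict[str, dict[str, list]] = {}

        for i, person in enumerate(survey.persons):
            # product_params defines the selected products: survey products
            # without configured parameters are outside the assessment
            uses = [
                u for u in survey.person_uses(person.person_id)
                if u.product_group in cfg.product_groups
                and u.product_id in cfg.product_params
            ]
            per_group: dict[str, list] = {g: [] for g in groups}
            for use in uses:
                params = cfg.product_params[use.product_id]
                rng = _stream(cfg.seed, i, _id_hash(use.product_id))
                mat = simulate_person_product(person, use, params, cfg, rng)
                pair_rng = _stream(cfg.seed, i, _PAIRING_TAG, _id_hash(use.product_id))
                mat = _permute(mat, pair_rng.permutation(n))
                per_group[use.product_group].append((use.product_id, mat))
                if cfg.keep_product_summaries:
                    single = _sum_products([mat], cfg.metric)
                    s = summarize_person(single)
                    rec = product_values.setdefault(
                        use.product_id, {"average": [], "highest": []}
                    )
                    rec["average"].append((i, s["average_daily"]))
                    rec["highest"].append((i, s["highest_daily"]))
            all_mats = []
            for g in groups:
                mats = [m for _, m in per_group[g]]
                all_mats.extend(mats)
                if mats:
                    daily[g][i] = _sum_products(mats, cfg.metric)
            if all_mats:
                daily["Total"][i] = _sum_products(all_mats, cfg.metric)

        persons_df = pd.DataFrame(
            {
                "person_id": [p.person_id for p in survey.persons],
                "sex": [p.sex for p in survey.persons],
                "nationality": [p.nationality for p in survey.persons],
                "body_weight": [p.body_weight for p in survey.persons],
            }
        )
        pv: dict[str, dict[str, np.ndarray]] = {}
        if cfg.keep_product_summaries:
            for pid, rec in product_values.items():
                pv[pid] = {}
                for key in ("average", "highest"):
                    arr = np.zeros((n_persons, n))
                    for i, vals in rec[key]:
                        arr[i] = vals
                    pv[pid][key] = arr
        return SimulationResult(
            persons=persons_df,
            metric=cfg.metric,
            n_product=n,
            seed=cfg.seed,
            daily=daily,
            product_values=pv,
        )


def run_assessment(
    config: ExposureConfig,
    pcp_survey: Survey | None = None,
    hcp_survey: Survey | None = None,
) -> SimulationResult:
    """Convenience wrapper: build the model and run it."""
    return AggregateExposureModel(config, pcp_survey, hcp_survey).run()


def tier1_additive(
    result: SimulationResult,
    percentile: float,
    time_frame: str = "highest",
    products: Sequence[str] | None = None,
) -> float:
    """Conservative tier-1 aggregate: the sum over products of the given
    population percentile of each product's single-product exposure.

    Uses the single-product replicate summaries retained during the run, so
    the contrast with the person-oriented aggregate shares the same draws.
    """
    if not result.product_values:
        raise ConfigurationError(
            "run with keep_product_summaries=True to compute tier-1 sums"
        )
    products = list(products) if products is not None else sorted(result.product_values)
    total = 0.0
    for pid in products:
        vals = result.product_values[pid][time_frame]
        total += float(np.percentile(vals.ravel(), percentile))
    return total
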