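"""Survey domain model: persons, product-use records and the conversion of
categorical survey answers into samplable probability distributions.

Consumer product usage surveys record, per person and product, a use
frequency (either a categorical interval such as "1-2 times per week" or a
day-by-day diary), a use amount (a categorical interval in grams per event,
or a fixed mean amount), and the body parts of application.  For simulation
the categorical answers are interpreted as uniform distributions within the
reported interval: a respondent reporting "1-2 times per week" contributes a
Uniform(1, 2) events/week frequency, "3-4 g" a Uniform(3, 4) g/event amount.

Diaries cover 7 or 14 consecutive days; 7-day diaries are tiled to the
simulation's fixed 14-day window.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SEXES",
    "COUNTRIES",
    "SURVEY_SOURCES",
    "BODY_PARTS",
    "PRODUCT_FORMS",
    "N_SIM_DAYS",
    "DEFAULT_FREQUENCY_CATEGORIES",
    "SurveyValidationError",
    "Person",
    "FrequencySpec",
    "AmountSpec",
    "ProductUse",
    "Survey",
    "frequency_interval_to_sampler",
    "amount_interval_to_sampler",
    "weekly_frequency_to_daily_prob",
    "prepare_diary",
    "read_survey",
    "write_survey",
]

SEXES = ("male", "female")
COUNTRIES = ("NL", "DE", "FR", "UK", "ES")
SURVEY_SOURCES = ("dutch_pcp", "eu_pcp", "eu_hcp")
BODY_PARTS = ("trunk", "head", "arms", "hands", "legs", "feet")
PRODUCT_FORMS = (
    "cream", "foam", "gel", "liquid", "powder", "spray", "tablets", "wipes",
)
PRODUCT_GROUPS = ("PCP", "HCP")

#: Number of simulated days per individual (fixed by the model design).
N_SIM_DAYS = 14

#: Default mapping from categorical frequency labels to [lo, hi] events/week.
#: The open upper category is mapped to [14, 21] events/week (2-3 uses/day);
#: override per deployment if survey-specific conversion tables are available.
DEFAULT_FREQUENCY_CATEGORIES: dict[str, tuple[float, float]] = {
    "<1/week": (0.0, 1.0),
    "1-2/week": (1.0, 2.0),
    "3-4/week": (3.0, 4.0),
    "5-6/week": (5.0, 6.0),
    "1/day": (7.0, 7.0),
    ">=2-3/day": (14.0, 21.0),
}


class SurveyValidationError(ValueError):
    """Raised when survey data violates the documented schema."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise SurveyValidationError(msg)


@dataclass(frozen=True)
class Person:
    """One surveyed individual.

    Only sex, nationality and body weight enter the simulation; surveys
    record further demographics (age, education, skin type ...) which are
    accepted by the file schema but ignored by the engine.
    """

    person_id: str
    sex: str
    nationality: str
    body_weight: float
    survey_source: str

    def __post_init__(self) -> None:
        _check(self.sex in SEXES, f"person {self.person_id}: unknown sex {self.sex!r}")
        _check(
            self.nationality in COUNTRIES,
            f"person {self.person_id}: unknown nationality {self.nationality!r}",
        )
        _check(
            self.body_weight > 0,
            f"person {self.person_id}: body_weight must be > 0, got {self.body_weight}",
        )
        _check(
            self.survey_source in SURVEY_SOURCES,
            f"person {self.person_id}: unknown survey_source {self.survey_source!r}",
        )


@dataclass(frozen=True)
class FrequencySpec:
    """Use-frequency specification: a categorical interval in events/week or
    a per-day diary of event counts."""

    mode: str  # "interval" | "diary"
    interval: tuple[float, float] | None = None
    diary: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        _check(self.mode in ("interval", "diary"), f"unknown frequency mode {self.mode!r}")
        if self.mode == "interval":
            _check(self.interval is not None, "interval mode requires an interval")
            lo, hi = self.interval
            _check(0 <= lo <= hi, f"invalid frequency interval [{lo}, {hi}]")
        else:
            _check(self.diary is not None, "diary mode requires a diary")
            _check(
                len(self.diary) == N_SIM_DAYS,
                f"diary must have {N_SIM_DAYS} days after preparation, got {len(self.diary)}",
            )
            _check(all(int(d) >= 0 for d in self.diary), "diary entries must be >= 0")

    @classmethod
    def from_interval(cls, lo: float, hi: float) -> "FrequencySpec":
        return cls(mode="interval", interval=(float(lo), float(hi)))

    @classmethod
    def from_diary(cls, days: Sequence[int]) -> "FrequencySpec":
        return cls(mode="diary", diary=tuple(int(d) for d in prepare_diary(days)))


@dataclass(frozen=True)
class AmountSpec:
    """Use-amount specification in grams per event: an interval or a fixed mean."""

    mode: str  # "interval" | "fixed"
    interval: tuple[float, float] | None = None
    fixed: float | None = None

    def __post_init__(self) -> None:
        _check(self.mode in ("interval", "fixed"), f"unknown amount mode {self.mode!r}")
        if self.mode == "interval":
            _check(self.interval is not None, "interval mode requires an interval")
            lo, hi = self.interval
            _check(0 <= lo <= hi, f"invalid amount interval [{lo}, {hi}]")
        else:
            _check(self.fixed is not None and self.fixed >= 0, "fixed amount must be >= 0")

    @classmethod
    def from_interval(cls, lo: float, hi: float) -> "AmountSpec":
        return cls(mode="interval", interval=(float(lo), float(hi)))

    @classmethod
    def from_fixed(cls, mean_g: float) -> "AmountSpec":
        return cls(mode="fixed", fixed=float(mean_g))


@dataclass(frozen=True)
class ProductUse:
    """One person x product usage record."""

    product_id: str
    product_group: str
    frequency: FrequencySpec
    amount: AmountSpec
    body_parts: frozenset[str] = frozenset()
    product_form: str | None = None

    def __post_init__(self) -> None:
        _check(
            self.product_group in PRODUCT_GROUPS,
            f"product {self.product_id}: unknown product_group {self.product_group!r}",
        )
        if self.product_form is not None:
            _check(
                self.product_form in PRODUCT_FORMS,
                f"product {self.product_id}: unknown product_form {self.product_form!r}",
            )
        for part in self.body_parts:
            _check(
                part in BODY_PARTS,
                f"product {self.product_id}: unknown body part {part!r}",
            )


@dataclass
class Survey:
    """A product-usage survey: persons plus their per-product use records.

    ``product_catalog`` maps product_id -> (product_group, product_form).
    """

    name: str
    persons: list[Person]
    uses: dict[str, list[ProductUse]]
    product_catalog: dict[str, tuple[str, str | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {p.person_id for p in self.persons}
        _check(len(ids) == len(self.persons), f"survey {self.name}: duplicate person_id")
        for pid, uses in self.uses.items():
            _check(pid in ids, f"survey {self.name}: uses reference unknown person {pid!r}")
            for u in uses:
                _check(
                    u.product_id in self.product_catalog,
                    f"survey {self.name}: product {u.product_id!r} not in catalog",
                )

    @property
    def sources(self) -> set[str]:
        return {p.survey_source for p in self.persons}

    def person_uses(self, person_id: str) -> list[ProductUse]:
        return self.uses.get(person_id, [])


# ---------------------------------------------------------------------------
# Categorical answer -> sampler conversion

def _uniform_sampler(lo: float, hi: float) -> Callable[..., np.ndarray | float]:
    if lo == hi:
        def sampler(rng: np.random.Generator, size=None):
            return lo if size is None else np.full(size, lo)
    else:
        def sampler(rng: np.random.Generator, size=None):
            return rng.uniform(lo, hi, size)
    return sampler


def frequency_interval_to_sampler(interval: Sequence[float]) -> Callable[..., np.ndarray | float]:
    """Uniform sampler over an events/week interval.

    A categorical answer like "1-2 times per week" is resolved to the
    interval [1, 2] and sampled uniformly; a degenerate interval [c, c]
    always yields c.
    """
    lo, hi = float(interval[0]), float(interval[1])
    _check(0 <= lo <= hi, f"invalid frequency interval [{lo}, {hi}]")
    return _uniform_sampler(lo, hi)


def amount_interval_to_sampler(interval: Sequence[float]) -> Callable[..., np.ndarray | float]:
    """Uniform sampler over a g/event interval."""
    lo, hi = float(interval[0]), float(interval[1])
    _check(0 <= lo <= hi, f"invalid amount interval [{lo}, {hi}]")
    return _uniform_sampler(lo, hi)


def weekly_frequency_to_daily_prob(f: float) -> float:
    """Daily use probability p = min(f/7, 1) from a weekly frequency f."""
    _check(f >= 0, f"frequency must be >= 0, got {f}")
    return min(f / 7.0, 1.0)


def prepare_diary(raw_diary: Sequence[int]) -> np.ndarray:
    """Normalize a 7- or 14-day diary to the 14-day simulation window.

    A 14-day diary is copied verbatim; a 7-day diary is tiled twice so the
    weekly pattern is preserved (the per-week count of use days is
    conserved).
    """
    arr = np.asarray(raw_diary, dtype=int)
    _check(arr.ndim == 1, "diary must be one-dimensional")
    _check(len(arr) in (7, 14), f"diary must have 7 or 14 days, got {len(arr)}")
    _check((arr >= 0).all(), "diary entries must be >= 0")
    if len(arr) == 7:
        arr = np.tile(arr, 2)
    return arr.copy()


# ---------------------------------------------------------------------------
# File I/O
#
# CSV schema: one row per person x product; a person with no products is a
# single row with empty product fields.  Columns:
#   person_id, sex, nationality, body_weight_kg, survey_source,
#   product_id, product_group, product_form, freq_mode, freq_lo, freq_hi,
#   diary, amount_mode, amount_lo_g, amount_hi_g, amount_fixed_g, body_parts
# diary is a 14-character digit string; body_parts is semicolon separated.
# Missing-value token: empty field.

_CSV_COLUMNS = [
    "person_id", "sex", "nationality", "body_weight_kg", "survey_source",
    "product_id", "product_group", "product_form", "freq_mode", "freq_lo",
    "freq_hi", "diary", "amount_mode", "amount_lo_g", "amount_hi_g",
    "amount_fixed_g", "body_parts",
]


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return repr(x)
    return str(x)


def _use_to_row(person: Person, use: ProductUse | None) -> dict[str, str]:
    row = {
        "person_id": person.person_id,
        "sex": person.sex,
        "nationality": person.nationality,
        "body_weight_kg": _fmt(person.body_weight),
        "survey_source": person.survey_source,
    }
    if use is None:
        row.update({c: "" for c in _CSV_COLUMNS[5:]})
        return row
    f, a = use.frequency, use.amount
    row.update({
        "product_id": use.product_id,
        "product_group": use.product_group,
        "product_form": _fmt(use.product_form),
        "freq_mode": f.mode,
        "freq_lo": _fmt(f.interval[0]) if f.mode == "interval" else "",
        "freq_hi": _fmt(f.interval[1]) if f.mode == "interval" else "",
        "diary": "".join(str(int(d)) for d in f.diary) if f.mode == "diary" else "",
        "amount_mode": a.mode,
        "amount_lo_g": _fmt(a.interval[0]) if a.mode == "interval" else "",
        "amount_hi_g": _fmt(a.interval[1]) if a.mode == "interval" else "",
        "amount_fixed_g": _fmt(a.fixed) if a.mode == "fixed" else "",
        "body_parts": ";".join(sorted(use.body_parts)),
    })
    return row


def write_survey(survey: Survey, path, fmt: str | None = None) -> None:
    """Write a survey to CSV (default) or JSON."""
    path = str(path)
    fmt = fmt or ("json" if path.endswith(".json") else "csv")
    if fmt == "json":
        payload = {
            "name": survey.name,
            "catalog": {
                pid: {"product_group": g, "product_form": form}
                for pid, (g, form) in sorted(survey.product_catalog.items())
            },
            "rows": [],
        }
        for person in survey.persons:
            uses = survey.person_uses(person.person_id)
            if not uses:
                payload["rows"].append(_use_to_row(person, None))
            for use in uses:
                payload["rows"].append(_use_to_row(person, use))
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for person in survey.persons:
            uses = survey.person_uses(person.person_id)
            if not uses:
                writer.writerow(_use_to_row(person, None))
            for use in uses:
                writer.writerow(_use_to_row(person, use))


def _parse_row(row: Mapping[str, str], rownum: int) -> tuple[Person, ProductUse | None]:
    def err(msg: str):
        raise SurveyValidationError(f"row {rownum}: {msg}")

    def fval(field: str) -> float:
        raw = (row.get(field) or "").strip()
        try:
            return float(raw)
        except ValueError:
            err(f"field {field!r}: cannot parse {raw!r} as a number")

    try:
        person = Person(
            person_id=(row.get("person_id") or "").strip(),
            sex=(row.get("sex") or "").strip(),
            nationality=(row.get("nationality") or "").strip(),
            body_weight=fval("body_weight_kg"),
            survey_source=(row.get("survey_source") or "").strip(),
        )
    except SurveyValidationError as exc:
        err(str(exc))
    product_id = (row.get("product_id") or "").strip()
    if not product_id:
        return person, None
    try:
        freq_mode = (row.get("freq_mode") or "").strip()
        if freq_mode == "interval":
            freq = FrequencySpec.from_interval(fval("freq_lo"), fval("freq_hi"))
        elif freq_mode == "diary":
            diary = (row.get("diary") or "").strip()
            freq = FrequencySpec.from_diary([int(ch) for ch in diary])
        else:
            err(f"field 'freq_mode': unknown mode {freq_mode!r}")
        amount_mode = (row.get("amount_mode") or "").strip()
        if amount_mode == "interval":
            amount = AmountSpec.from_interval(fval("amount_lo_g"), fval("amount_hi_g"))
        elif amount_mode == "fixed":
            amount = AmountSpec.from_fixed(fval("amount_fixed_g"))
        else:
            err(f"field 'amount_mode': unknown mode {amount_mode!r}")
        parts = frozenset(
            p for p in (row.get("body_parts") or "").split(";") if p
        )
        form = (row.get("product_form") or "").strip() or None
        use = ProductUse(
            product_id=product_id,
            product_group=(row.get("product_group") or "").strip(),
            product_form=form,
            frequency=freq,
            amount=amount,
            body_parts=parts,
        )
    except SurveyValidationError as exc:
        err(str(exc))
    return person, use


def _assemble(name: str, parsed: Iterable[tuple[Person, ProductUse | None]],
              catalog: dict[str, tuple[str, str | None]] | None = None) -> Survey:
    persons: list[Person] = []
    seen: dict[str, Person] = {}
    uses: dict[str, list[ProductUse]] = {}
    cat: dict[str, tuple[str, str | None]] = dict(catalog or {})
    for person, use in parsed:
        prev = seen.get(person.person_id)
        if prev is None:
            seen[person.person_id] = person
            persons.append(person)
        elif prev != person:
            raise SurveyValidationError(
                f"person {person.person_id!r}: conflicting demographic rows"
            )
        if use is not None:
            uses.setdefault(person.person_id, []).append(use)
            cat.setdefault(use.product_id, (use.product_group, use.product_form))
    return Survey(name=name, persons=persons, uses=uses, product_catalog=cat)


def read_survey(path, fmt: str | None = None, name: str | None = None) -> Survey:
    """Read a survey from the documented CSV or JSON schema.

    Schema violations raise :class:`SurveyValidationError` naming the row
    and field.
    """
    path = str(path)
    fmt = fmt or ("json" if path.endswith(".json") else "csv")
    name = name or path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    if fmt == "json":
        with open(path) as fh:
            payload = json.load(fh)
        catalog = {
            pid: (meta["product_group"], meta.get("product_form") or None)
            for pid, meta in payload.get("catalog", {}).items()
        }
        parsed = [_parse_row(row, i + 1) for i, row in enumerate(payload["rows"])]
        return _assemble(payload.get("name", name), parsed, catalog)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise SurveyValidationError(f"missing columns: {sorted(missing)}")
        parsed = [_parse_row(row, i + 2) for i, row in enumerate(reader)]
    return _assemble(name, parsed)
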