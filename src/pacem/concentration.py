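"""Occurrence-weighted concentration model.

The substance concentration a simulated individual encounters in a product
is drawn in two stages:

    concentration = Bernoulli(occurrence) x P(concentration)

where *occurrence* is the fraction of marketed products of that type that
contain the substance at all, and P(concentration) is a parametric
distribution (point, uniform, normal, lognormal or triangular) of the mass
fraction (g substance / g product) in the products that do contain it.

Also implemented here are the rules for building concentration
distributions from laboratory measurement campaigns: with two or more
positive samples a lognormal is fitted by maximum likelihood on the log
values; with exactly one positive sample c, a Uniform(c/10, 10c) is
assumed; with none, the product is treated as never containing the
substance.  HCP measurement data is typically pooled by generic product
form (liquids, sprays, wipes, ...) and the fitted form-level distribution
assigned to every product of that form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DISTRIBUTION_KINDS",
    "ConcentrationError",
    "Distribution",
    "ConcentrationSpec",
    "sample_concentration",
    "fit_concentration_spec",
    "group_product_forms",
]

DISTRIBUTION_KINDS = ("point", "uniform", "normal", "lognormal", "triangular")


class ConcentrationError(ValueError):
    """Invalid concentration specification or configuration."""


@dataclass(frozen=True)
class Distribution:
    """Parametric distribution of in-product mass fraction (g/g).

    kinds and params:
      - point:      value
      - uniform:    lo, hi
      - normal:     mean, sd          (truncated at 0 by rejection)
      - lognormal:  mu_log, sigma_log (natural-log scale; see from_median_gsd)
      - triangular: lo, mode, hi      (truncated at 0 by rejection)
    """

    kind: str
    params: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.kind not in DISTRIBUTION_KINDS:
            raise ConcentrationError(f"unknown distribution kind {self.kind!r}")
        p = dict(self.params)
        if self.kind == "point":
            if p["value"] < 0:
                raise ConcentrationError("point value must be >= 0")
        elif self.kind == "uniform":
            if not 0 <= p["lo"] <= p["hi"]:
                raise ConcentrationError(f"invalid uniform bounds [{p['lo']}, {p['hi']}]")
        elif self.kind == "normal":
            if p["sd"] < 0:
                raise ConcentrationError("normal sd must be >= 0")
        elif self.kind == "lognormal":
            if p["sigma_log"] < 0:
                raise ConcentrationError("lognormal sigma_log must be >= 0")
        elif self.kind == "triangular":
            if not p["lo"] <= p["mode"] <= p["hi"]:
                raise ConcentrationError("triangular requires lo <= mode <= hi")

    # -- constructors -------------------------------------------------------
    @classmethod
    def point(cls, value: float) -> "Distribution":
        return cls("point", (("value", float(value)),))

    @classmethod
    def uniform(cls, lo: float, hi: float) -> "Distribution":
        return cls("uniform", (("lo", float(lo)), ("hi", float(hi))))

    @classmethod
    def normal(cls, mean: float, sd: float) -> "Distribution":
        return cls("normal", (("mean", float(mean)), ("sd", float(sd))))

    @classmethod
    def lognormal(cls, mu_log: float, sigma_log: float) -> "Distribution":
        return cls("lognormal", (("mu_log", float(mu_log)), ("sigma_log", float(sigma_log))))

    @classmethod
    def from_median_gsd(cls, median: float, gsd: float) -> "Distribution":
        """Lognormal from median and geometric standard deviation."""
        if median <= 0 or gsd < 1:
            raise ConcentrationError("median must be > 0 and gsd >= 1")
        return cls.lognormal(math.log(median), math.log(gsd))

    @classmethod
    def triangular(cls, lo: float, mode: float, hi: float) -> "Distribution":
        return cls("triangular", (("lo", float(lo)), ("mode", float(mode)), ("hi", float(hi))))

    @property
    def p(self) -> dict[str, float]:
        return dict(self.params)

    # -- sampling -----------------------------------------------------------
    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.p
        if self.kind == "point":
            return np.full(size, p["value"])
        if self.kind == "uniform":
            if p["lo"] == p["hi"]:
                return np.full(size, p["lo"])
            return rng.uniform(p["lo"], p["hi"], size)
        if self.kind == "lognormal":
            return rng.lognormal(p["mu_log"], p["sigma_log"], size)
        if self.kind == "normal":
            draw = lambda n: rng.normal(p["mean"], p["sd"], n)
        else:  # triangular
            if p["lo"] == p["hi"]:
                return np.full(size, p["lo"])
            draw = lambda n: rng.triangular(p["lo"], p["mode"], p["hi"], n)
        # mass fractions cannot be negative: resample below-zero draws
        out = draw(size)
        bad = out < 0
        while bad.any():
            out[bad] = draw(int(bad.sum()))
            bad = out < 0
        return out


@dataclass(frozen=True)
class ConcentrationSpec:
    """Occurrence fraction plus in-product concentration distribution."""

    occurrence: float
    distribution: Distribution

    def __post_init__(self) -> None:
        if not 0 <= self.occurrence <= 1:
            raise ConcentrationError(
                f"occurrence must be in [0, 1], got {self.occurrence}"
            )


def sample_concentration(
    spec: ConcentrationSpec, rng: np.random.Generator, size: int | None = None
) -> np.ndarray | float:
    """Draw concentrations: 0 with probability 1 - occurrence, otherwise a
    draw from the distribution.  Values are capped at 1 g/g (with a warning)
    since a mass fraction cannot exceed 1."""
    n = 1 if size is None else int(size)
    out = np.zeros(n)
    if spec.occurrence > 0:
        present = rng.random(n) < spec.occurrence
        k = int(present.sum())
        if k:
            out[present] = spec.distribution.sample(rng, k)
    if (out > 1).any():
        warnings.warn(
            "sampled concentration exceeds 1 g/g; capping at 1", stacklevel=2
        )
        np.minimum(out, 1.0, out=out)
    return float(out[0]) if size is None else out


def fit_concentration_spec(
    measurements: Sequence[float], n_total_sampled: int
) -> ConcentrationSpec:
    """Build a ConcentrationSpec from a measurement campaign.

    ``measurements`` are the positive (detected) concentrations among
    ``n_total_sampled`` sampled products.  Occurrence is the raw positive
    fraction.  With >= 2 positives a lognormal is fitted by maximum
    likelihood on the natural-log values; with exactly one positive sample
    c, Uniform(c/10, 10c) is assumed; with none, occurrence is 0.
    """
    m = np.asarray(measurements, dtype=float)
    if n_total_sampled < len(m):
        raise ConcentrationError(
            f"n_total_sampled ({n_total_sampled}) < number of positives ({len(m)})"
        )
    if len(m) and (m <= 0).any():
        raise ConcentrationError("measurements must be strictly positive")
    if len(m) == 0:
        return ConcentrationSpec(0.0, Distribution.point(0.0))
    occurrence = len(m) / n_total_sampled
    if len(m) == 1:
        c = float(m[0])
        return ConcentrationSpec(occurrence, Distribution.uniform(c / 10.0, 10.0 * c))
    logs = np.log(m)
    # MLE for lognormal: mean and (biased, 1/n) sd of the log values
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))
    return ConcentrationSpec(occurrence, Distribution.lognormal(mu, sigma))


def group_product_forms(
    products: Mapping[str, str | None],
    form_specs: Mapping[str, ConcentrationSpec],
    product_specs: Mapping[str, ConcentrationSpec] | None = None,
) -> dict[str, ConcentrationSpec]:
    """Resolve a ConcentrationSpec for every product.

    ``products`` maps product_id -> product form (or None).  Explicit
    per-product specs take precedence; otherwise the product inherits the
    spec of its generic form (so e.g. one "liquid" distribution serves all
    liquid cleaner products).  A product with neither raises.
    """
    product_specs = dict(product_specs or {})
    out: dict[str, ConcentrationSpec] = {}
    for pid, form in products.items():
        if pid in product_specs:
            out[pid] = product_specs[pid]
        elif form is not None and form in form_specs:
            out[pid] = form_specs[form]
        else:
            raise ConcentrationError(
                f"no concentration specification for product {pid!r} "
                f"(form {form!r}): provide a per-product or per-form spec"
            )
    return out
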