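"""Assessment configuration files (YAML or JSON).

A run configuration mirrors the assessment settings of the interactive
tool: product group selection, exposure metric, country, routes and
absorption fractions, per-product (or per-form) concentration and exposure
parameters, the replicate count N_product, the seed, and reporting
options.  Example::

    metric: dermal_load
    product_groups: [PCP, HCP]
    country: NL
    n_product: 100
    seed: 1
    surveys:
      pcp: surveys/pcp.csv
      hcp: surveys/hcp.csv
    products:
      - product_id: shampoo
        occurrence: 0.3
        distribution: {kind: lognormal, median: 1.0e-4, gsd: 2.0}
        retention: 0.01
      - form: liquid
        occurrence: 0.25
        distribution: {kind: uniform, lo: 1.0e-5, hi: 1.0e-3}
        retention: {hands: 0.01}
    output: {time_frame: highest, sex: both, exposed_only: false}

Entries keyed by ``form`` apply to every product of that form without an
explicit per-product entry.  For the systemic metric, ``routes``,
``absorption_fractions`` and per-product ``exposure_fractions`` replace
``retention``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .concentration import (
    ConcentrationError,
    ConcentrationSpec,
    Distribution,
    group_product_forms,
)
from .engine import ConfigurationError, ExposureConfig, ProductParams
from .survey import Survey, read_survey

__all__ = ["RunSpec", "load_run_spec", "parse_distribution", "build_exposure_config"]


def parse_distribution(block: Mapping[str, Any]) -> Distribution:
    """Parse a distribution block; lognormal accepts either (median, gsd)
    or (mu_log, sigma_log)."""
    kind = block.get("kind")
    if kind == "point":
        return Distribution.point(block["value"])
    if kind == "uniform":
        return Distribution.uniform(block["lo"], block["hi"])
    if kind == "normal":
        return Distribution.normal(block["mean"], block["sd"])
    if kind == "lognormal":
        if "median" in block:
            return Distribution.from_median_gsd(block["median"], block["gsd"])
        return Distribution.lognormal(block["mu_log"], block["sigma_log"])
    if kind == "triangular":
        return Distribution.triangular(block["lo"], block["mode"], block["hi"])
    raise ConcentrationError(f"unknown distribution kind {kind!r}")


def _parse_product_entry(entry: Mapping[str, Any]) -> tuple[str | None, str | None, ProductParams]:
    pid = entry.get("product_id")
    form = entry.get("form")
    if (pid is None) == (form is None):
        raise ConfigurationError(
            "each product entry needs exactly one of 'product_id' or 'form'"
        )
    spec = ConcentrationSpec(
        occurrence=float(entry["occurrence"]),
        distribution=parse_distribution(entry["distribution"]),
    )
    params = ProductParams(
        concentration=spec,
        retention=entry.get("retention"),
        exposure_fractions=entry.get("exposure_fractions"),
    )
    return pid, form, params


@dataclass
class RunSpec:
    """Parsed run configuration: surveys, exposure config factory and
    reporting options."""

    raw: dict
    pcp_survey_path: str | None
    hcp_survey_path: str | None
    output: dict = field(default_factory=dict)
    digest: str = ""

    def load_surveys(self, base: Path) -> tuple[Survey | None, Survey | None]:
        def load(p):
            if p is None:
                return None
            path = Path(p)
            if not path.is_absolute():
                path = base / path
            return read_survey(path)

        return load(self.pcp_survey_path), load(self.hcp_survey_path)


def load_run_spec(path: str | Path) -> RunSpec:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            raw = yaml.safe_load(fh)
        else:
            raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError("run configuration must be a mapping")
    surveys = raw.get("surveys", {})
    digest = hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()
    ).hexdigest()
    return RunSpec(
        raw=raw,
        pcp_survey_path=surveys.get("pcp"),
        hcp_survey_path=surveys.get("hcp"),
        output=raw.get("output", {}),
        digest=digest,
    )


def build_exposure_config(
    spec: RunSpec, pcp_survey: Survey | None, hcp_survey: Survey | None
) -> ExposureConfig:
    """Resolve product/form entries against the survey catalogs into a
    complete :class:`ExposureConfig`."""
    raw = spec.raw
    entries = raw.get("products", [])
    per_product: dict[str, ProductParams] = {}
    per_form: dict[str, ProductParams] = {}
    for entry in entries:
        pid, form, params = _parse_product_entry(entry)
        if pid is not None:
            per_product[pid] = params
        else:
            per_form[form] = params

    catalog: dict[str, str | None] = {}
    for survey in (pcp_survey, hcp_survey):
        if survey is not None:
            for pid, (_, form) in survey.product_catalog.items():
                catalog.setdefault(pid, form)
    # only products with any configured spec are simulated; resolve form
    # inheritance for the rest of their parameters via the same precedence
    selected = {
        pid: form
        for pid, form in catalog.items()
        if pid in per_product or (form is not None and form in per_form)
    }
    if not selected:
        raise ConfigurationError("no configured products found in the surveys")
    spec_map = group_product_forms(
        selected,
        {f: p.concentration for f, p in per_form.items()},
        {pid: p.concentration for pid, p in per_product.items()},
    )
    params_map: dict[str, ProductParams] = {}
    for pid, cspec in spec_map.items():
        src = per_product.get(pid) or per_form[selected[pid]]
        params_map[pid] = ProductParams(
            concentration=cspec,
            retention=src.retention,
            exposure_fractions=src.exposure_fractions,
        )

    kwargs: dict[str, Any] = {
        "metric": raw.get("metric", "dermal_load"),
        "product_params": params_map,
        "n_product": int(raw.get("n_product", 100)),
        "seed": int(raw.get("seed", 0)),
        "country": raw.get("country"),
        "product_groups": tuple(raw.get("product_groups", ["PCP", "HCP"])),
    }
    if "routes" in raw:
        kwargs["routes"] = tuple(raw["routes"])
    if "absorption_fractions" in raw:
        kwargs["absorption_fractions"] = dict(raw["absorption_fractions"])
    if "surface_areas" in raw:
        kwargs["surface_areas"] = dict(raw["surface_areas"])
    return ExposureConfig(**kwargs)
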