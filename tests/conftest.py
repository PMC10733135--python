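import numpy as np
import pandas as pd
import pytest

from pacem.concentration import ConcentrationSpec, Distribution
from pacem.engine import ExposureConfig, ProductParams, SimulationResult
from pacem.survey import (
    AmountSpec,
    FrequencySpec,
    Person,
    ProductUse,
    Survey,
)

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_person(pid="p1", sex="female", nat="NL", bw=60.0, source="dutch_pcp"):
    return Person(pid, sex, nat, bw, source)


def make_use(
    product_id="prod",
    group="PCP",
    freq=(7.0, 7.0),
    amount=1.0,
    body_parts=("hands",),
    form=None,
):
    fspec = FrequencySpec.from_interval(*freq)
    aspec = (
        AmountSpec.from_fixed(amount)
        if np.isscalar(amount)
        else AmountSpec.from_interval(*amount)
    )
    return ProductUse(
        product_id=product_id,
        product_group=group,
        product_form=form,
        frequency=fspec,
        amount=aspec,
        body_parts=frozenset(body_parts),
    )


def point_params(conc=1e-3, occurrence=1.0, retention=1.0, ef=None):
    return ProductParams(
        concentration=ConcentrationSpec(occurrence, Distribution.point(conc)),
        retention=retention,
        exposure_fractions=ef,
    )


@pytest.fixture
def tiny_survey():
    """Three-person single-product PCP survey with daily deterministic use."""
    persons = [
        make_person("p1", "female", "NL", 60.0),
        make_person("p2", "male", "NL", 80.0),
        make_person("p3", "female", "NL", 70.0),
    ]
    use = make_use("cream", freq=(7.0, 7.0), amount=1.0, body_parts=("hands",))
    return Survey(
        name="tiny",
        persons=persons,
        uses={p.person_id: [use] for p in persons},
        product_catalog={"cream": ("PCP", None)},
    )


def fake_result(values, metric="dermal_load", sexes=None, seed=0):
    """SimulationResult with an injected per-person x replicate x day tensor."""
    daily = np.asarray(values, dtype=float)
    assert daily.ndim == 3
    n_persons = daily.shape[0]
    sexes = sexes or ["female" if i % 2 else "male" for i in range(n_persons)]
    persons = pd.DataFrame(
        {
            "person_id": [f"p{i}" for i in range(n_persons)],
            "sex": sexes,
            "nationality": ["NL"] * n_persons,
            "body_weight": [70.0] * n_persons,
        }
    )
    return SimulationResult(
        persons=persons,
        metric=metric,
        n_product=daily.shape[1],
        seed=seed,
        daily={"Total": daily},
    )


def single_product_config(conc=1e-3, occurrence=1.0, retention=1.0,
                          area=1000.0, n_product=5, seed=0, **kw):
    return ExposureConfig(
        metric="dermal_load",
        product_params={"cream": point_params(conc, occurrence, retention)},
        n_product=n_product,
        seed=seed,
        surface_areas={"hands": area},
        product_groups=("PCP",),
        **kw,
    )
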