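"""Shared fixtures: packaged defaults, printed reference tables, flat backgrounds."""

import numpy as np
import pytest

from osteohta.parameters import load_parameters, load_printed_tables
from osteohta.synthetic_inputs import MAX_AGE, MIN_AGE, BaselineHazards, LifeTable


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def printed():
    return load_printed_tables()


def flat_life_table(q: float) -> LifeTable:
    """Constant six-month death probability (terminal age closes at 1)."""
    ages = np.arange(MIN_AGE, MAX_AGE + 1, dtype=float)
    q6m = np.full_like(ages, q)
    q6m[-1] = 1.0
    return LifeTable(ages=ages, q6m=q6m)


def flat_hazards(hip=0.0, vertebral=0.0, other=0.0, excess=1.0) -> BaselineHazards:
    """Age-constant SIX-MONTH fracture probabilities."""
    return BaselineHazards.from_parametric(
        {"hip": hip, "vertebral": vertebral, "other": other},
        {"hip": 0.0, "vertebral": 0.0, "other": 0.0},
        excess_mortality_hip=excess,
    )


@pytest.fixture()
def zero_mortality():
    return flat_life_table(0.0)
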