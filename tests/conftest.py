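"""Shared fixtures: synthetic input bundles and pre-run scenario ledgers.

Everything is generated programmatically from seeded configurations; no
data files are stored.
"""

from __future__ import annotations

import pandas as pd
import pytest

import hwpcarbon as h


@pytest.fixture(scope="session")
def small_config() -> h.SyntheticConfig:
    """A compact 10-year instance for oracle comparisons."""
    return h.SyntheticConfig(
        seed=7, start_year=2000, peak_year=2005, end_year=2009, n_end_uses=10
    )


@pytest.fixture(scope="session")
def small_inputs(small_config) -> h.ModelInputs:
    return h.gen_inputs(small_config)


@pytest.fixture(scope="session")
def ca_config() -> h.SyntheticConfig:
    """The full California-like study window (1952-2019, peak 1989)."""
    return h.SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def ca_inputs(ca_config) -> h.ModelInputs:
    return h.gen_inputs(ca_config)


@pytest.fixture(scope="session")
def ca_ledgers(ca_inputs) -> dict[str, h.AnnualLedger]:
    """All seven scenarios run on the shared California-like inputs."""
    options = h.EngineOptions(shift_year=True)
    return {
        name: h.run_simulation(h.prepare_scenario(ca_inputs, name), options)
        for name in h.SCENARIO_NAMES
    }


def single_pulse_inputs(
    *,
    half_life: float = 5.0,
    landfill_fixed_ratio: float = 0.0,
    landfill_half_life: float = 29.0,
    fates: dict[str, float] | None = None,
    start: int = 2000,
    end: int = 2100,
    category: str = "wood",
) -> h.ModelInputs:
    """One end use, 1 Tg C harvested in the first year, fully allocated.

    Default fate routing is 100% landfill; override with ``fates``.
    """
    years = list(range(start, end + 1))
    fates = fates or {"landfill": 1.0}
    harvest = pd.DataFrame(
        {
            "year": years,
            "primary_product": "box",
            "carbon_mass": [1.0] + [0.0] * (len(years) - 1),
        }
    )
    end_use_ratios = pd.DataFrame(
        [
            {"year": y, "source_category": "box", "target_category": "box", "fraction": 1.0}
            for y in years
        ]
    )
    fate_rows = pd.DataFrame(
        [
            {
                "year": y,
                "discard_category": category,
                "fate": fate,
                "fraction": fates.get(fate, 0.0),
            }
            for y in years
            for fate in h.FATES
        ]
    )
    decay = pd.DataFrame(
        [
            {
                "discard_category": category,
                "dump_half_life": 16.5,
                "landfill_fixed_ratio": landfill_fixed_ratio,
                "landfill_half_life": landfill_half_life,
                "recovered_half_life": 2.6,
            }
        ]
    )
    end_use_params = pd.DataFrame(
        [
            {
                "end_use": "box",
                "half_life": half_life,
                "discard_category": category,
                "fuelwood_flag": False,
            }
        ]
    )
    return h.ModelInputs(harvest, None, end_use_ratios, fate_rows, decay, end_use_params)
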