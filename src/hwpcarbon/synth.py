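"""Synthetic California-like model inputs.

Generates, from one seeded random generator, an input bundle with the
qualitative structure the analysis assumes: a 1952–2019 harvest series that
rises to a late-1980s peak and then declines; primary-product and end-use
ratio tables whose rows sum to one, with wood pulp ceasing to draw from the
harvest after about 2001; a discard-fate trajectory in which dumps fall to
about 2% of discards after 1990 as landfilling rises (with visible shifts
around 1970 and 1980); and a five-category paper waste-characterisation
series over 1960–2018.

Magnitudes are chosen so that cumulative solid-waste storage lands in the
hundreds of MMT CO2Eq; no numeric claim attaches to synthetic magnitudes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .defaults import PAPER_SPLIT_CATEGORIES, default_decay_params_table
from .errors import ValidationError
from .params import ModelInputs

HARVEST_CLASSES = {
    "softwood, sawtimber": 0.60,
    "hardwood, sawtimber": 0.08,
    "softwood, pulpwood": 0.22,
    "hardwood, pulpwood": 0.10,
}

# primary products and their base shares per harvest class (pre-pulp-phase-out)
PRIMARY_SHARES = {
    "softwood, sawtimber": {
        "lumber": 0.55, "structural panels": 0.14, "nonstructural panels": 0.06,
        "wood pulp": 0.07, "fuelwood": 0.06, "miscellaneous products": 0.12,
    },
    "hardwood, sawtimber": {
        "lumber": 0.40, "structural panels": 0.05, "nonstructural panels": 0.15,
        "wood pulp": 0.10, "fuelwood": 0.15, "miscellaneous products": 0.15,
    },
    "softwood, pulpwood": {
        "lumber": 0.0, "structural panels": 0.0, "nonstructural panels": 0.10,
        "wood pulp": 0.70, "fuelwood": 0.12, "miscellaneous products": 0.08,
    },
    "hardwood, pulpwood": {
        "lumber": 0.0, "structural panels": 0.0, "nonstructural panels": 0.12,
        "wood pulp": 0.60, "fuelwood": 0.18, "miscellaneous products": 0.10,
    },
}

# end-use label templates per primary product; the product tag in the label
# is what the wood crosswalk keys on
_EU_TEMPLATES = {
    "lumber": (
        ["new residential construction", "repair and remodeling",
         "nonresidential construction", "furniture", "pallets and containers",
         "manufacturing", "railroad ties", "fencing and decking"],
        "lumber",
    ),
    "structural panels": (
        ["sheathing", "flooring underlayment", "roof decking", "concrete forms"],
        ["softwood plywood", "oriented strand board"],
    ),
    "nonstructural panels": (
        ["cabinets", "shelving", "door skins", "moulding"],
        ["medium-density fiberboard", "hardboard"],
    ),
    "miscellaneous products": (
        ["shipping dunnage", "signs and posts", "turned products",
         "other industrial products"],
        "other industrial",
    ),
}


@dataclasses.dataclass
class SyntheticConfig:
    """Knobs for the synthetic input generator.

    Defaults emulate the California study window: harvest 1952–2019 peaking
    in 1989, waste characterisation 1960–2018, pulp drawing down to zero
    after 2001.  ``peak_mass`` is the total harvest carbon (Tg C) in the
    peak year.
    """

    seed: int = 0
    start_year: int = 1952
    end_year: int = 2019
    peak_year: int = 1989
    peak_mass: float = 5.0
    decline_rate: float = 0.045
    n_end_uses: int = 224
    pulp_fraction: float = 1.0  # scales the base pulp shares
    pulp_end_year: int | None = 2001
    pulp_end_fraction_by_year: dict[int, float] | None = None
    noise_sd: float = 0.05
    half_life_range: tuple[float, float] = (1.0, 100.0)

    def __post_init__(self) -> None:
        if not self.start_year < self.peak_year < self.end_year:
            raise ValidationError("need start_year < peak_year < end_year")
        if self.peak_mass <= 0:
            raise ValidationError("peak_mass must be positive")
        if not 0.0 <= self.pulp_fraction <= 1.0:
            raise ValidationError("pulp_fraction must lie in [0, 1]")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    def _pulp_scale(self, year: int) -> float:
        """Multiplier on the base wood-pulp shares for one year."""
        if self.pulp_end_fraction_by_year is not None:
            sched = self.pulp_end_fraction_by_year
            keys = sorted(sched)
            prior = [k for k in keys if k <= year]
            return self.pulp_fraction * (sched[prior[-1]] if prior else sched[keys[0]])
        if self.pulp_end_year is not None and year > self.pulp_end_year:
            return 0.0
        return self.pulp_fraction


# ---------------------------------------------------------------------------


def gen_harvest(config: SyntheticConfig) -> pd.DataFrame:
    """Harvest carbon series by harvest class (Tg C/yr): geometric rise to
    the peak year, geometric decline after, multiplicative seeded noise.
    The series maximum is pinned at the peak year by construction."""
    rng = config.rng(1)
    years = np.arange(config.start_year, config.end_year + 1)
    shape = np.where(
        years <= config.peak_year,
        0.35 + 0.65 * (years - config.start_year) / (config.peak_year - config.start_year),
        (1.0 - config.decline_rate) ** (years - config.peak_year),
    )
    noise = np.exp(rng.normal(0.0, config.noise_sd, size=len(years)))
    series = config.peak_mass * shape * noise
    peak_idx = int(np.argmax(years == config.peak_year))
    # keep the stated peak the strict maximum despite noise
    cap = series[peak_idx]
    series[series > cap] = 0.995 * cap
    # noisy class shares, renormalised per year so the yearly total (and
    # hence the peak position) is exactly the series above
    share_noise = {
        cls: share * np.exp(rng.normal(0.0, config.noise_sd / 2, size=len(years)))
        for cls, share in HARVEST_CLASSES.items()
    }
    denom = np.sum(list(share_noise.values()), axis=0)
    rows = []
    for cls, shares in share_noise.items():
        rows.append(
            pd.DataFrame(
                {
                    "year": years,
                    "primary_product": cls,
                    "carbon_mass": series * shares / denom,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _primary_ratio_rows(config: SyntheticConfig) -> pd.DataFrame:
    """Year-by-year allocation of each harvest class across primary
    products; the wood-pulp share follows the phase-out schedule with its
    mass renormalised onto the other products."""
    rows = []
    for year in range(config.start_year, config.end_year + 1):
        scale = config._pulp_scale(year)
        for cls, shares in PRIMARY_SHARES.items():
            pulp = shares["wood pulp"] * scale
            others = {k: v for k, v in shares.items() if k != "wood pulp"}
            other_total = sum(others.values())
            remaining = 1.0 - pulp
            for product, share in others.items():
                rows.append(
                    {
                        "year": year,
                        "source_category": cls,
                        "target_category": product,
                        "fraction": share / other_total * remaining,
                    }
                )
            rows.append(
                {
                    "year": year,
                    "source_category": cls,
                    "target_category": "wood pulp",
                    "fraction": pulp,
                }
            )
    return pd.DataFrame(rows)


def _end_use_names(config: SyntheticConfig) -> dict[str, list[str]]:
    """Deterministic end-use labels per primary product, n_end_uses total
    (including the single wood-pulp and fuelwood end uses)."""
    n_named = max(config.n_end_uses - 2, len(_EU_TEMPLATES))
    primaries = list(_EU_TEMPLATES)
    per = [n_named // len(primaries)] * len(primaries)
    for i in range(n_named % len(primaries)):
        per[i] += 1
    names: dict[str, list[str]] = {}
    for count, primary in zip(per, primaries):
        bases, tags = _EU_TEMPLATES[primary]
        if isinstance(tags, str):
            tags = [tags]
        labels = []
        k = 0
        while len(labels) < count:
            base = bases[k % len(bases)]
            tag = tags[(k // len(bases)) % len(tags)]
            serial = k // (len(bases) * len(tags))
            suffix = f" {serial + 1}" if serial else ""
            labels.append(f"{base}{suffix}, {tag}")
            k += 1
        names[primary] = labels
    names["wood pulp"] = ["wood pulp"]
    names["fuelwood"] = ["fuelwood"]
    return names


def _fate_schedule(year: int, kind: str) -> dict[str, float]:
    """Piecewise-linear discard-fate proportions for the aggregate wood and
    paper categories; the landfill share is the remainder, so rows sum to 1
    exactly.  Dumps decline to 2% after 1990; landfilling rises with
    visible steps through the 1970s and 1980s."""

    def interp(knots: dict[int, float]) -> float:
        xs = sorted(knots)
        return float(np.interp(year, xs, [knots[x] for x in xs]))

    if kind == "wood":
        dump = interp({1952: 0.55, 1970: 0.35, 1980: 0.15, 1990: 0.02, 2019: 0.02})
        recovered = interp({1952: 0.02, 1990: 0.06, 2019: 0.12})
        bwoec = interp({1952: 0.15, 1990: 0.08, 2019: 0.05})
        composted = 0.0
    else:
        dump = interp({1952: 0.55, 1970: 0.35, 1980: 0.15, 1990: 0.02, 2019: 0.02})
        recovered = interp({1952: 0.10, 1990: 0.22, 2019: 0.35})
        bwoec = interp({1952: 0.10, 1990: 0.05, 2019: 0.03})
        composted = interp({1952: 0.0, 1999: 0.0, 2005: 0.01, 2019: 0.02})
    bwec = 0.0  # end-of-life burning for energy: none by default
    landfill = 1.0 - (dump + recovered + bwoec + composted + bwec)
    return {
        "recovered": recovered,
        "burned_with_energy_capture": bwec,
        "burned_without_energy_capture": bwoec,
        "composted": composted,
        "landfill": landfill,
        "dump": dump,
    }


def gen_ratio_tables(config: SyntheticConfig) -> dict[str, pd.DataFrame]:
    """Primary ratios, end-use ratios, discard fates, end-use parameters and
    decay parameters, all satisfying the sum-to-one invariants."""
    rng = config.rng(2)
    primary_ratios = _primary_ratio_rows(config)
    names = _end_use_names(config)

    eu_rows, ratio_rows = [], []
    years = list(range(config.start_year, config.end_year + 1))
    lo, hi = config.half_life_range
    for primary, labels in names.items():
        weights = rng.dirichlet(np.full(len(labels), 2.0))
        half_lives = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(labels)))
        for label, w, hl in zip(labels, weights, half_lives):
            if primary == "wood pulp":
                category, hl, fuel = "paper", 2.5, False
            elif primary == "fuelwood":
                category, fuel = "wood", True
            else:
                category, fuel = "wood", False
            eu_rows.append(
                {
                    "end_use": label,
                    "half_life": float(hl),
                    "discard_category": category,
                    "fuelwood_flag": fuel,
                }
            )
            for year in years:
                ratio_rows.append(
                    {
                        "year": year,
                        "source_category": primary,
                        "target_category": label,
                        "fraction": float(w),
                    }
                )

    fate_rows = [
        {"year": year, "discard_category": kind, "fate": fate, "fraction": frac}
        for year in years
        for kind in ("wood", "paper")
        for fate, frac in _fate_schedule(year, kind).items()
    ]

    return {
        "primary_ratios": primary_ratios,
        "end_use_ratios": pd.DataFrame(ratio_rows),
        "discard_fates": pd.DataFrame(fate_rows),
        "end_use_params": pd.DataFrame(eu_rows),
        "decay_params": default_decay_params_table(),
    }


def gen_waste_characterization(config: SyntheticConfig) -> pd.DataFrame:
    """Five-category paper tonnage series, 1960–2018: corrugated share
    rising, newspaper declining, smooth trends with seeded noise."""
    rng = config.rng(3)
    years = np.arange(1960, 2019)
    u = (years - years[0]) / (years[-1] - years[0])
    shares = {
        "corrugated": 0.30 + 0.12 * u,
        "newspaper": 0.25 - 0.17 * u,
        "office": 0.18 - 0.06 * u,
        "coated": 0.07 - 0.02 * u,
    }
    shares["other_mixed_paper"] = 1.0 - sum(shares.values())
    total = 30_000.0 * (1.0 + 1.4 * u)  # thousand tons, rising
    rows = []
    for cat in PAPER_SPLIT_CATEGORIES:
        noise = np.exp(rng.normal(0.0, 0.03, size=len(years)))
        rows.append(
            pd.DataFrame(
                {
                    "year": years,
                    "paper_category": cat,
                    "tonnage": np.maximum(total * shares[cat] * noise, 0.0),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def gen_inputs(config: SyntheticConfig | None = None) -> ModelInputs:
    """Full synthetic input bundle, validated."""
    config = config or SyntheticConfig()
    tables = gen_ratio_tables(config)
    inputs = ModelInputs(
        harvest=gen_harvest(config),
        primary_ratios=tables["primary_ratios"],
        end_use_ratios=tables["end_use_ratios"],
        discard_fates=tables["discard_fates"],
        decay_params=tables["decay_params"],
        end_use_params=tables["end_use_params"],
        waste_characterization=gen_waste_characterization(config),
    )
    inputs.validate()
    return inputs
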