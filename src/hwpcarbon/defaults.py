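"""Default parameter values and category vocabularies.

The solid-waste parameterisation distinguishes two aggregate discard
categories (wood, paper) which scenario updates disaggregate into
product-specific categories.  Fixed-carbon ratios are the fractions of
landfilled carbon assumed permanently inert; half-lives drive first-order
decay of everything else.
"""

from __future__ import annotations

import pandas as pd

# The six recognised discard fates.
FATES = (
    "recovered",
    "burned_with_energy_capture",
    "burned_without_energy_capture",
    "composted",
    "landfill",
    "dump",
)

# Wood-derived discard categories: the aggregate catchall plus the two
# product-specific categories the crosswalk introduces ("plywood" also
# covers oriented strand board and medium-density fiberboard).
WOOD_CATEGORIES = ("wood", "lumber", "plywood")

# Paper-derived discard categories: the aggregate catchall plus the five
# waste-characterisation paper categories.
PAPER_CATEGORIES = (
    "paper",
    "corrugated",
    "newspaper",
    "office",
    "coated",
    "other_mixed_paper",
)

# The five specific paper categories used for new paper end-use ratios.
PAPER_SPLIT_CATEGORIES = (
    "corrugated",
    "newspaper",
    "office",
    "coated",
    "other_mixed_paper",
)

# Default discard parameters: dump half-life (yr), landfill fixed-carbon
# ratio, landfill half-life (yr), recovered half-life (yr).
DEFAULT_DECAY_PARAMS = {
    "paper": (8.25, 0.44, 14.5, 2.6),
    "wood": (16.5, 0.77, 29.0, 2.6),
}

DEFAULT_FIXED_RATIO = {"wood": 0.77, "paper": 0.44}

# EPA WARM v15 product-specific fixed-carbon ratios for landfills.
# "wood_flooring" has no matching end use in the end-use list and is never
# applied by a scenario, but is part of the published parameter table.
EPA_FIXED_RATIOS = {
    "corrugated": 0.55,
    "newspaper": 0.84,
    "office": 0.12,
    "coated": 0.74,
    "lumber": 0.88,
    "plywood": 0.84,  # medium-density fiberboard value, applied to OSB/MDF/plywood
    "wood_flooring": 0.95,
}

EPA_WOOD_PRODUCTS = ("lumber", "plywood", "wood_flooring")
EPA_PAPER_PRODUCTS = ("corrugated", "newspaper", "office", "coated")

# IPCC North American defaults for the non-degradable fraction.
IPCC_FIXED_RATIOS = {"wood": 0.9, "paper": 0.5}

# Recognised scenario names.
SCENARIO_NAMES = (
    "default",
    "epa_paper_only",
    "epa_wood_only",
    "epa_paper_and_wood",
    "dumps_reroute",
    "combined",
    "ipcc",
)

# Year after which open dumps are assumed closed under the reroute scenario.
DEFAULT_DUMP_CUTOFF_YEAR = 1995

# Mass of CO2 per mass of C (molar ratio 44/12).
CO2_PER_C = 44.0 / 12.0


def category_kind(category: str) -> str:
    """Return ``"wood"`` or ``"paper"`` for a discard category label."""
    if category in WOOD_CATEGORIES:
        return "wood"
    if category in PAPER_CATEGORIES:
        return "paper"
    raise KeyError(f"unknown discard category: {category!r}")


def default_decay_params_table(categories=("wood", "paper")) -> pd.DataFrame:
    """Default decay-parameter table; disaggregated categories inherit
    their parent aggregate's values."""
    rows = []
    for cat in categories:
        dump_hl, fixed, lf_hl, rec_hl = DEFAULT_DECAY_PARAMS[category_kind(cat)]
        rows.append(
            {
                "discard_category": cat,
                "dump_half_life": dump_hl,
                "landfill_fixed_ratio": fixed,
                "landfill_half_life": lf_hl,
                "recovered_half_life": rec_hl,
            }
        )
    return pd.DataFrame(rows)
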