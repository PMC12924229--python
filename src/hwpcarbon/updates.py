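"""Parameter-update procedures for product-specific waste accounting.

Four updates, composable through :func:`prepare_scenario`:

* ``crosswalk_wood`` — disaggregate the aggregate "wood" discard category
  into lumber, plywood (covering plywood, oriented strand board and
  medium-density fiberboard) and a generic wood catchall, by keyword
  matching on end-use labels;
* ``build_paper_end_use_ratios`` — turn a waste-characterisation tonnage
  series into year-by-year ratios distributing wood pulp across five paper
  categories (corrugated, newspaper, office, coated, other mixed paper);
* ``apply_fixed_carbon_scenario`` — swap landfill fixed-carbon ratios for a
  named parameter set (EPA product-specific values, IPCC North American
  bulk defaults), catchall categories keeping the model defaults;
* ``reroute_dumps`` — close open dumps from a cutoff year (default 1995),
  shifting their discard share to landfills.

Disaggregated categories inherit the parent's discard-fate proportions and
half-lives; only the fixed-carbon ratios differ.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .defaults import (
    DEFAULT_DUMP_CUTOFF_YEAR,
    EPA_FIXED_RATIOS,
    IPCC_FIXED_RATIOS,
    PAPER_SPLIT_CATEGORIES,
    category_kind,
)
from .errors import (
    AllZeroYearError,
    AmbiguousCrosswalkError,
    UnknownCategoryError,
    UnknownScenarioError,
)
from .params import FixedCarbonScenario, ModelInputs

WOOD_PULP_LABEL = "wood pulp"


# ---------------------------------------------------------------------------
# crosswalk
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CrosswalkRule:
    keywords: tuple[str, ...]
    target: str
    priority: int


@dataclasses.dataclass
class Crosswalk:
    """Keyword matcher assigning end uses to discard categories.

    Matching is case-insensitive substring search over the end-use label.
    The matching rule with the lowest priority number wins; two matches at
    equal priority with different targets are a hard error rather than a
    silent first-match.  Unmatched end uses keep the catchall category.
    """

    rules: list[CrosswalkRule]

    def match(self, label: str) -> str | None:
        text = label.lower()
        hits = [
            rule
            for rule in self.rules
            if any(kw in text for kw in rule.keywords)
        ]
        if not hits:
            return None
        best = min(rule.priority for rule in hits)
        targets = {rule.target for rule in hits if rule.priority == best}
        if len(targets) > 1:
            raise AmbiguousCrosswalkError(
                f"end use {label!r} matches {sorted(targets)} at priority {best}"
            )
        return targets.pop()


def default_crosswalk() -> Crosswalk:
    """Crosswalk from end-use labels to product-specific wood categories."""
    return Crosswalk(
        rules=[
            CrosswalkRule(("lumber",), "lumber", 1),
            CrosswalkRule(
                ("plywood", "oriented strand board", "medium-density fiberboard"),
                "plywood",
                1,
            ),
        ]
    )


def read_crosswalk(path) -> Crosswalk:
    """Read crosswalk.csv (pattern, target, priority); patterns with
    identical (target, priority) are merged into one keyword rule."""
    df = pd.read_csv(path)
    rules = [
        CrosswalkRule(tuple(sub["pattern"].str.lower()), target, int(priority))
        for (target, priority), sub in df.groupby(["target", "priority"])
    ]
    return Crosswalk(rules=rules)


def crosswalk_wood(
    end_use_params: pd.DataFrame, crosswalk: Crosswalk | None = None
) -> pd.DataFrame:
    """Re-map wood-discard end uses to product-specific categories.

    Only end uses currently in the aggregate "wood" category are touched;
    paper mappings are left untouched.  Unmatched wood end uses remain in
    "wood" as the catchall.
    """
    crosswalk = default_crosswalk() if crosswalk is None else crosswalk
    out = end_use_params.copy()
    wood_mask = out["discard_category"] == "wood"
    out.loc[wood_mask, "discard_category"] = [
        crosswalk.match(label) or "wood" for label in out.loc[wood_mask, "end_use"]
    ]
    return out


# ---------------------------------------------------------------------------
# paper end-use ratios
# ---------------------------------------------------------------------------


def build_paper_end_use_ratios(
    series: pd.DataFrame, years_needed: range | list[int]
) -> pd.DataFrame:
    """Normalise a waste-characterisation tonnage series into per-year
    wood-pulp-to-paper-category ratios.

    For each year covered by the series, fraction(category) =
    tonnage / total tonnage.  Years before the series start take the
    earliest year's fractions; years after take the latest (constant
    extrapolation).  A year with zero total tonnage is an error.
    """
    wide = (
        series.pivot_table(
            index="year", columns="paper_category", values="tonnage", aggfunc="sum"
        )
        .reindex(columns=list(PAPER_SPLIT_CATEGORIES))
        .fillna(0.0)
        .sort_index()
    )
    totals = wide.sum(axis=1)
    zero = totals[totals <= 0]
    if not zero.empty:
        raise AllZeroYearError(
            f"waste_characterization: zero total tonnage in year {int(zero.index[0])}"
        )
    fractions = wide.div(totals, axis=0)
    first, last = fractions.index.min(), fractions.index.max()
    rows = []
    for year in years_needed:
        src = min(max(year, first), last)
        for cat in PAPER_SPLIT_CATEGORIES:
            rows.append(
                {
                    "year": int(year),
                    "source_category": WOOD_PULP_LABEL,
                    "target_category": cat,
                    "fraction": float(fractions.loc[src, cat]),
                }
            )
    return pd.DataFrame(rows)


def expand_paper_end_uses(
    inputs: ModelInputs, paper_ratios: pd.DataFrame
) -> ModelInputs:
    """Split every paper-discard (wood pulp) end use into the five specific
    paper categories using per-year ratios.

    Each affected end use ``e`` with end-use-ratio fraction ``q`` becomes
    five end uses ``e (cat)`` with fractions ``q * p_cat(year)``, the same
    in-use half-life, and discard category ``cat``.  Fate and decay rows
    for the new categories are inherited from the parent "paper" category.
    """
    out = inputs.copy()
    eup = out.end_use_params
    pulp_mask = (eup["discard_category"] == "paper") & (~eup["fuelwood_flag"])
    pulp_uses = eup.loc[pulp_mask, "end_use"].tolist()
    if not pulp_uses:
        return out

    p = paper_ratios.rename(
        columns={"target_category": "paper_category", "fraction": "p"}
    )[["year", "paper_category", "p"]]

    # expand end-use parameter rows
    new_rows = []
    for _, row in eup[pulp_mask].iterrows():
        for cat in PAPER_SPLIT_CATEGORIES:
            r = row.copy()
            r["end_use"] = f"{row['end_use']} ({cat})"
            r["discard_category"] = cat
            new_rows.append(r)
    out.end_use_params = pd.concat(
        [eup[~pulp_mask], pd.DataFrame(new_rows)], ignore_index=True
    )

    # expand allocation rows
    ratios = out.end_use_ratios
    hit = ratios["target_category"].isin(pulp_uses)
    expanded = ratios[hit].merge(p, on="year")
    expanded["target_category"] = (
        expanded["target_category"] + " (" + expanded["paper_category"] + ")"
    )
    expanded["fraction"] = expanded["fraction"] * expanded["p"]
    out.end_use_ratios = pd.concat(
        [ratios[~hit], expanded[["year", "source_category", "target_category", "fraction"]]],
        ignore_index=True,
    )

    out.discard_fates = inherit_category_rows(
        out.discard_fates, "paper", PAPER_SPLIT_CATEGORIES
    )
    out.decay_params = inherit_decay_rows(
        out.decay_params, "paper", PAPER_SPLIT_CATEGORIES
    )
    return out


def inherit_category_rows(
    fates: pd.DataFrame, parent: str, children
) -> pd.DataFrame:
    """Copy the parent category's discard-fate rows to each child category
    that does not already have rows."""
    existing = set(fates["discard_category"].unique())
    blocks = [fates]
    parent_rows = fates[fates["discard_category"] == parent]
    for child in children:
        if child not in existing:
            rows = parent_rows.copy()
            rows["discard_category"] = child
            blocks.append(rows)
    return pd.concat(blocks, ignore_index=True)


def inherit_decay_rows(
    decay_params: pd.DataFrame, parent: str, children
) -> pd.DataFrame:
    """Copy the parent category's decay-parameter row to each missing child."""
    existing = set(decay_params["discard_category"].unique())
    blocks = [decay_params]
    parent_row = decay_params[decay_params["discard_category"] == parent]
    for child in children:
        if child not in existing:
            row = parent_row.copy()
            row["discard_category"] = child
            blocks.append(row)
    return pd.concat(blocks, ignore_index=True)


# ---------------------------------------------------------------------------
# fixed-carbon scenarios
# ---------------------------------------------------------------------------


def apply_fixed_carbon_scenario(
    decay_params: pd.DataFrame, scenario: FixedCarbonScenario
) -> pd.DataFrame:
    """Return decay parameters with the scenario's landfill fixed-carbon
    overrides applied; an override naming an absent category is an error."""
    out = decay_params.copy()
    categories = set(out["discard_category"])
    for cat, value in scenario.ratio_overrides.items():
        if cat not in categories:
            raise UnknownCategoryError(
                f"scenario {scenario.name!r}: override for category {cat!r} "
                f"not present in this run"
            )
        out.loc[out["discard_category"] == cat, "landfill_fixed_ratio"] = value
    return out


def make_scenario(
    name: str,
    categories=None,
    cutoff_year: int = DEFAULT_DUMP_CUTOFF_YEAR,
) -> FixedCarbonScenario:
    """Build the named fixed-carbon scenario.

    EPA scenarios override the product-specific categories they update,
    catchalls ("wood", "paper", "other_mixed_paper") keeping the model
    defaults.  The IPCC scenario applies 0.9 to every wood-derived and 0.5
    to every paper-derived category present in ``categories``.
    """
    epa_wood = {c: EPA_FIXED_RATIOS[c] for c in ("lumber", "plywood")}
    epa_paper = {c: EPA_FIXED_RATIOS[c] for c in ("corrugated", "newspaper", "office", "coated")}
    if name == "default":
        return FixedCarbonScenario(name)
    if name == "epa_paper_only":
        return FixedCarbonScenario(name, dict(epa_paper))
    if name == "epa_wood_only":
        return FixedCarbonScenario(name, dict(epa_wood))
    if name == "epa_paper_and_wood":
        return FixedCarbonScenario(name, {**epa_paper, **epa_wood})
    if name == "dumps_reroute":
        return FixedCarbonScenario(name, reroute_dumps=True, cutoff_year=cutoff_year)
    if name == "combined":
        return FixedCarbonScenario(
            name, {**epa_paper, **epa_wood}, reroute_dumps=True, cutoff_year=cutoff_year
        )
    if name == "ipcc":
        cats = list(categories) if categories is not None else ["wood", "paper"]
        overrides = {c: IPCC_FIXED_RATIOS[category_kind(c)] for c in cats}
        return FixedCarbonScenario(name, overrides)
    raise UnknownScenarioError(f"unknown scenario name {name!r}")


# ---------------------------------------------------------------------------
# dump rerouting
# ---------------------------------------------------------------------------


def reroute_dumps(
    fates: pd.DataFrame, cutoff_year: int = DEFAULT_DUMP_CUTOFF_YEAR
) -> pd.DataFrame:
    """From ``cutoff_year`` on, close dumps: the dump fraction is added to
    the landfill fraction and set to zero.  Idempotent; earlier years are
    untouched and rows still sum to 1."""
    out = fates.copy()
    late = out["year"] >= cutoff_year
    dump_rows = out[late & (out["fate"] == "dump")]
    moved = dump_rows.set_index(["year", "discard_category"])["fraction"]
    lf_mask = late & (out["fate"] == "landfill")
    keys = list(zip(out.loc[lf_mask, "year"], out.loc[lf_mask, "discard_category"]))
    out.loc[lf_mask, "fraction"] = (
        out.loc[lf_mask, "fraction"].to_numpy()
        + moved.reindex(keys).fillna(0.0).to_numpy()
    )
    out.loc[late & (out["fate"] == "dump"), "fraction"] = 0.0
    return out


# ---------------------------------------------------------------------------
# scenario assembly
# ---------------------------------------------------------------------------

_NEEDS_WOOD_SPLIT = {"epa_wood_only", "epa_paper_and_wood", "combined"}
_NEEDS_PAPER_SPLIT = {"epa_paper_only", "epa_paper_and_wood", "combined"}


def prepare_scenario(
    inputs: ModelInputs,
    scenario: FixedCarbonScenario | str,
    cutoff_year: int = DEFAULT_DUMP_CUTOFF_YEAR,
    crosswalk: Crosswalk | None = None,
) -> ModelInputs:
    """Apply a named scenario's full parameter-update pipeline to inputs.

    EPA wood scenarios disaggregate the wood category via the crosswalk;
    EPA paper scenarios build paper end-use ratios from the input bundle's
    waste-characterisation series and expand wood-pulp end uses; dump
    scenarios reroute post-cutoff dump shares to landfills.  Fixed-carbon
    overrides are applied last, to whatever categories then exist.
    """
    name = scenario if isinstance(scenario, str) else scenario.name
    if name not in (
        "default",
        "epa_paper_only",
        "epa_wood_only",
        "epa_paper_and_wood",
        "dumps_reroute",
        "combined",
        "ipcc",
    ):
        raise UnknownScenarioError(f"unknown scenario name {name!r}")

    out = inputs.copy()
    if name in _NEEDS_WOOD_SPLIT:
        out.end_use_params = crosswalk_wood(out.end_use_params, crosswalk)
        new_wood = sorted(
            set(out.end_use_params["discard_category"]) & {"lumber", "plywood"}
        )
        out.discard_fates = inherit_category_rows(out.discard_fates, "wood", new_wood)
        out.decay_params = inherit_decay_rows(out.decay_params, "wood", new_wood)
    if name in _NEEDS_PAPER_SPLIT:
        if out.waste_characterization is None:
            raise UnknownCategoryError(
                f"scenario {name!r} needs a waste-characterization series to "
                f"build paper end-use ratios"
            )
        years = sorted(out.discard_fates["year"].unique())
        paper_ratios = build_paper_end_use_ratios(out.waste_characterization, years)
        out = expand_paper_end_uses(out, paper_ratios)

    if isinstance(scenario, str):
        scenario = make_scenario(
            name,
            categories=sorted(out.end_use_params["discard_category"].unique()),
            cutoff_year=cutoff_year,
        )
    if scenario.reroute_dumps:
        out.discard_fates = reroute_dumps(out.discard_fates, scenario.cutoff_year)
    out.decay_params = apply_fixed_carbon_scenario(out.decay_params, scenario)
    return out
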