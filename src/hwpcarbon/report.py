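"""Summary reporting: cumulative totals, scenario deltas, product tables.

Sign convention follows greenhouse-gas inventory practice: carbon *storage*
is reported negative, *emissions* positive, in MMT CO2Eq (carbon mass
times 44/12; 1 Tg C = 1 MMT C).  Percent changes are expressed so that
deeper storage is negative and reduced emissions positive.  All identities
hold before rounding; presentation rounds to 2 decimals.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple

import numpy as np
import pandas as pd

from .defaults import CO2_PER_C, PAPER_CATEGORIES, WOOD_CATEGORIES
from .engine import AnnualLedger
from .errors import ValidationError


def to_co2eq(mass: float):
    """Convert carbon mass (Tg C) to MMT CO2Eq (× 44/12)."""
    return mass * CO2_PER_C


class CumulativeTotals(NamedTuple):
    swds: float     # carbon in landfills + dumps, negative (storage)
    ewoec: float    # cumulative emissions without energy capture, positive
    ewec: float     # cumulative emissions with energy capture, positive
    in_use: float   # products in use, negative (storage)


def cumulative_totals(ledger: AnnualLedger, year: int | None = None) -> CumulativeTotals:
    """Cumulative pool totals at a reported year, in MMT CO2Eq."""
    year = ledger.final_year if year is None else year
    swds_c = (
        ledger.value(year, "landfill_fixed")
        + ledger.value(year, "landfill_decayable")
        + ledger.value(year, "dump")
    )
    return CumulativeTotals(
        swds=-to_co2eq(swds_c),
        ewoec=to_co2eq(ledger.value(year, "cum_ewoec")),
        ewec=to_co2eq(ledger.value(year, "cum_ewec")),
        in_use=-to_co2eq(ledger.value(year, "in_use")),
    )


def mean_annual(cumulative: float, n_years: int) -> float:
    """Mean annual change: cumulative total divided by reporting years."""
    if n_years <= 0:
        raise ValidationError("n_years must be positive")
    return cumulative / n_years


def percent_change(alt: float, baseline: float) -> float:
    """Scenario change relative to baseline, in percent.

    Computed as ``100 * (baseline - alt) / baseline``: for a (negative)
    storage total, deeper storage gives a negative percent; for a
    (positive) emissions total, reduced emissions give a positive percent.
    """
    if baseline == 0:
        raise ValidationError("percent change undefined for zero baseline")
    return 100.0 * (baseline - alt) / baseline


@dataclasses.dataclass
class ScenarioReport:
    """One scenario's summary versus a baseline (all MMT CO2Eq)."""

    name: str
    cumulative_swds: float
    cumulative_ewoec: float
    mean_annual_swds: float
    mean_annual_ewoec: float
    delta_swds: float            # alt - baseline (negative = deeper storage)
    delta_ewoec: float           # alt - baseline (negative = fewer emissions)
    percent_change_swds: float
    percent_change_ewoec: float
    n_years: int


def summarize_scenario(
    ledger: AnnualLedger, baseline: AnnualLedger, name: str
) -> ScenarioReport:
    if ledger.final_year != baseline.final_year:
        raise ValidationError("scenario and baseline ledgers end in different years")
    alt = cumulative_totals(ledger)
    base = cumulative_totals(baseline)
    n = ledger.n_years
    return ScenarioReport(
        name=name,
        cumulative_swds=alt.swds,
        cumulative_ewoec=alt.ewoec,
        mean_annual_swds=mean_annual(alt.swds, n),
        mean_annual_ewoec=mean_annual(alt.ewoec, n),
        delta_swds=alt.swds - base.swds,
        delta_ewoec=alt.ewoec - base.ewoec,
        percent_change_swds=percent_change(alt.swds, base.swds),
        percent_change_ewoec=percent_change(alt.ewoec, base.ewoec),
        n_years=n,
    )


def scenario_table(
    ledgers: dict[str, AnnualLedger], baseline: str = "default"
) -> pd.DataFrame:
    """Scenario-comparison table: one row per scenario with cumulative
    totals, mean-annual values, deltas and percent changes vs baseline."""
    if baseline not in ledgers:
        raise ValidationError(f"baseline scenario {baseline!r} not among ledgers")
    if len(ledgers) < 2:
        raise ValidationError("need at least two scenarios to compare")
    base = ledgers[baseline]
    rows = []
    for name, ledger in ledgers.items():
        rep = summarize_scenario(ledger, base, name)
        rows.append(
            {
                "scenario": name,
                "cumulative_swds": rep.cumulative_swds,
                "cumulative_ewoec": rep.cumulative_ewoec,
                "mean_annual_swds": rep.mean_annual_swds,
                "mean_annual_ewoec": rep.mean_annual_ewoec,
                "delta_swds": rep.delta_swds if name != baseline else 0.0,
                "delta_ewoec": rep.delta_ewoec if name != baseline else 0.0,
                "percent_change_swds": rep.percent_change_swds if name != baseline else 0.0,
                "percent_change_ewoec": rep.percent_change_ewoec if name != baseline else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _landfill_columns(ledger: AnnualLedger, year: int) -> pd.DataFrame:
    """Per-category cumulative landfill storage (negative) and emissions
    (positive) at a reported year, MMT CO2Eq, plus mean-annual columns."""
    t = ledger._year_index(year)
    stock = (
        ledger.by_category["landfill_fixed"][t]
        + ledger.by_category["landfill_decayable"][t]
    )
    loss = ledger.by_category["cum_landfill_loss"][t]
    n = t + 1
    return pd.DataFrame(
        {
            "category": ledger.categories,
            "storage": -to_co2eq(stock),
            "emissions": to_co2eq(loss),
            "mean_annual_storage": -to_co2eq(stock) / n,
            "mean_annual_emissions": to_co2eq(loss) / n,
        }
    )


def landfill_product_table(
    ledger: AnnualLedger,
    baseline_ledger: AnnualLedger | None = None,
    year: int | None = None,
) -> pd.DataFrame:
    """Landfill carbon storage and emissions by product category, with
    wood-group and paper-group subtotals and grand totals.

    When a baseline ledger is given its columns are appended with a
    ``_baseline`` suffix (aligned on category where possible; the two runs
    may have different category sets) and group/total rows include both.
    """
    year = ledger.final_year if year is None else year
    table = _landfill_columns(ledger, year)
    value_cols = ["storage", "emissions", "mean_annual_storage", "mean_annual_emissions"]
    if baseline_ledger is not None:
        base = _landfill_columns(baseline_ledger, year)
        table = table.merge(base, on="category", how="outer", suffixes=("", "_baseline"))
        value_cols += [c + "_baseline" for c in value_cols]
    table = table.sort_values("category").reset_index(drop=True)

    def group_row(label: str, members) -> dict:
        sub = table[table["category"].isin(members)]
        row = {"category": label}
        for col in value_cols:
            row[col] = sub[col].sum()
        return row

    groups = pd.DataFrame(
        [
            group_row("wood group", WOOD_CATEGORIES),
            group_row("paper group", PAPER_CATEGORIES),
            group_row("all products", set(table["category"])),
        ]
    )
    return pd.concat([table, groups], ignore_index=True).fillna(0.0)


def annual_series(ledger: AnnualLedger, basis: str = "net") -> pd.DataFrame:
    """Per-year landfill storage added (negative) and emissions (positive),
    MMT CO2Eq.

    ``basis="net"`` counts the year's landfill inflow minus that year's
    decay losses as storage added; ``basis="gross"`` counts the raw inflow.
    """
    if basis not in ("net", "gross"):
        raise ValidationError("basis must be 'net' or 'gross'")
    inflow = ledger.total("landfill_inflow")
    loss = ledger.total("landfill_loss")
    storage = inflow - loss if basis == "net" else inflow
    return pd.DataFrame(
        {
            "year": ledger.years,
            "storage_added": -to_co2eq(storage.to_numpy()),
            "emissions": to_co2eq(loss.to_numpy()),
        }
    )


def plot_annual_series(series: pd.DataFrame, path) -> None:
    """Bar chart of annual landfill storage (below axis) and emissions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4.5))
    ax.bar(series["year"], series["storage_added"], color="#2a6f4e", label="storage added")
    ax.bar(series["year"], series["emissions"], color="#b2532a", label="emissions")
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xlabel("year")
    ax.set_ylabel("MMT CO2Eq (storage negative)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cumulative(ledgers: dict[str, AnnualLedger], path) -> None:
    """Cumulative SWDS (negative) and EWOEC (positive) trajectories."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4.5))
    for name, ledger in ledgers.items():
        swds = -(
            ledger.total("landfill_fixed")
            + ledger.total("landfill_decayable")
            + ledger.total("dump")
        ) * CO2_PER_C
        ewoec = ledger.total("cum_ewoec") * CO2_PER_C
        (line,) = ax.plot(ledger.years, swds, label=f"{name} SWDS")
        ax.plot(ledger.years, ewoec, linestyle="--", color=line.get_color(),
                label=f"{name} EWOEC")
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xlabel("year")
    ax.set_ylabel("MMT CO2Eq (storage negative)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
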