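"""Annual-time-step carbon accounting for harvested wood products.

The engine follows each year's harvested carbon through primary products and
end uses (first-order decay in service), then routes discarded mass across
six fates: recovery, burning with/without energy capture, composting,
landfills and dumps.  Landfilled carbon splits into a permanently inert
("fixed") fraction and a decayable fraction subject to first-order decay;
dumps decay faster (aerobic) and hold no fixed fraction.  Cumulative
emissions are ledgered as EWEC (with energy capture) and EWOEC (without).

Within a simulated year the order of operations is:

1. existing pools decay (products in use, recovered, landfill decayable,
   dumps) — a cohort entering a pool therefore takes its first decay loss
   the year *after* entry;
2. the recovered pool's outflow re-enters the discarded stream of the same
   end use (one-year re-discard lag);
3. the year's harvest is allocated to end uses; fuelwood-flagged
   allocations go straight to EWEC;
4. discarded mass is split across the six fates at the year's proportions;
   landfill inflow splits into fixed and decayable; burned-without-energy
   and composted inflows emit in the disposal year.

All solid-waste pools are tracked per end use and aggregated to discard
categories only when the ledger is built.  Because first-order decay is
memoryless this pooled bookkeeping is exact, and because disaggregating a
discard category is then a pure relabelling, a sub-categorisation whose
sub-categories inherit the parent's parameters reproduces the aggregate
run's totals bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EngineError, MissingParameterError, ValidationError
from .params import ModelInputs

__all__ = [
    "EngineOptions",
    "PoolState",
    "AnnualLedger",
    "decay_fraction",
    "run_simulation",
    "swds_total",
    "write_ledger",
    "read_ledger",
]

# Per-category ledger quantities: pool stocks, cumulative ledgers, annual flows.
STOCK_QUANTITIES = (
    "in_use",
    "recovered",
    "landfill_fixed",
    "landfill_decayable",
    "dump",
)
CUM_QUANTITIES = ("cum_ewoec", "cum_landfill_loss", "cum_dump_loss", "cum_compost")
FLOW_QUANTITIES = (
    "discarded",
    "landfill_inflow",
    "landfill_loss",
    "dump_loss",
    "recovered_outflow",
)
CATEGORY_QUANTITIES = STOCK_QUANTITIES + CUM_QUANTITIES + FLOW_QUANTITIES
TOTAL_ONLY_QUANTITIES = ("cum_ewec", "cum_harvest")
TOTAL_LABEL = "total"


def _REPR_FLOAT(x) -> str:
    """Shortest round-trip float serialisation for CSV output."""
    return repr(float(x))


def decay_fraction(half_life: float) -> float:
    """Annual first-order loss fraction, ``1 - 2**(-1/half_life)``.

    >>> decay_fraction(1.0)
    0.5
    """
    if half_life <= 0:
        raise ValidationError(f"half-life must be positive, got {half_life}")
    return -np.expm1(-np.log(2.0) / half_life)


@dataclasses.dataclass
class EngineOptions:
    """Simulation window and reporting conventions.

    With ``shift_year`` the state computed through year ``t`` is reported
    under year ``t + 1`` (emissions of one year are reported the next), so a
    1952–2019 harvest yields a 1953–2020 ledger.
    """

    shift_year: bool = True
    start_year: int | None = None
    end_year: int | None = None
    dump_is_anaerobic: bool = False  # reserved; dumps currently always aerobic

    def __post_init__(self) -> None:
        if (
            self.start_year is not None
            and self.end_year is not None
            and self.end_year < self.start_year
        ):
            raise ValidationError("end_year must be >= start_year")


@dataclasses.dataclass
class PoolState:
    """Pool stocks and cumulative ledgers at one reported year (Tg C)."""

    in_use: dict[str, float]
    recovered: dict[str, float]
    landfill_fixed: dict[str, float]
    landfill_decayable: dict[str, float]
    dump: dict[str, float]
    cum_ewec: float
    cum_ewoec: dict[str, float]
    cum_compost_emit: float


def swds_total(state: PoolState) -> float:
    """Total carbon in solid waste disposal sites: landfills (fixed +
    decayable) plus dumps, summed over discard categories (Tg C)."""
    return (
        sum(state.landfill_fixed.values())
        + sum(state.landfill_decayable.values())
        + sum(state.dump.values())
    )


class AnnualLedger:
    """Per-year pool stocks, cumulative ledgers and annual flows.

    Values are held as dense arrays: ``by_category[quantity]`` has shape
    (n_years, n_categories) and ``totals[quantity]`` shape (n_years,).
    Totals are summed over end uses in a fixed sorted order at build time,
    independently of the category grouping.
    """

    def __init__(
        self,
        years: np.ndarray,
        categories: list[str],
        by_category: dict[str, np.ndarray],
        totals: dict[str, np.ndarray],
    ) -> None:
        self.years = np.asarray(years, dtype=int)
        if len(self.years) > 1 and not (np.diff(self.years) > 0).all():
            raise ValidationError("ledger years must be strictly increasing")
        self.categories = list(categories)
        self.by_category = by_category
        self.totals = totals

    # -- accessors ---------------------------------------------------------

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def final_year(self) -> int:
        return int(self.years[-1])

    def _year_index(self, year: int) -> int:
        idx = np.searchsorted(self.years, year)
        if idx >= len(self.years) or self.years[idx] != year:
            raise KeyError(f"year {year} not in ledger ({self.years[0]}..{self.final_year})")
        return int(idx)

    def total(self, quantity: str) -> pd.Series:
        """Per-year totals of one quantity, indexed by reported year."""
        return pd.Series(self.totals[quantity], index=self.years, name=quantity)

    def category_frame(self, quantity: str) -> pd.DataFrame:
        """Per-year, per-category values of one quantity."""
        return pd.DataFrame(
            self.by_category[quantity], index=self.years, columns=self.categories
        )

    def value(self, year: int, quantity: str, category: str | None = None) -> float:
        t = self._year_index(year)
        if category is None or category == TOTAL_LABEL:
            return float(self.totals[quantity][t])
        return float(self.by_category[quantity][t, self.categories.index(category)])

    def state(self, year: int) -> PoolState:
        t = self._year_index(year)

        def cat_dict(q: str) -> dict[str, float]:
            return dict(zip(self.categories, self.by_category[q][t]))

        return PoolState(
            in_use=cat_dict("in_use"),
            recovered=cat_dict("recovered"),
            landfill_fixed=cat_dict("landfill_fixed"),
            landfill_decayable=cat_dict("landfill_decayable"),
            dump=cat_dict("dump"),
            cum_ewec=float(self.totals["cum_ewec"][t]),
            cum_ewoec=cat_dict("cum_ewoec"),
            cum_compost_emit=float(self.totals["cum_compost"][t]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy long form: one row per (year, quantity, category)."""
        records = []
        for q in CATEGORY_QUANTITIES:
            arr = self.by_category[q]
            for j, cat in enumerate(self.categories):
                records.append(
                    pd.DataFrame(
                        {
                            "year": self.years,
                            "quantity": q,
                            "category": cat,
                            "value": arr[:, j],
                        }
                    )
                )
        for q in CATEGORY_QUANTITIES + TOTAL_ONLY_QUANTITIES:
            records.append(
                pd.DataFrame(
                    {
                        "year": self.years,
                        "quantity": q,
                        "category": TOTAL_LABEL,
                        "value": self.totals[q],
                    }
                )
            )
        if not records:
            return pd.DataFrame(columns=["year", "quantity", "category", "value"])
        return pd.concat(records, ignore_index=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnualLedger):
            return NotImplemented
        return (
            np.array_equal(self.years, other.years)
            and self.categories == other.categories
            and all(
                np.array_equal(self.by_category[q], other.by_category[q])
                for q in CATEGORY_QUANTITIES
            )
            and all(
                np.array_equal(self.totals[q], other.totals[q])
                for q in CATEGORY_QUANTITIES + TOTAL_ONLY_QUANTITIES
            )
        )


def write_ledger(ledger: AnnualLedger, path: str | Path) -> None:
    """Write a ledger as a tidy CSV; re-reading reproduces it bit-exactly
    (floats are serialised with full repr precision)."""
    ledger.to_frame().to_csv(path, index=False, float_format=_REPR_FLOAT)


def read_ledger(path: str | Path) -> AnnualLedger:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        return AnnualLedger(np.array([], dtype=int), [],
                            {q: np.zeros((0, 0)) for q in CATEGORY_QUANTITIES},
                            {q: np.zeros(0) for q in CATEGORY_QUANTITIES + TOTAL_ONLY_QUANTITIES})
    years = np.sort(df["year"].unique())
    categories = sorted(c for c in df["category"].unique() if c != TOTAL_LABEL)
    by_category = {}
    for q in CATEGORY_QUANTITIES:
        sub = df[(df["quantity"] == q) & (df["category"] != TOTAL_LABEL)]
        pivot = sub.pivot(index="year", columns="category", values="value")
        pivot = pivot.reindex(index=years, columns=categories)
        by_category[q] = pivot.to_numpy(dtype=float)
    totals = {}
    for q in CATEGORY_QUANTITIES + TOTAL_ONLY_QUANTITIES:
        sub = df[(df["quantity"] == q) & (df["category"] == TOTAL_LABEL)]
        totals[q] = sub.set_index("year")["value"].reindex(years).to_numpy(dtype=float)
    return AnnualLedger(years, categories, by_category, totals)


# ---------------------------------------------------------------------------
# harvest allocation
# ---------------------------------------------------------------------------


def _allocate(masses: pd.DataFrame, ratios: pd.DataFrame, name: str) -> pd.DataFrame:
    """Push (year, category, mass) through a (year, source, target, fraction)
    allocation table; positive mass with no matching ratio rows is an error."""
    merged = masses.merge(
        ratios,
        left_on=["year", "category"],
        right_on=["year", "source_category"],
        how="left",
    )
    lost = merged[merged["fraction"].isna() & (merged["mass"] > 0)]
    if not lost.empty:
        row = lost.iloc[0]
        raise MissingParameterError(
            f"{name}: no ratio rows for (year {row.year}, source {row.category!r})"
        )
    merged = merged.dropna(subset=["fraction"]).copy()
    merged["mass"] = merged["mass"] * merged["fraction"]
    out = merged.groupby(["year", "target_category"], as_index=False)["mass"].sum()
    return out.rename(columns={"target_category": "category"})


def _harvest_to_end_uses(
    inputs: ModelInputs, years: np.ndarray, end_uses: list[str]
) -> np.ndarray:
    """Dense (n_years, n_end_uses) harvest-carbon allocation matrix (Tg C)."""
    harvest = (
        inputs.harvest.groupby(["year", "primary_product"], as_index=False)["carbon_mass"]
        .sum()
        .rename(columns={"primary_product": "category", "carbon_mass": "mass"})
    )
    harvest = harvest[harvest["year"].isin(years)]
    if inputs.primary_ratios is not None:
        harvest = _allocate(harvest, inputs.primary_ratios, "primary_ratios")
    alloc = _allocate(harvest, inputs.end_use_ratios, "end_use_ratios")

    eu_index = {eu: i for i, eu in enumerate(end_uses)}
    unknown = set(alloc["category"]) - set(eu_index)
    if unknown:
        raise MissingParameterError(
            f"end uses with allocated mass but no parameters: {sorted(unknown)[:5]}"
        )
    year_index = {int(y): t for t, y in enumerate(years)}
    A = np.zeros((len(years), len(end_uses)))
    rows = alloc["year"].map(year_index).to_numpy()
    cols = alloc["category"].map(eu_index).to_numpy()
    np.add.at(A, (rows, cols), alloc["mass"].to_numpy())
    return A


def _fate_matrices(
    fates: pd.DataFrame,
    years: np.ndarray,
    categories: list[str],
    eu_cat_idx: np.ndarray,
) -> dict[str, np.ndarray]:
    """Per-fate (n_years, n_end_uses) fraction matrices, looked up through
    each end use's discard category."""
    from .defaults import FATES

    out = {}
    pivot = fates.pivot_table(
        index="year", columns=["discard_category", "fate"], values="fraction",
        aggfunc="sum",
    )
    for cat in categories:
        if cat not in pivot.columns.get_level_values(0):
            raise MissingParameterError(f"discard_fates: no rows for category {cat!r}")
    missing_years = set(years.tolist()) - set(pivot.index.tolist())
    if missing_years:
        raise MissingParameterError(
            f"discard_fates: missing year(s) {sorted(missing_years)[:5]}"
        )
    for fate in FATES:
        cat_mat = np.zeros((len(years), len(categories)))
        for j, cat in enumerate(categories):
            if (cat, fate) in pivot.columns:
                col = pivot[(cat, fate)].reindex(years)
                cat_mat[:, j] = col.fillna(0.0).to_numpy()
        out[fate] = cat_mat[:, eu_cat_idx]
    return out


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def run_simulation(
    inputs: ModelInputs,
    options: EngineOptions | None = None,
    scenario=None,
) -> AnnualLedger:
    """Run the annual carbon accounting simulation.

    ``scenario`` may be a :class:`~hwpcarbon.params.FixedCarbonScenario` or a
    scenario name; it is applied to the inputs (fixed-carbon overrides,
    category disaggregation, dump rerouting) before simulation.  Pass
    ``None`` to run the inputs exactly as given.
    """
    if scenario is not None:
        from .updates import prepare_scenario

        inputs = prepare_scenario(inputs, scenario)
    options = options or EngineOptions()
    inputs.validate()

    start = options.start_year
    end = options.end_year
    hyears = inputs.harvest["year"]
    start = int(hyears.min()) if start is None else start
    end = int(hyears.max()) if end is None else end
    years = np.arange(start, end + 1)

    eup = inputs.end_use_params.sort_values("end_use").reset_index(drop=True)
    end_uses = eup["end_use"].tolist()
    n_eu = len(end_uses)
    categories = sorted(eup["discard_category"].unique())
    eu_cat_idx = np.array([categories.index(c) for c in eup["discard_category"]])
    fuel = eup["fuelwood_flag"].to_numpy(dtype=bool)

    dp = inputs.decay_params.set_index("discard_category")
    missing = [c for c in categories if c not in dp.index]
    if missing:
        raise MissingParameterError(f"decay_params: no rows for categories {missing}")
    lam_use = np.array([decay_fraction(h) for h in eup["half_life"]])
    lam_lf = np.array(
        [decay_fraction(dp.loc[c, "landfill_half_life"]) for c in categories]
    )[eu_cat_idx]
    lam_dump = np.array(
        [decay_fraction(dp.loc[c, "dump_half_life"]) for c in categories]
    )[eu_cat_idx]
    lam_rec = np.array(
        [decay_fraction(dp.loc[c, "recovered_half_life"]) for c in categories]
    )[eu_cat_idx]
    f_fixed = np.array(
        [float(dp.loc[c, "landfill_fixed_ratio"]) for c in categories]
    )[eu_cat_idx]

    A = _harvest_to_end_uses(inputs, years, end_uses)
    F = _fate_matrices(inputs.discard_fates, years, categories, eu_cat_idx)

    # per-end-use state
    in_use = np.zeros(n_eu)
    recovered = np.zeros(n_eu)
    lf_fixed = np.zeros(n_eu)
    lf_decay = np.zeros(n_eu)
    dump = np.zeros(n_eu)
    cum_ewoec = np.zeros(n_eu)
    cum_lf_loss = np.zeros(n_eu)
    cum_dump_loss = np.zeros(n_eu)
    cum_compost = np.zeros(n_eu)
    cum_ewec = 0.0
    cum_harvest = 0.0

    n_years = len(years)
    n_cat = len(categories)
    cat_masks = [eu_cat_idx == j for j in range(n_cat)]
    by_cat = {q: np.zeros((n_years, n_cat)) for q in CATEGORY_QUANTITIES}
    totals = {q: np.zeros(n_years) for q in CATEGORY_QUANTITIES + TOTAL_ONLY_QUANTITIES}

    for t in range(n_years):
        # (1) decay existing pools
        inuse_loss = in_use * lam_use
        in_use = in_use - inuse_loss
        rec_out = recovered * lam_rec
        recovered = recovered - rec_out
        lf_loss = lf_decay * lam_lf
        lf_decay = lf_decay - lf_loss
        dp_loss = dump * lam_dump
        dump = dump - dp_loss
        cum_lf_loss = cum_lf_loss + lf_loss
        cum_dump_loss = cum_dump_loss + dp_loss
        cum_ewoec = cum_ewoec + lf_loss + dp_loss

        # (3) harvest allocation; fuelwood straight to EWEC
        alloc = A[t]
        cum_harvest += float(alloc.sum())
        cum_ewec += float(alloc[fuel].sum())
        in_use = in_use + np.where(fuel, 0.0, alloc)

        # (2)+(4) discarded stream: in-use losses plus re-discarded recovery
        discarded = inuse_loss + rec_out
        rec_in = discarded * F["recovered"][t]
        bwec = discarded * F["burned_with_energy_capture"][t]
        bwoec = discarded * F["burned_without_energy_capture"][t]
        comp = discarded * F["composted"][t]
        lf_in = discarded * F["landfill"][t]
        dp_in = discarded * F["dump"][t]

        recovered = recovered + rec_in
        cum_ewec += float(bwec.sum())
        cum_ewoec = cum_ewoec + bwoec
        cum_compost = cum_compost + comp
        fixed_in = lf_in * f_fixed
        lf_fixed = lf_fixed + fixed_in
        lf_decay = lf_decay + (lf_in - fixed_in)
        dump = dump + dp_in

        if not (
            np.isfinite(in_use).all()
            and np.isfinite(lf_decay).all()
            and np.isfinite(dump).all()
        ):
            raise EngineError(f"non-finite pool state in year {years[t]}")

        per_eu = {
            "in_use": in_use,
            "recovered": recovered,
            "landfill_fixed": lf_fixed,
            "landfill_decayable": lf_decay,
            "dump": dump,
            "cum_ewoec": cum_ewoec,
            "cum_landfill_loss": cum_lf_loss,
            "cum_dump_loss": cum_dump_loss,
            "cum_compost": cum_compost,
            "discarded": discarded,
            "landfill_inflow": lf_in,
            "landfill_loss": lf_loss,
            "dump_loss": dp_loss,
            "recovered_outflow": rec_out,
        }
        for q, arr in per_eu.items():
            # totals summed over all end uses in fixed sorted order, not
            # via the category grouping, so relabelling cannot change them
            totals[q][t] = arr.sum()
            for j in range(n_cat):
                by_cat[q][t, j] = arr[cat_masks[j]].sum()
        totals["cum_ewec"][t] = cum_ewec
        totals["cum_harvest"][t] = cum_harvest

    reported_years = years + 1 if options.shift_year else years
    return AnnualLedger(reported_years, categories, by_cat, totals)
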