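"""Input data model: harvest series, ratio tables, decay parameters.

All tables are plain :class:`pandas.DataFrame` objects in long (tidy) form,
read from uncompressed CSV so every input can be inspected and diffed.
Validation is strict and total: a malformed table raises one of the named
errors in :mod:`hwpcarbon.errors`, always with the offending coordinates.

Schemas
-------
harvest.csv             year, primary_product, carbon_mass[, volume, conversion_factor]
primary_ratios.csv      year, source_category, target_category, fraction
end_use_ratios.csv      year, source_category, target_category, fraction
discard_fates.csv       year, discard_category, fate, fraction
decay_params.csv        discard_category, dump_half_life, landfill_fixed_ratio,
                        landfill_half_life, recovered_half_life
end_use_params.csv      end_use, half_life, discard_category, fuelwood_flag
waste_characterization.csv  year, paper_category, tonnage
scenario.yaml           name, ratio_overrides, options
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .defaults import FATES, SCENARIO_NAMES
from .errors import (
    MissingYearError,
    NegativeValueError,
    RatioSumError,
    UnknownFateError,
    UnknownScenarioError,
    ValidationError,
)

RATIO_SUM_TOL = 1e-9


def _REPR_FLOAT(x) -> str:
    """Shortest round-trip float serialisation for CSV output."""
    return repr(float(x))


@dataclasses.dataclass
class FixedCarbonScenario:
    """A named fixed-carbon parameterisation.

    ``ratio_overrides`` maps discard-category labels to landfill fixed-carbon
    ratios that replace the defaults; categories not named keep their
    defaults.  ``reroute_dumps`` additionally closes dumps from
    ``cutoff_year`` on, shifting their discard share to landfills.
    """

    name: str
    ratio_overrides: dict[str, float] = dataclasses.field(default_factory=dict)
    reroute_dumps: bool = False
    cutoff_year: int = 1995

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise UnknownScenarioError(
                f"unknown scenario {self.name!r}; expected one of {SCENARIO_NAMES}"
            )
        for cat, value in self.ratio_overrides.items():
            if not 0.0 <= value <= 1.0:
                raise NegativeValueError(
                    f"fixed-carbon override for {cat!r} is {value}, outside [0, 1]"
                )


@dataclasses.dataclass
class ModelInputs:
    """The full input bundle consumed by the simulation engine."""

    harvest: pd.DataFrame
    primary_ratios: pd.DataFrame | None
    end_use_ratios: pd.DataFrame
    discard_fates: pd.DataFrame
    decay_params: pd.DataFrame
    end_use_params: pd.DataFrame
    waste_characterization: pd.DataFrame | None = None

    def copy(self) -> "ModelInputs":
        return ModelInputs(
            harvest=self.harvest.copy(),
            primary_ratios=None if self.primary_ratios is None else self.primary_ratios.copy(),
            end_use_ratios=self.end_use_ratios.copy(),
            discard_fates=self.discard_fates.copy(),
            decay_params=self.decay_params.copy(),
            end_use_params=self.end_use_params.copy(),
            waste_characterization=(
                None
                if self.waste_characterization is None
                else self.waste_characterization.copy()
            ),
        )

    def validate(self) -> None:
        validate_harvest(self.harvest)
        if self.primary_ratios is not None:
            validate_ratio_table(self.primary_ratios, name="primary_ratios")
        validate_ratio_table(self.end_use_ratios, name="end_use_ratios")
        validate_discard_fates(self.discard_fates)
        validate_decay_params(self.decay_params)
        validate_end_use_params(self.end_use_params)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{name}: missing column(s) {missing}")


def validate_harvest(df: pd.DataFrame) -> None:
    """Harvest series: contiguous years, non-negative carbon masses."""
    _require_columns(df, ("year", "primary_product", "carbon_mass"), "harvest")
    if df["carbon_mass"].isna().any():
        row = df[df["carbon_mass"].isna()].iloc[0]
        raise ValidationError(
            f"harvest: NaN carbon_mass (year {row.year}, product {row.primary_product!r})"
        )
    neg = df[df["carbon_mass"] < 0]
    if not neg.empty:
        row = neg.iloc[0]
        raise NegativeValueError(
            f"harvest: negative carbon_mass {row.carbon_mass} "
            f"(year {row.year}, product {row.primary_product!r})"
        )
    years = np.sort(df["year"].unique())
    gaps = set(range(int(years.min()), int(years.max()) + 1)) - set(years.tolist())
    if gaps:
        raise MissingYearError(f"harvest: missing year(s) {sorted(gaps)}")
    if "conversion_factor" in df.columns:
        bad = df[df["conversion_factor"].notna() & (df["conversion_factor"] <= 0)]
        if not bad.empty:
            row = bad.iloc[0]
            raise NegativeValueError(
                f"harvest: non-positive conversion_factor (year {row.year}, "
                f"product {row.primary_product!r})"
            )


def validate_ratio_table(
    df: pd.DataFrame,
    name: str = "ratio_table",
    tol: float = RATIO_SUM_TOL,
    renormalize: bool = False,
) -> pd.DataFrame:
    """Check a (year, source, target, fraction) allocation table.

    Fractions must lie in [0, 1] and sum to 1 over targets for each
    (year, source).  With ``renormalize=True`` (off by default) sums within
    1e-6 of 1 are silently rescaled instead of rejected; genuine data errors
    should surface, so renormalisation is opt-in.
    """
    _require_columns(df, ("year", "source_category", "target_category", "fraction"), name)
    neg = df[df["fraction"] < 0]
    if not neg.empty:
        row = neg.iloc[0]
        raise NegativeValueError(
            f"{name}: negative fraction (year {row.year}, source "
            f"{row.source_category!r}, target {row.target_category!r})"
        )
    sums = df.groupby(["year", "source_category"])["fraction"].sum()
    bad = sums[(sums - 1.0).abs() > tol]
    if not bad.empty:
        if renormalize and (bad - 1.0).abs().max() < 1e-6:
            df = df.copy()
            keys = df.set_index(["year", "source_category"]).index
            df["fraction"] = df["fraction"].to_numpy() / sums.loc[keys].to_numpy()
            return df
        year, source = bad.index[0]
        raise RatioSumError(
            f"{name}: fractions for (year {year}, source {source!r}) "
            f"sum to {bad.iloc[0]:.12g}, not 1"
        )
    return df


def validate_discard_fates(
    df: pd.DataFrame, tol: float = RATIO_SUM_TOL, renormalize: bool = False
) -> pd.DataFrame:
    """Check a discard-fate table (year, discard_category, fate, fraction)."""
    _require_columns(df, ("year", "discard_category", "fate", "fraction"), "discard_fates")
    unknown = df[~df["fate"].isin(FATES)]
    if not unknown.empty:
        row = unknown.iloc[0]
        raise UnknownFateError(
            f"discard_fates: unknown fate {row.fate!r} "
            f"(year {row.year}, category {row.discard_category!r})"
        )
    renamed = df.rename(
        columns={"discard_category": "source_category", "fate": "target_category"}
    )
    out = validate_ratio_table(renamed, name="discard_fates", tol=tol, renormalize=renormalize)
    return out.rename(
        columns={"source_category": "discard_category", "target_category": "fate"}
    )


def validate_decay_params(df: pd.DataFrame) -> None:
    _require_columns(
        df,
        (
            "discard_category",
            "dump_half_life",
            "landfill_fixed_ratio",
            "landfill_half_life",
            "recovered_half_life",
        ),
        "decay_params",
    )
    for col in ("dump_half_life", "landfill_half_life", "recovered_half_life"):
        bad = df[df[col] <= 0]
        if not bad.empty:
            raise NegativeValueError(
                f"decay_params: non-positive {col} for "
                f"category {bad.iloc[0].discard_category!r}"
            )
    bad = df[(df["landfill_fixed_ratio"] < 0) | (df["landfill_fixed_ratio"] > 1)]
    if not bad.empty:
        raise NegativeValueError(
            f"decay_params: landfill_fixed_ratio outside [0, 1] for "
            f"category {bad.iloc[0].discard_category!r}"
        )
    dup = df["discard_category"].duplicated()
    if dup.any():
        raise ValidationError(
            f"decay_params: duplicate category "
            f"{df.loc[dup, 'discard_category'].iloc[0]!r}"
        )


def validate_end_use_params(df: pd.DataFrame) -> None:
    _require_columns(
        df, ("end_use", "half_life", "discard_category", "fuelwood_flag"), "end_use_params"
    )
    bad = df[df["half_life"] <= 0]
    if not bad.empty:
        raise NegativeValueError(
            f"end_use_params: non-positive half_life for end use "
            f"{bad.iloc[0].end_use!r}"
        )
    dup = df["end_use"].duplicated()
    if dup.any():
        raise ValidationError(
            f"end_use_params: end use {df.loc[dup, 'end_use'].iloc[0]!r} "
            f"maps to more than one discard category"
        )


def validate_waste_characterization(df: pd.DataFrame) -> None:
    _require_columns(
        df, ("year", "paper_category", "tonnage"), "waste_characterization"
    )
    neg = df[df["tonnage"] < 0]
    if not neg.empty:
        row = neg.iloc[0]
        raise NegativeValueError(
            f"waste_characterization: negative tonnage "
            f"(year {row.year}, category {row.paper_category!r})"
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_harvest(path: str | Path) -> pd.DataFrame:
    """Read a harvest series; volume-form rows are converted to carbon mass
    (carbon_mass = volume * conversion_factor) where carbon_mass is absent."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "carbon_mass" not in df.columns:
        df["carbon_mass"] = np.nan
    if "volume" in df.columns:
        needs = df["carbon_mass"].isna()
        if needs.any():
            if "conversion_factor" not in df.columns:
                raise ValidationError(
                    "harvest: volume form requires a conversion_factor column"
                )
            df.loc[needs, "carbon_mass"] = (
                df.loc[needs, "volume"] * df.loc[needs, "conversion_factor"]
            )
    if df["carbon_mass"].isna().any():
        row = df[df["carbon_mass"].isna()].iloc[0]
        raise ValidationError(
            f"harvest: no carbon_mass or volume for "
            f"(year {row.year}, product {row.primary_product!r})"
        )
    validate_harvest(df)
    return df


def read_ratio_table(path: str | Path, name: str = "ratio_table",
                     renormalize: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    return validate_ratio_table(df, name=name, renormalize=renormalize)


def read_discard_fates(path: str | Path, renormalize: bool = False) -> pd.DataFrame:
    return validate_discard_fates(pd.read_csv(path, float_precision="round_trip"), renormalize=renormalize)


def read_decay_params(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    validate_decay_params(df)
    return df


def read_end_use_params(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    df["fuelwood_flag"] = df["fuelwood_flag"].astype(bool)
    validate_end_use_params(df)
    return df


def read_waste_characterization(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    validate_waste_characterization(df)
    return df


def read_scenario_yaml(path: str | Path) -> FixedCarbonScenario:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return FixedCarbonScenario(
        name=raw["name"],
        ratio_overrides=dict(raw.get("ratio_overrides") or {}),
        reroute_dumps=bool(raw.get("reroute_dumps", False)),
        cutoff_year=int(raw.get("cutoff_year", 1995)),
    )


def write_scenario_yaml(scenario: FixedCarbonScenario, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "name": scenario.name,
                "ratio_overrides": dict(scenario.ratio_overrides),
                "reroute_dumps": scenario.reroute_dumps,
                "cutoff_year": scenario.cutoff_year,
            },
            fh,
            sort_keys=True,
        )


_INPUT_FILES = {
    "harvest": "harvest.csv",
    "primary_ratios": "primary_ratios.csv",
    "end_use_ratios": "end_use_ratios.csv",
    "discard_fates": "discard_fates.csv",
    "decay_params": "decay_params.csv",
    "end_use_params": "end_use_params.csv",
    "waste_characterization": "waste_characterization.csv",
}


def read_inputs(directory: str | Path, renormalize: bool = False) -> ModelInputs:
    """Read the full CSV input set from a directory.

    ``primary_ratios.csv`` and ``waste_characterization.csv`` are optional;
    everything else must be present and valid.
    """
    directory = Path(directory)
    for key in ("harvest", "end_use_ratios", "discard_fates", "decay_params",
                "end_use_params"):
        if not (directory / _INPUT_FILES[key]).exists():
            raise ValidationError(f"missing input file: {_INPUT_FILES[key]}")

    primary_path = directory / _INPUT_FILES["primary_ratios"]
    waste_path = directory / _INPUT_FILES["waste_characterization"]
    return ModelInputs(
        harvest=read_harvest(directory / _INPUT_FILES["harvest"]),
        primary_ratios=(
            read_ratio_table(primary_path, "primary_ratios", renormalize)
            if primary_path.exists()
            else None
        ),
        end_use_ratios=read_ratio_table(
            directory / _INPUT_FILES["end_use_ratios"], "end_use_ratios", renormalize
        ),
        discard_fates=read_discard_fates(
            directory / _INPUT_FILES["discard_fates"], renormalize
        ),
        decay_params=read_decay_params(directory / _INPUT_FILES["decay_params"]),
        end_use_params=read_end_use_params(directory / _INPUT_FILES["end_use_params"]),
        waste_characterization=(
            read_waste_characterization(waste_path) if waste_path.exists() else None
        ),
    )


def write_inputs(inputs: ModelInputs, directory: str | Path) -> None:
    """Write the full input bundle as the CSV set ``read_inputs`` expects."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    # shortest-round-trip float serialisation, so
    # read_inputs(write_inputs(x)) reproduces every float bit-exactly
    kw = {"index": False, "float_format": _REPR_FLOAT}
    inputs.harvest.to_csv(directory / _INPUT_FILES["harvest"], **kw)
    if inputs.primary_ratios is not None:
        inputs.primary_ratios.to_csv(directory / _INPUT_FILES["primary_ratios"], **kw)
    inputs.end_use_ratios.to_csv(directory / _INPUT_FILES["end_use_ratios"], **kw)
    inputs.discard_fates.to_csv(directory / _INPUT_FILES["discard_fates"], **kw)
    inputs.decay_params.to_csv(directory / _INPUT_FILES["decay_params"], **kw)
    inputs.end_use_params.to_csv(directory / _INPUT_FILES["end_use_params"], **kw)
    if inputs.waste_characterization is not None:
        inputs.waste_characterization.to_csv(
            directory / _INPUT_FILES["waste_characterization"], **kw
        )
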