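#!/usr/bin/env python
"""Annual landfill storage and emission series, default vs combined.

Writes the per-year net landfill storage added (negative) and landfill
emissions (positive) for both parameterisations, reports the peak years,
and renders bar-chart and cumulative-trajectory figures.
"""

from pathlib import Path

import hwpcarbon as h

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ledgers = {
        name: h.read_ledger(RESULTS / "ledgers" / f"{name}.csv")
        for name in ("default", "combined")
    }
    for name, ledger in ledgers.items():
        series = h.annual_series(ledger, basis="net")
        out = RESULTS / f"annual_landfill_{name}.csv"
        series.round(4).to_csv(out, index=False)
        peak_storage = series.loc[series["storage_added"].idxmin()]
        peak_emis = series.loc[series["emissions"].idxmax()]
        print(
            f"{name:9s} storage peaks {int(peak_storage['year'])} "
            f"({peak_storage['storage_added']:.2f}), emissions peak "
            f"{int(peak_emis['year'])} ({peak_emis['emissions']:.2f}) MMT CO2Eq"
        )
        h.report.plot_annual_series(series, RESULTS / f"annual_landfill_{name}.png")
    h.report.plot_cumulative(ledgers, RESULTS / "cumulative_trajectories.png")
    print(f"series, figures written to {RESULTS}")


if __name__ == "__main__":
    main()
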