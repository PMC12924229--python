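#!/usr/bin/env python
"""Compare every update scenario against the default parameterisation.

Builds the scenario-comparison table (cumulative totals, mean-annual
values, deltas and percent changes in MMT CO2Eq) from the ledgers written
by 02 and checks the expected ordering: every update deepens SWDS storage
and lowers EWOEC, with the IPCC bulk defaults moving furthest.
"""

from pathlib import Path

import hwpcarbon as h

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ledgers = {
        name: h.read_ledger(RESULTS / "ledgers" / f"{name}.csv")
        for name in h.SCENARIO_NAMES
    }
    table = h.scenario_table(ledgers, baseline="default")
    out = RESULTS / "scenario_comparison.csv"
    table.round(2).to_csv(out, index=False)
    print(table.round(2).to_string(index=False))

    by_name = table.set_index("scenario")
    order = by_name["cumulative_swds"].sort_values().index.tolist()
    print("\nstorage depth ordering (deepest first):", " > ".join(order))
    assert order[0] == "ipcc" and order[-1] == "default", "unexpected ordering"
    print(f"table written to {out}")


if __name__ == "__main__":
    main()
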