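#!/usr/bin/env python
"""Scenario sweep over cohort entry/exit ages.

Repeats the comparison for the base case and the six entry/exit-age
variants (10/15/20/60-year horizons, entry at 40 or 50) and writes the
scenario table under results/.
"""

from pathlib import Path

from lpi_cea import default_parameters, scenario_sweep

OUT = Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = scenario_sweep(default_parameters())
    table.to_csv(OUT / "scenario_table.csv", index=False)

    cols = ["scenario", "cost_lpi_jpy", "cost_observation_jpy",
            "delta_cost_jpy", "delta_qaly", "icer_label"]
    print(table[cols].to_string(index=False,
                                float_format=lambda x: f"{x:,.4g}"))
    icers = table.set_index("horizon")["icer_jpy_per_qaly"]
    print("\nLonger horizons amortise the up-front laser cost over more "
          "prevented progression:")
    at40 = table[table.entry_age == 40].set_index("horizon")["icer_jpy_per_qaly"]
    for h in (10, 20, 60):
        print(f"  {h:2d}-year horizon: ICER {at40[h]:,.0f} JPY/QALY")
    print("Moving cohort entry from 40 to 50 barely changes the ICER "
          "(age brackets shift one decade).")


if __name__ == "__main__":
    main()
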