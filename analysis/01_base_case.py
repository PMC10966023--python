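#!/usr/bin/env python
"""Base-case cost-utility comparison: prophylactic iridotomy vs observation.

Runs the 20-year, entry-age-40 Markov cohort for both arms at default
parameters, prints the incremental comparison, and writes the per-cycle
traces and the CEA row under results/base_case/.
"""

from pathlib import Path

from lpi_cea import BASE_SCENARIO, LPI, OBSERVATION, compare, default_parameters, run_cohort

OUT = Path("results/base_case")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = default_parameters()
    lpi = run_cohort(params, LPI, BASE_SCENARIO)
    obs = run_cohort(params, OBSERVATION, BASE_SCENARIO)
    cea = compare(lpi, obs, params.wtp, params.jpy_per_gbp)

    lpi.trace.to_csv(OUT / "trace_lpi.csv")
    obs.trace.to_csv(OUT / "trace_observation.csv")
    cea.to_frame().to_csv(OUT / "cea.csv", index=False)
    params.to_csv(OUT / "parameters.csv")

    print(f"scenario: {BASE_SCENARIO.label}")
    print(f"  LPI          {lpi.total_cost:11,.0f} JPY  {lpi.total_qaly:8.4f} QALYs")
    print(f"  observation  {obs.total_cost:11,.0f} JPY  {obs.total_qaly:8.4f} QALYs")
    print(f"  incremental  {cea.delta_cost:11,.0f} JPY  {cea.delta_qaly:8.5f} QALYs")
    print(f"  ICER         {cea.icer_label} JPY/QALY ({cea.icer_gbp:,} GBP/QALY)")
    verdict = "below" if cea.icer is not None and cea.icer < params.wtp else "above"
    print(f"  -> {verdict} the willingness-to-pay threshold of "
          f"{params.wtp:,.0f} JPY/QALY (NMB {cea.nmb:,.0f} JPY)")


if __name__ == "__main__":
    main()
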