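#!/usr/bin/env python
"""One-way deterministic sensitivity analysis with tornado ranking.

Moves each ranged input to its bounds (+/-30% probabilities, +/-8%
utilities, +/-20% costs, discount rate 0-4%), re-computes the base-case
ICER, ranks the excursion spans, and writes results/tornado.csv plus a
tornado diagram (SVG).
"""

from pathlib import Path

from lpi_cea import BASE_SCENARIO, default_parameters, run_comparison, tornado
from lpi_cea.dsa import tornado_frame

OUT = Path("results")


def plot(df, base_icer, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = df.iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 5))
    for i, row in enumerate(df.itertuples()):
        lo, hi = sorted([row.icer_low, row.icer_high])
        ax.barh(i, hi - lo, left=lo, color="#4878b0", height=0.6)
    ax.axvline(base_icer, color="k", lw=1, ls="--",
               label=f"base case {base_icer:,.0f}")
    ax.set_yticks(range(len(df)), df["parameter"])
    ax.set_xlabel("ICER, JPY per QALY")
    ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = default_parameters()
    _, _, base = run_comparison(params, BASE_SCENARIO)
    entries = tornado(params, BASE_SCENARIO, top_k=12)
    df = tornado_frame(entries)
    df.to_csv(OUT / "tornado.csv", index=False)
    plot(df, base.icer, OUT / "tornado.svg")

    print(f"base-case ICER: {base.icer:,.0f} JPY/QALY")
    print(df.to_string(index=False, float_format=lambda x: f"{x:,.4g}"))
    worst = max(max(e.icer_at_low or 0, e.icer_at_high or 0) for e in entries)
    print(f"\nmost influential input: {entries[0].parameter} "
          f"(span {entries[0].span:,.0f} JPY/QALY)")
    print(f"worst one-way ICER: {worst:,.0f} JPY/QALY")
    print("The routine follow-up costs of the PACS state dominate the "
          "ranking: they accrue for nearly the whole cohort every year, "
          "while progression events are rare.")


if __name__ == "__main__":
    main()
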