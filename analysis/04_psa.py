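#!/usr/bin/env python
"""Probabilistic sensitivity analysis.

Propagates parameter uncertainty (method-of-moments beta/gamma draws,
10,000 Monte Carlo iterations) through the base-case comparison, writes
the incremental-plane samples and the cost-effectiveness acceptability
curve, and plots both.
"""

from pathlib import Path

from lpi_cea import BASE_SCENARIO, ceac, ceac_crossing, default_parameters, run_psa

OUT = Path("results")
SEED = 2026
ITERATIONS = 10_000


def plot(result, curve, wtp) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.scatter(result.delta_qaly, result.delta_cost, s=2, alpha=0.3,
                color="#4878b0")
    lo, hi = ax1.get_xlim()
    ax1.plot([lo, hi], [wtp * lo, wtp * hi], "k--", lw=1,
             label=f"WTP {wtp:,.0f}")
    ax1.axhline(0, color="grey", lw=0.5)
    ax1.axvline(0, color="grey", lw=0.5)
    ax1.set_xlabel("incremental QALYs")
    ax1.set_ylabel("incremental cost, JPY")
    ax1.legend(frameon=False)
    ax2.plot(curve["wtp_jpy_per_qaly"] / 1e6, curve["prob_cost_effective"])
    ax2.axhline(0.5, color="grey", lw=0.5, ls=":")
    ax2.set_xlabel("willingness to pay, million JPY/QALY")
    ax2.set_ylabel("P(cost-effective)")
    ax2.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(OUT / "psa.svg")
    plt.close(fig)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = default_parameters()
    result = run_psa(params, BASE_SCENARIO, n_iterations=ITERATIONS,
                     seed=SEED)
    result.to_frame().to_csv(OUT / "psa_samples.csv", index=False)
    curve = ceac(result, range(0, 12_000_001, 250_000))
    curve.to_csv(OUT / "ceac.csv", index=False)
    plot(result, curve, params.wtp)

    pce = result.prob_cost_effective()
    print(f"iterations                    : {result.n_iterations} "
          f"(seed {SEED})")
    print(f"P(cost-effective at {params.wtp:,.0f}) : {100 * pce:.1f}%")
    print(f"dominant quadrant (cheaper, better): "
          f"{100 * result.fraction_dominant():.1f}%")
    print(f"CEAC reaches 50% at           : {ceac_crossing(result):,.0f} "
          f"JPY/QALY")
    if result.resampled_iterations:
        print(f"resampled iterations          : {result.resampled_iterations}")


if __name__ == "__main__":
    main()
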