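"""Assemble the investment guide posts and summary figure.

Runs the full pipeline end to end and writes the Table-3-style
guide-post tables (per income group and maturity category), the
funding-gap summary, and a component cost figure under results/.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from phcguide.reporting import RunConfig, run_pipeline

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "report"


def main() -> None:
    bundle = run_pipeline(RunConfig(seed=SEED, out_dir=OUT))

    gp = bundle["guideposts"]["m1"].set_index("group")
    cols = [
        "additional_per_capita",
        "additional_per_capita_recurrent",
        "current_phc_per_capita",
        "total_recurrent_per_capita_2030",
        "workers_per_1000_current",
        "workers_per_1000_2030",
        "visits_per_capita_2030",
        "le_gain_years",
    ]
    print(f"Measure-1 investment guide posts (US$2014 per capita, seed {SEED}):")
    print(gp.loc[[g for g in gp.index if not g.startswith("maturity")], cols].round(1).to_string())
    print("\nAnnual additional cost (billion US$2014):")
    for mid, frame in bundle["guideposts"].items():
        total = frame.set_index("group").loc["all", "additional_cost_annual"] / 1e9
        print(f"  measure {mid[-1]}: {total:,.1f}")
    print("\nGap countries in 2030 by scenario:")
    print(bundle["gap_counts"].to_string(index=False))

    # component figure (measure comparison)
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for mid, res in bundle["ledgers"].items():
        comp = res.totals(["component"]).set_index("component")["amount"] / 11 / 1e9
        comp = comp.sort_values(ascending=False)
        ax.plot(comp.index, comp.values, marker="o", label=f"measure {mid[-1]}")
    ax.set_ylabel("annual additional cost (billion US$2014)")
    ax.tick_params(axis="x", rotation=45)
    ax.legend()
    fig.tight_layout()
    fig.savefig(OUT / "annual_cost_by_component.png", dpi=120)
    print(f"\nTables and figure written to {OUT}")


if __name__ == "__main__":
    main()
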