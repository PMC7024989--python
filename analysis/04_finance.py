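"""Financing scenarios and PHC funding-gap counts.

Projects current health expenditure under business-as-usual, +1pp and
+2pp scenarios, compares measure-1 incremental costs against
incremental funds in 2030, and counts gap countries per scenario.
"""

import sys
from pathlib import Path

import pandas as pd

from phcguide.catalog import MEASURES
from phcguide.costing import CostResult, cost_country
from phcguide.financing import SCENARIOS, count_gap_countries, funding_gap, project_che
from phcguide.synthetic_data import GeneratorConfig, generate_catalog, generate_countries

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "financing"


def main() -> None:
    profiles = generate_countries(GeneratorConfig(seed=SEED))
    catalog = generate_catalog(seed=SEED)
    OUT.mkdir(parents=True, exist_ok=True)

    costs = CostResult.concat(
        [cost_country(p, catalog, MEASURES["m1"]).result for p in profiles]
    )

    rows, counts = [], {}
    for scenario in SCENARIOS:
        projections = [project_che(p, scenario) for p in profiles]
        counts[scenario] = count_gap_countries(projections, costs, 2030)
        for proj in projections:
            rows.append(
                {
                    "country_id": proj.country_id,
                    "scenario": scenario,
                    "che_pct_gdp_2030": proj.che_pct_gdp_by_year[2030],
                    "gap_2030": funding_gap(proj, costs, 1.0, 2030),
                }
            )
    gaps = pd.DataFrame(rows)
    gaps.to_csv(OUT / "gaps_2030.csv", index=False)
    pd.Series(counts, name="countries_with_gap").to_csv(OUT / "gap_counts.csv")

    print(f"Countries with a measure-1 funding gap in 2030 (of {len(profiles)}, seed {SEED}):")
    for s, c in counts.items():
        print(f"  {s:<11} {c}")
    print("\nMean projected CHE %GDP in 2030 by scenario:")
    print(gaps.groupby("scenario")["che_pct_gdp_2030"].mean().round(2).to_string())
    print(f"\nTables written to {OUT}")


if __name__ == "__main__":
    main()
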