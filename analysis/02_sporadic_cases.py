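#!/usr/bin/env python
"""How many sporadic illnesses do those recreation events cause?

Applies the cohort-derived attributable risks to the sampled recreation
events, splits cases into mild (no healthcare contact) and moderate (HCP/ED
contact) tiers, and writes the activity x illness case table to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from aquaburden import packaged_scenario_path, read_scenario, run_simulation, summarize


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--iterations", type=int, default=100_000)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    scenario = read_scenario(packaged_scenario_path("us2007"))
    result = run_simulation(scenario, n_iterations=args.iterations, seed=args.seed)

    illnesses = scenario.illnesses()
    rows = []
    for a in scenario.activities:
        row = {"activity": a.name}
        for ill in illnesses:
            key = (a.name, ill)
            if key in result.cases:
                c = summarize(result.cases[key])
                row[ill] = f"{c.mean / 1e6:.2f} ({c.p5 / 1e6:.2f}-{c.p95 / 1e6:.2f})"
            else:
                row[ill] = "--"
        rows.append(row)
    totals = {"activity": "total"}
    for ill in illnesses:
        c = summarize(result.illness_total[ill])
        totals[ill] = f"{c.mean / 1e6:.2f} ({c.p5 / 1e6:.2f}-{c.p95 / 1e6:.2f})"
    rows.append(totals)
    table = pd.DataFrame(rows)

    args.out.mkdir(parents=True, exist_ok=True)
    path = args.out / "sporadic_cases.csv"
    table.to_csv(path, index=False)

    print("Annual sporadic cases, millions (mean and C90):\n")
    print(table.to_string(index=False))
    total = summarize(result.total_cases)
    share = summarize(result.moderate_share)
    print(
        f"\nAll illnesses: {total.mean / 1e6:.1f}M cases/year; "
        f"{100 * share.mean:.1f}% are moderate (HCP or ED contact)."
    )
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
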