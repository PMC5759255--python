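#!/usr/bin/env python
"""What does recreational waterborne illness cost the US each year?

Runs the full Monte Carlo pipeline on the national 2007 scenario and writes
the component x severity-tier cost table, the summary JSON, and the run
manifest to results/.  Every monetary figure is 2007 USD.
"""

import argparse
from pathlib import Path

from aquaburden import packaged_scenario_path, read_scenario, run_simulation, summarize
from aquaburden.simulation import render_tables


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--iterations", type=int, default=100_000)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    scenario = read_scenario(packaged_scenario_path("us2007"))
    result = run_simulation(scenario, n_iterations=args.iterations, seed=args.seed)
    written = render_tables(result, scenario, args.out)

    print("Annual cost by severity tier, millions of 2007 USD (mean, C90):")
    for tier, bd in result.tiers.items():
        c = summarize(bd.total)
        print(f"  {tier:9s} {c.mean / 1e6:8.1f}  ({c.p5 / 1e6:.1f}-{c.p95 / 1e6:.1f})")
    grand = summarize(result.grand_total)
    print(
        f"\nGrand total: ${grand.mean / 1e9:.2f}B/year "
        f"(C90 {grand.p5 / 1e9:.2f}-{grand.p95 / 1e9:.2f}B)."
    )
    prod = sum(summarize(bd.productivity).mean for bd in result.tiers.values())
    print(f"Lost productivity across tiers: ${prod / 1e6:.0f}M "
          f"({100 * prod / grand.mean:.0f}% of the total).")
    for tier in ("mild", "moderate", "severe"):
        c = summarize(result.per_case[tier])
        print(f"Cost per {tier} case: ${c.mean:,.2f} (C90 {c.p5:,.2f}-{c.p95:,.2f})")
    print("\nwrote:")
    for path in written:
        print(f"  {path}")


if __name__ == "__main__":
    main()
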