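#!/usr/bin/env python
"""Base-case deterministic analysis.

Runs both strategies through the cohort engine from the built-in point
estimates and reports per-arm discounted totals, the incremental QALYs and
costs, the iNMB at £20,000/QALY, and the dominance classification.

Expected headline: the care-pathway arm accrues ~3.18 QALYs vs ~3.09 for
usual care (gain ~0.085) and — before the year-1 cost-gap calibration
examined in 03_cost_gap.py — costs ~£582 less, so it dominates usual care.
Writes results/base_case/{report.csv,report.json,traces.csv}.
"""

import sys
from pathlib import Path

from star_cea import builtin_star_parameters, run_arm, run_comparison
from star_cea.io import round_report, trace_frame
from star_cea.markov_engine import run_trace

import pandas as pd

OUT = Path(__file__).resolve().parent.parent / "results" / "base_case"


def main() -> int:
    params = builtin_star_parameters()
    table = run_comparison(params, ["base"])
    OUT.mkdir(parents=True, exist_ok=True)
    round_report(table).to_csv(OUT / "report.csv", index=False)
    (OUT / "report.json").write_text(table.to_json(orient="records", indent=2))

    traces = []
    for arm in params.arms:
        trace = run_trace(params.initial_array(), params.transition_array(arm), params.horizon)
        traces.append(trace_frame(trace, arm))
    pd.concat(traces, ignore_index=True).to_csv(OUT / "traces.csv", index=False)

    row = table.iloc[0]
    print("Base case (built-in point estimates, 5-year horizon, 3.5% discount):")
    for arm in params.arms:
        res = run_arm(params, arm)
        print(f"  {arm:<11} QALYs {res.total_qalys:7.4f}   costs £{res.total_costs:9.2f}")
    print(f"  ΔQALYs {row['delta_qalys']:+.4f}  ΔCosts £{row['delta_costs']:+.2f}  "
          f"iNMB £{row['inmb']:.2f}  -> {row['dominance']}")
    print(f"wrote {OUT}/report.csv")
    return 0


if __name__ == "__main__":
    sys.exit(main())
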