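#!/usr/bin/env python
"""Parameter recovery on synthetic panels.

The real data sources are access-restricted, so this analysis validates the
derivation chain end to end on synthetic data with known structure: generate
a trial-like panel (two arms, utilities at 0/6/12 months) and a cohort-like
panel (yearly for five years), derive a full parameter bundle from them, run
the engine, and compare against the totals implied in closed form by the
generating parameters.  With 10,000 patients per panel the derived totals
agree within a fraction of a percent.  Writes results/recovery/summary.json.
"""

import json
import sys
from pathlib import Path

from star_cea import run_arm, save_parameters
from star_cea.derivation import derive_parameter_set
from star_cea.synthetic_data import GeneratorConfig, implied_parameters, simulate_cohort, simulate_trial

OUT = Path(__file__).resolve().parent.parent / "results" / "recovery"
SEED = 1


def main() -> int:
    cfg = GeneratorConfig(n_trial_per_arm=10_000, n_cohort=10_000)
    trial = simulate_trial(cfg, seed=SEED)
    cohort = simulate_cohort(cfg, seed=SEED + 1)
    derived = derive_parameter_set(trial, cohort)
    implied = implied_parameters(cfg)

    OUT.mkdir(parents=True, exist_ok=True)
    save_parameters(derived, OUT / "derived_parameters.yaml")

    summary = {"seed": SEED, "n_trial_per_arm": cfg.n_trial_per_arm, "n_cohort": cfg.n_cohort}
    print("derive -> run pipeline vs closed-form generator-implied totals:")
    for arm in derived.arms:
        got, want = run_arm(derived, arm), run_arm(implied, arm)
        rq = abs(got.total_qalys / want.total_qalys - 1)
        rc = abs(got.total_costs / want.total_costs - 1)
        summary[arm] = {
            "derived_qalys": got.total_qalys, "implied_qalys": want.total_qalys,
            "derived_costs": got.total_costs, "implied_costs": want.total_costs,
            "rel_err_qalys": rq, "rel_err_costs": rc,
        }
        print(f"  {arm:<11} QALYs {got.total_qalys:.4f} vs {want.total_qalys:.4f} "
              f"({rq:.2%}); costs £{got.total_costs:.1f} vs £{want.total_costs:.1f} ({rc:.2%})")
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2))
    print(f"wrote {OUT}/summary.json")
    return 0


if __name__ == "__main__":
    sys.exit(main())
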