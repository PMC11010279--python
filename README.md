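# star-cea

A tested, reusable implementation of a model-based cost-utility analysis of a
structured pain-management care pathway for chronic pain after total knee
replacement, compared with usual postoperative care.

Roughly one in five people who undergo a knee replacement still report
chronic pain months after surgery. The pathway evaluated here screens those
patients at three months post-operation (chronic pain defined as an Oxford
Knee Score pain subscale, OKS-PS 0–28, of ≤ 14) and refers them to existing
services, at a one-off delivery cost of £191. This package implements the
five-year economic model of that decision for health economists and
modellers: a two-state (CP/NCP) cohort Markov model with annual cycles,
time-dependent transition probabilities, payoffs attributed by end-of-cycle
state, and 3.5% discounting from year 2, evaluated as

- incremental QALYs and costs (intervention − comparator),
- incremental net monetary benefit  iNMB = λ·ΔQ − ΔC  at λ = £20,000/QALY,
- ICER ΔC/ΔQ on trade-off quadrants, with dominance classification,
- probabilistic sensitivity analysis (moment-matched beta/gamma parameter
  distributions), CEAC and 95% cost-effectiveness-plane ellipse.

It also implements the parameter-derivation chain used to populate the model
from patient-level data — transition estimation from longitudinal panels,
area-under-the-curve QALYs with baseline-utility adjustment, and projection
of utilities (percentage-of-potential-change) and costs (annual percentage
change) beyond the trial's one-year horizon — plus a synthetic-data module
that emulates the restricted trial/cohort sources so the whole chain is
testable. See `docs/methods.md` for the model account.

## Worked example

```python
from star_cea import builtin_star_parameters, run_arm, compare_arms

params = builtin_star_parameters()          # built-in published point estimates
star = run_arm(params, "star")
usual = run_arm(params, "usual_care")
print(f"{star.total_qalys:.4f}  {usual.total_qalys:.4f}  £{usual.total_costs:.2f}")
ce = compare_arms(star, usual, params.wtp_threshold)
print(f"ΔQALYs {ce.delta_qalys:+.4f}  ΔCosts £{ce.delta_costs:+.2f}  "
      f"iNMB £{ce.inmb:.2f}  {ce.dominance.value}")
```

prints

```
3.1762  3.0913  £3563.31
ΔQALYs +0.0849  ΔCosts £-582.07  iNMB £2279.80  intervention_dominant
```

Read: over five years a patient on the care pathway accrues 3.176 discounted
QALYs versus 3.091 under usual care — a gain of about 0.085 QALYs — while
costing less, so the intervention dominates. The intervention-arm cost is
lower than the published £3,188.86 by a constant ≈£208 that the published
per-state inputs do not itemise; `params.extra_arm_year1_cost` exposes it
explicitly, and `analysis/03_cost_gap.py` quantifies it (see the calibration
note in `docs/methods.md`).

The numbered scripts under `analysis/` run the full study: base case,
scenario analyses, the cost-gap calibration, a 10,000-draw PSA with CEAC and
CE-plane figure, and parameter recovery on synthetic panels. Each writes its
tables under `results/`. The same functionality is available from a shell:

```bash
star-cea run --builtin --scenarios base,s1_pooled_qalys,s3_common_hospital --out results/run
star-cea psa --builtin -n 10000 --seed 1 --out results/psa
star-cea simulate --kind trial -n 2000 --seed 1 --out results/trial.csv
star-cea derive --trial results/trial.csv --cohort results/cohort.csv --out results/derived
```

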