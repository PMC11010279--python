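# Methods

## The decision problem and model structure

The package models the five-year cost-utility of a structured pain-management
care pathway offered to adults who still report chronic knee pain three months
after a total knee replacement, against usual postoperative care, from the
perspective of a national health service payer.

Chronic pain (CP) is defined on the pain subscale of the Oxford Knee Score
(OKS-PS, 0–28): a score of 14 or less is CP, anything higher is NCP. The model
is a deterministic cohort Markov simulation with exactly these two states,
annual cycles, and a five-year horizon. The whole cohort enters in CP. Each
cycle the cohort is redistributed by a year-specific 2×2 transition matrix;
the intervention affects only the year-1 CP row (it is delivered during the
first year only), and years 2–5 use cohort-derived dynamics shared by both
arms — a deliberately conservative assumption that any benefit beyond year 1
comes solely from having escaped chronic pain earlier.

There is no death state: the horizon is short and the intervention is assumed
not to influence mortality. There is no half-cycle correction: payoffs (a QALY
weight and an annual cost per state) are attributed by **end-of-cycle**
membership. This convention is a substantive choice — it is the one under
which the published per-arm totals are reproduced exactly from the published
per-state inputs, and it is applied uniformly to QALYs and costs in both arms.

Discounting follows the national guideline of 3.5% per year applied from the
second year onwards: cycle *t* is discounted by (1.035)^−(t−1), so year 1 is
undiscounted. The one-off cost of delivering the care pathway (£191) is
charged undiscounted in cycle 1 of the intervention arm, independent of state
membership.

## Parameters

The built-in bundle stores the published point estimates exactly as printed
(probabilities and utilities to three decimals, costs in whole pounds). No
attempt is made to reconstruct unrounded source estimates; the consequences of
this are quantified below. Defaults that matter:

| parameter | default | units | note |
|---|---|---|---|
| `discount_rate` | 0.035 | /year | year 1 undiscounted |
| `horizon` | 5 | years | annual cycles |
| `wtp_threshold` | 20 000 | £/QALY | lower end of the national 20–30k range |
| `intervention_oneoff_cost` | 191 | £ | year 1, intervention arm only |
| `extra_arm_year1_cost` | 0 | £ | calibration knob, see below |
| `initial_distribution` | 100% CP | — | everyone enters in chronic pain |

The year-1 NCP transition row is structurally empty (no cohort mass occupies
NCP at entry); it is stored as the identity row (0, 1) so every row is a valid
stochastic row. Results are unaffected.

## Derivation procedures

When patient-level panels are supplied (or generated synthetically), the full
bundle is rebuilt from data:

* **Transitions** are maximum-likelihood row proportions between paired
  assessments, available-case (patients missing either observation are
  dropped and counted). Year 1 comes from the trial per arm; years 2–5 from
  consecutive yearly cohort assessments, shared by both arms.
* **Year-1 QALYs** are per-patient trapezoidal areas under the utility-time
  curve at 0/6/12 months, 0.25·(u₀+u₆) + 0.25·(u₆+u₁₂), averaged per
  arm × 12-month state and adjusted for baseline utility by a linear model
  with a single pooled slope, each group evaluated at the pooled mean
  baseline.
* **Utility projection (years 2–5)** uses the percentage-of-potential-change
  method: the reference cohort's year-on-year change is expressed relative to
  the *potential* change and applied to the anchor's own potential. For an
  improvement the potential is the headroom to the scale maximum
  (popc = (to − from)/(1 − from), applied to 1 − current). For a
  deterioration the potential is the distance to the scale minimum, which for
  a zero minimum reduces to proportional change (current · to/from). The
  direction-aware rule is adopted because it reproduces the published
  projected rows from their anchors: the declining NCP cells round exactly to
  the published 0.742 / 0.739 / 0.728 / 0.714, which no single-denominator
  variant achieves; all eight projected cells agree within 0.001. Residual
  sub-0.001 discrepancies in the improving rows are a rounding artefact: the
  published reference rows are themselves projections printed to three
  decimals, so change ratios extracted from them carry rounding error.
* **Cost projection (years 2–5)** applies the cohort's annual percentage
  changes multiplicatively to year-1 anchors — equivalently, rescales the
  cohort series to the anchor. Hospital admission costs are arm-specific in
  year 1 only and pooled thereafter; prescriptions and consultations are
  pooled across arms throughout, matching the published table's structure.

## The intervention-arm cost gap (calibration note)

Under the conventions above, the published inputs reproduce the comparator
totals (3.0913 QALYs, £3,563.31), the intervention QALY total (3.1762), and
the common-hospital-cost scenario's comparator cost (£3,142.11) — but the
intervention-arm total cost comes out £207.62 *below* the published £3,188.86,
and the same scenario implies a shortfall of £207.53 (analysis/03_cost_gap.py
recomputes both). The gap is therefore a constant, undiscounted year-1,
intervention-arm-only cost missing from the itemised inputs; its source is not
identifiable from the published material. The engine does not hard-code a
correction. Instead `extra_arm_year1_cost` (default 0) makes the discrepancy
explicit: set to £207.62, it also reproduces the scenario's published
incremental cost (£242.67 vs £242.91) and an ICER near the published
£2,839/QALY. Downstream intervention-arm cost figures, and anything derived
from them (cost deltas, iNMB magnitudes), therefore differ from the published
values unless the knob is set; QALY results are unaffected.

A related rounding effect: the incremental QALYs computed from the printed
three-decimal inputs are 0.0849, not the published 0.086 (which arises from
unrounded source estimates). A ~0.0005 rounding error on each arm total is
amplified roughly twelvefold in their small difference. The per-arm totals
agree with the published figures to ≤0.05%.

## Scenarios

Scenarios are declarative overrides on the single-sourced base bundle, and
each application is idempotent:

1. **Pooled QALYs** — one utility series per state, shared by both arms; any
   remaining QALY difference is attributable purely to transition dynamics.
2. **Classification at 10 weeks** — year-1 transitions replaced with the
   10-week-classification estimates and a non-degenerate share of the cohort
   entering in NCP. That share is not published; the default 0.10 is a
   labelled assumption, so this scenario's published row is a qualitative,
   not numerical, target.
3. **Common hospital costs** — year-1 hospital admission costs depend on the
   state only (CP £1,935, NCP £1,237 in both arms), isolating how much of the
   cost saving hinges on the intervention reducing admissions.

## Probabilistic sensitivity analysis

Every transition probability, utility weight and cost component receives a
distribution moment-matched to its point estimate: beta for [0,1] quantities,
gamma for costs, with standard deviation = dispersion × mean (default 0.15;
for means near 1 the SD is capped just inside the beta-feasible region).
Two-state rows are sampled as one beta draw on the to-CP probability with the
complement to NCP — equivalent to a Dirichlet row for two states. Exact zeros
and ones (e.g. the structural year-1 NCP row) and structural constants
(discount rate, horizon, one-off cost) are never sampled. The published
analysis does not print its hyperparameters or correlations, so its
probability of cost-effectiveness (0.62 at £20,000/QALY) and iNMB interval
are guides rather than targets; the default dispersion yields ≈0.66 with the
95% ellipse spanning all four quadrants, the same qualitative picture.

All draws come from one seeded generator in stable parameter order; runs are
byte-reproducible from the seed. Because the engine output is multilinear in
the independently sampled parameters, the PSA mean is an unbiased estimate of
the deterministic result — a property the tests exploit. The model is run
vectorised across draws, so 10,000 simulations take well under a second.

One structural caveat: for a dominant, mostly cost-saving intervention the
acceptability curve is *not* monotone in the threshold — at λ = 0 it equals
the fraction of cost-saving draws (≈0.96) and tends to the fraction of
QALY-gaining draws (≈0.63) as λ → ∞. Monotonicity holds on the subset of
draws with positive QALY gain, and that is the property asserted in the
tests.

## Synthetic data

The generator emulates the statistical structure the derivation assumes,
without attempting to reproduce the source studies' demographics: latent pain
states evolve first (Bernoulli year-1 exit in the trial, year-specific
matrices in the cohort), and observations are drawn conditionally on state —
OKS-PS uniform on the state's side of the threshold (so classification
recovers the latent state exactly), utilities Gaussian around state means and
capped at 1 (negative values allowed, as on the EQ-5D-3L), costs gamma with
coefficient of variation 0.5 and an optional point mass at zero.

Defaults are the published year-1 conditions where available: exit
probabilities 0.645 (intervention) / 0.506 (usual care), cohort dynamics and
state-mean series from the published years 2–5 rows, state-conditional cost
means from the published year-1 anchors. Values the publication does not
state were chosen once as field-typical: 2,000 patients per trial arm and
5,000 in the cohort (large enough for stable recovery demonstrations; the
source trial is smaller), baseline utility mean 0.45 with state means
0.50/0.72 at follow-up, SD 0.15, and a 50/50 CP/NCP cohort entry mix so both
transition rows have populated risk sets. The six-month state equals the
twelve-month state, consistent with the reported faster six-month exit in the
intervention arm. What passing recovery tests show is that the derivation
chain is consistent and unbiased under its own assumptions — not that it is
robust to features of real data the generator omits (informative missingness,
within-patient correlation of costs, measurement error straddling the OKS
threshold).

`implied_parameters` is the closed-form oracle for pipeline tests: the exact
bundle infinite data would yield, including the analytic mean of the capped
utility distribution and the mixture-weighted pooled hospital anchors.

## Numerical choices and degenerate inputs

Row-stochasticity and cohort mass are enforced to 1e-9 (tested to 1e-12 on
the fixture); totals are exact sums of per-cycle values. The ICER is computed
only on trade-off quadrants and left undefined (not ±inf) when ΔQALY = 0 or
under dominance. The coverage ellipse uses the sample mean/covariance scaled
by the χ²₂ quantile; a singular covariance raises. Report CSVs round at the
boundary only (2 dp money and QALY totals, 3 dp probabilities and incremental
QALYs); JSON outputs carry full precision.

## Known limitations

* Two states and annual cycles cannot represent within-year transitions; the
  published discussion notes the intervention's faster six-month exit is
  invisible at this resolution, biasing against the intervention.
* No mortality, no social-care costs, no price-year adjustment — all
  exclusions inherited from the modelled analysis.
* The intervention-arm published cost totals are reproducible only up to the
  documented constant gap; PSA dispersions are assumptions.
* Scenario 2's initial state split is an assumption; its published row cannot
  be checked numerically.
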