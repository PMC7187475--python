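# Methods

## Model structure

The analysis is a deterministic (expected-value) Markov cohort model, not a
microsimulation: a probability distribution over eleven states — ten tooth
health states plus an absorbing Death state — is propagated through
row-stochastic transition matrices, one 6-month cycle at a time, from age
15 to age 85 (140 cycles). All eight permanent molars are treated as
exchangeable and independent, each starting from the same baseline
distribution (82.7% sound, 2.5% enamel decay, 0.3% dentine decay, 3.6%
filled, 10.9% missing), so a single per-molar trace serves all eight:
per-molar quantities (QALY, DMFT-time) are read off the trace directly and
costs are multiplied by eight.

Death is modelled explicitly rather than as leakage so that occupancy mass
is conserved at every cycle — a property the test suite checks to 1e-9 —
and so that survival-gated accruals (the varnish fee) are well defined.
Caries history is irreversible: no transition may re-enter NoDisease, and
the validator rejects matrices that try.

### Age indexing and mortality

Transition matrices are indexed by integer age; the matrix for a fractional
age uses the floor (two cycles share each age band). Bands run 15–75; ages
76–85 reuse the age-75 band for *caries dynamics*, while background
mortality continues to rise with actual age: the mortality augmentation
builds bands 76–84 from the age-75 tooth matrix plus the actual age's death
probability. The per-cycle death probability is `p = 1 − (1 − q_a)^0.5`
from the annual `q_a`, applied uniformly across tooth states (tooth state
does not alter survival), scaling each row by `(1 − p)` and assigning `p`
to Death.

### The intervention mechanism

The prevented fraction PF scales selected transition probabilities by
`(1 − PF)`; the removed mass is added to the **source state's
self-transition**, not redistributed proportionally, because the varnish's
mechanism is to hold the tooth in its current state longer. This makes
row-sum preservation exact by construction. Base case: PF = 0.43 on
NoDisease→EnamelDecay and EnamelDecay→DentineDecay, constant over the whole
horizon (constant long-term efficacy, 100% adherence). Because the PF
adjustment and the uniform mortality scaling commute, applying PF before
mortality augmentation (as the scenario runner does) is exact.

Scenario 1 extends the affected set with DentineDecay→Filling and
scenario 2 further with Filling→RepeatFilling. The clinical wording behind
scenario 1 is ambiguous; we read "reduce dental caries from X" as
inhibiting the outflow of X, and keep the affected sets config-driven so
any alternative reading is a one-line change. Note a structural
consequence: inhibiting DentineDecay→Filling moves mass between two
DMFT-flagged states, so scenario 1's DMFT equals the base case's while its
cost falls (fewer filling events) and its QALY falls (longer dwell in
untreated dentine decay, utility 0.24). Scenario 3 keeps base-case efficacy
and doubles the per-cycle varnish fee (two applications per cycle,
$75.40), leaving both effect measures unchanged.

## Economic accumulation

- **Event costing.** A state's unit cost is charged on the incident mass
  *entering* it each cycle (`entries(k+1)[t] = Σ_{s≠t} x_k[s] P_k[s,t]`),
  so each re-entry into RepeatFilling re-incurs the filling fee ($203, the
  minimum-cost assumption), and baseline prevalence is not billed. No
  ongoing background cost accrues in any state.
- **QALY / DMFT-time.** Whole-cycle accrual on the cycle-start occupancy
  (no half-cycle correction by default; a trapezoid correction is available
  behind `half_cycle_correction`). DMFT is accumulated as discounted years
  in DMFT-flagged states per molar; a `dmft_aggregation_factor` (default 1)
  is exposed because the published totals' aggregation is not fully
  determined — though the per-molar reading is the only one consistent
  with the printed numbers: summing over eight molars would have a hard
  floor of 8 × 0.148 × 19.34 ≈ 22.9 discounted DMFT-years from the
  baseline distribution alone, above the printed 15.52.
- **Intervention cost.** $37.70 per application cycle, accrued only while
  alive (charging the dead is indefensible), independent of tooth state.

### Discounting convention

Discounting is annual-step: the factor is constant within each model year
(`discount_factor(r, t) = (1+r)^−⌊t⌋`). The timing switch
`discount_timing` fixes which year's factor a cycle's accruals receive:

- `year_end` (default): amounts accrued in model year *y* are discounted by
  `(1+r)^−(y+1)` — the ordinary-annuity convention of a spreadsheet NPV
  column. Under it the 70-year varnish annuity is
  `37.70 × 2 × Σ_{y=1..70} 1.05^−y ≈ $1458`, within 0.5% of the published
  $1465 intervention cost.
- `year_start`: `(1+r)^−y` (annuity-due), giving ≈ $1531 for the same
  annuity.
- `cycle_end`: continuous per-cycle compounding `(1+r)^−(k+1)/2`.

The published analysis does not state its convention; `year_end` is the
default because it is standard spreadsheet practice and best matches the
printed intervention-cost total. All three conventions agree at 0%
discounting, where QALY with full health and no mortality equals the
70-year horizon exactly.

### ICERs

`Δcost/Δeffect` with the effect oriented so benefit is positive
(prevented-DMFT = comparator − intervention; QALY gained = intervention −
comparator). A zero effect difference yields an explicit undefined flag,
never a division. Verdicts follow the standard cost-effectiveness-plane
rules against the AUD $28,033/QALY threshold: SE dominant, NW dominated,
NE cost-effective iff ICER ≤ threshold, SW iff ICER ≥ threshold. The
sensitivity interval on each ICER is deterministic — the scenario rerun at
the PF bounds (0.30, 0.57) — not a probabilistic analysis.

## Synthetic data and calibration

The comparator arm's transition probabilities were estimated from private
insurer claims data and never published, so the packaged matrices are
synthetic. The generator emulates what the analysis assumes: a one-way
restorative pathway with constant per-cycle base rates (constant caries
incidence; an optional multiplicative age gradient per decade defaults to
1.0), and a Gompertz-style life table (annual q doubling every 9 years
from 2×10⁻⁴ at age 15 — roughly 57% survival to 85, plausible for a
high-income population).

Calibration matches model **outputs**, never the unobtainable matrices: a
staged, bounded Nelder-Mead search over the logs of six parameters (caries
onset, enamel→dentine, dentine→filling, filling→repeat, one common scale
on the downstream restorative rates, and the mortality baseline) minimises
the summed squared relative error of the comparator totals against the
reference values. Bounds (per-cycle rates capped at 0.5–0.6, the refill
rate at 0.25, annual q₁₅ in [5×10⁻⁵, 1.5×10⁻³]) are part of the design:
without them the three 5%-discounted targets alone admit a degenerate
solution with near-certain caries onset per cycle. The packaged defaults
are the result of calibrating to the comparator column at **all three
discount rates** (nine targets), which pins the whole time path; they
reproduce every reference total within ≈1.5%. The search runs ≈4000
objective evaluations in under 30 s; each evaluation is one 140-cycle
cohort run. The reproducibility seed is 20190827.

The intervention arm is deliberately excluded from calibration; that its
emergent results land in the north-east quadrant, far below the
willingness-to-pay threshold, with scenario orderings matching the
published tables (scenario 3 ICERs strictly above base case; scenarios 1–2
cheaper but lower-QALY than base case) is the substantive validation.

### What the synthetic model does and does not show

Passing tests on the calibrated model demonstrate the *mechanics* —
conservation, monotonicity in PF and discount rate, ICER arithmetic,
calibration identifiability in output space — under one plausible
transition structure. They do not certify the published point estimates:
with the true matrices unpublished, the emergent intervention-arm totals
here differ from the printed ones (e.g. ICER per prevented-DMFT ≈ 590 vs
849), because the split of caries burden between onset and progression is
under-determined by comparator totals alone. The exact ICER arithmetic is
therefore checked separately by feeding the *published* per-arm totals
through `compute_icer`, which reproduces eleven of the twelve printed
ICERs within 1% (the twelfth, scenario 2 per QALY, recomputes to 1976 vs
the printed 1999 — a 1.15% gap fully attributable to the printed inputs'
rounding: a QALY difference printed as 0.46 carries ±2.2% ratio
uncertainty).

## Numerical choices and limitations

- Validation tolerances: row-stochasticity 1e-9; engine-vs-oracle
  agreement 1e-12 (the brute-force path-enumeration oracle accepts
  instances up to ~5 states × 6 cycles).
- The path-enumeration oracle, spreadsheet-style accumulation checks, and
  closed-form mortality/discounting examples are independent recomputations,
  not calls into the code paths they verify.
- Ties/degenerate inputs: PF = 0 leaves the model bitwise unchanged; equal
  arms produce an undefined-ICER flag; an all-identity model is valid and
  stationary.
- No between-teeth correlation, no caries-risk heterogeneity, no adherence
  modelling, no non-molar teeth, no hospitalisation offsets, no declining
  discount rates, no probabilistic sensitivity analysis — all outside the
  model's scope by design.
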