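# cariescea

A Markov cohort cost-effectiveness analysis of **biannual professional
fluoride varnish** versus current practice (non-routine application) for
preventing dental caries in the eight permanent molars, from a health-system
perspective, over a 70-year horizon.

The package is aimed at health economists and oral-health researchers who
want a tested, configurable re-implementation of this style of
decision-analytic dental model: state-transition mechanics, event-based
costing, QALY/DMFT accumulation under different discounting conventions,
ICERs with deterministic sensitivity intervals, and a calibrated synthetic
stand-in for transition probabilities that were never published.

## The model

A single molar occupies one of ten health states, ordered by clinical
progression:

> NoDisease → EnamelDecay → DentineDecay → Filling →
> {RepeatFilling, RootCanal, Crown, Extraction} → {Bridge, Implant}

plus an explicit absorbing **Death** state (background mortality, uniform
across tooth states). A cohort aged 15 is propagated in 6-month cycles until
age 85 (140 cycles) through age-indexed row-stochastic matrices `P_a`:

```
x_{k+1} = x_k P_{a(k)},   a(k) = ⌊15 + k/2⌋ (clamped to 75 for ages 76–85)
```

The intervention arm modifies two early-caries transitions by the *prevented
fraction* PF = 0.43 (95% CI 0.30–0.57): `p(ND→EN)` and `p(EN→DN)` are scaled
by (1 − PF), the removed mass returning to the source state's
self-transition. Varnish confers no benefit once a tooth is filled.

Per cycle the model accrues, discounted at 5%/yr (0% and 3.5% variants):

- **cost** — each state's unit cost (AUD, e.g. Filling $203, Implant $5316)
  charged on *entry*, times 8 molars; plus the varnish fee $37.70 per cycle
  per surviving individual in the intervention arm;
- **QALY** — occupancy × utility weight (e.g. DentineDecay 0.24, Filling
  0.77, Extraction 0.56) × ½ year, averaged per molar;
- **DMFT-time** — discounted years spent in DMFT-flagged states per molar.

ICERs are `Δcost / Δeffect` for both effect measures (prevented-DMFT and
QALY gained), judged against the AUD $28,033/QALY willingness-to-pay
threshold; prevented-fraction bound reruns give the sensitivity intervals,
and three scenarios vary the affected-transition set and application
frequency.

The original transition matrices derive from unpublished insurer claims
data, so `cariescea.synthetic_data` generates matrices with the assumed
structure and **calibrates** them (bounded Nelder-Mead on six rate
parameters) so the comparator arm reproduces the published comparator totals
at all three discount rates; the intervention arm is *never* calibrated — it
emerges from the PF mechanism.

## Worked example

```python
import cariescea as cc

core = cc.default_config()          # calibrated synthetic base case
results = cc.run_suite(core)        # base case, discount variants, scenarios 1-3
base = next(r for r in results if r.config.label == "base_case")
print(base.comparator.total_cost, base.comparator.dmft, base.comparator.qaly)
print(base.icer_dmft.icer, base.icer_qaly.icer, base.icer_qaly.verdict)
```

prints (to the shown precision):

```
comparator  : cost 2315  DMFT 15.44  QALY 14.52
intervention: cost 3455  DMFT 13.50  QALY 15.03
ICER per prevented-DMFT:  590  (309, 1086)
ICER per QALY gained   : 2241  (1175, 4125)
verdict: cost_effective NE
```

The comparator column sits within 1.5% of the published totals (2303,
15.52, 14.74) by calibration; the intervention row is emergent, lands in
the north-east quadrant (more costly, more effective) and is well below the
$28,033/QALY threshold, reproducing the study's qualitative conclusion.
Intervals in parentheses are the PF-bound reruns.

The same run is available from the shell:

```bash
caries-cea run --out-dir results/ --plot     # full suite + CE-plane PNGs
caries-cea scenario --label base_case
caries-cea calibrate --out gp.yaml           # re-run the calibration
```

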