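# Methods

## The model

`devtrans` implements a continuous-time stock-and-flow model of how a
child's *cognitive vulnerabilities* (CV; depressogenic attention and
rumination styles that raise depression and suicidal-ideation risk) and
*family support* (FS; the family's mobilized beneficial response) co-evolve
from age 0 to 21. Both stocks live on a 0–100 ratio scale with provisional
units (CVU, FSU; intermediate constructs use ACU and MBU), and every
equation is dimensionally consistent under the package's unit checker.

The state equations, with all effects routed through monotone table
functions (identity/linear by default):

```
AvoidantCoping        = ac_per_cv · table_ac(CV)
MaladaptiveBehaviors' = (mb_per_ac · table_mb(AvoidantCoping) − MB) / onset_mb_delay
PerceivedMB'          = (MB − PerceivedMB) / family_response_delay
PerceivedAC'          = (AvoidantCoping − PerceivedAC) / family_response_delay
IndicatedFS           = min(fr_mb_weight · PerceivedMB + fr_ac_weight · PerceivedAC, max_fs)
FS'                   = (IndicatedFS − FS) / fs_at
CV'                   = effect_mb_gain · table_emb(MB) · (max_cv − CV)/max_cv / cv_at
                        + TransitionShock(t)
                        − effect_fs_gain · table_efs(FS) · (CV/max_cv) / cv_at
```

School transitions (kindergarten, middle school, high school,
post-secondary; ages 5, 11, 14, 18) enter as pulse shocks of 50 CVU each.
The headroom factor `(max_cv − CV)/max_cv` on the inflow and the occupancy
factor `CV/max_cv` on the drain are the standard stock-to-own-flow
formulations; they appear in the loop analysis as minor balancing loops and
keep the stock inside its range structurally. Hard bounds are still
enforced by post-step clipping (logged on the trajectory); on the recovery
preset clipping never fires, and on escalation presets it fires only when a
pulse lands near the ceiling.

Three major feedback mechanisms arise:

* **R1** (reinforcing): CV → avoidant coping → (delayed) maladaptive
  behaviors → effect on CV → developmental inflow → CV. A vicious cycle
  while CV rises, a virtuous one while it falls.
* **B1** (balancing): maladaptive behaviors are perceived after the family
  response delay, raise the indicated level of support, FS adjusts toward it
  over `fs_at`, and the FS effect drains CV.
* **B2** (balancing): the same channel responding to perceived avoidant
  coping directly.

Both perception delays share `family_response_delay`, and both CV effects
share the single adjustment time `cv_at` — modeled as traits of the family
and of the child respectively. FS is assumed always beneficial
(`effect_fs_gain ≥ 0`). The two family-response channels combine
additively, capped at `max_fs`, which keeps B1 and B2 simultaneously active
while respecting the 0–100 scale.

## Parameters

| parameter | units | default (case1) | meaning |
|---|---|---|---|
| `initial_cv`, `initial_fs` | CVU, FSU | 10, 25 | stock levels at age 0 |
| `cv_at` | year | 0.75 | CV adjustment time (both effects) |
| `fs_at` | year | 0.75 | FS mobilization/step-down time |
| `family_response_delay` | year | 0.5 | perception delay (both channels) |
| `onset_mb_delay` | year | 2.0 | avoidant coping → maladaptive behaviors onset |
| `ac_per_cv` | ACU/CVU | 1.0 | coping per unit vulnerability |
| `mb_per_ac` | MBU/ACU | 1.0 | behavior per unit coping |
| `effect_mb_gain` | CVU/MBU | 0.5 | strength of R1 |
| `effect_fs_gain` | CVU/FSU | 0.9 | strength of the FS drain |
| `fr_mb_weight`, `fr_ac_weight` | FSU/MBU, FSU/ACU | 1.0, 1.0 | indicated support per perceived unit |
| `transition_times` | year | 5, 11, 14, 18 | school transitions |
| `transition_magnitude` | CVU | 50 | shock per transition |
| `pulse_smoothing_tau` | year | none | material-delay spread of the shock |

Smooth states are initialized in equilibrium with their inputs at t = 0
(`MB(0) = PerceivedMB(0) = mb_per_ac·AC(0)`, `PerceivedAC(0) = AC(0)`),
preventing spurious startup transients; scenarios may override this.

## Numerical scheme

Fixed-step integration on a uniform grid, default Euler at dt = 1/32 year
(standard system-dynamics practice; keeps pulse semantics exact), classic
RK4 available. Pulses are *left-point impulses*: the full mass
(`magnitude`) lands at the onset grid point and the continuous rates then
act on the boosted state for the remainder of the step, for both methods.
This makes the integrated shock exactly `magnitude` per pulse and lets
Euler (dt = 1/64) and RK4 (dt = 1/8) trajectories of every preset agree
within 1 CVU pointwise — the naive "pulse as a rate of magnitude/dt
evaluated with pre-pulse drains" formulation leaves a first-order offset of
`dt·Δ(drain)` at each onset. Clipping to declared bounds is applied both
when impulse mass lands and after the combined step, and every clip is
logged. Table inputs outside the breakpoint range clamp to the nearest
endpoint (the convention of graphical SD tools); the
continuously differentiable table variant replaces each linear segment by a
cubic Hermite smoothstep through the same breakpoints. Default identity
tables carry 11 collinear breakpoints so this variant is a ≤ 1-unit
perturbation of the linear form. The smoothed-pulse variant routes the
discrete pulse through a first-order material delay (pending-mass stock
draining at `pending/τ`, τ = 0.25 year by convention here), conserving the
integrated mass to well under 1%.

## Loop scores and dominance

For a link x → z at step t, the link score is the signed share of z's
change attributable to x, holding z's other inputs at their previous
values: magnitude `|Δₓz|/|Δz|` with `Δₓz = z(x(t), others(t−dt)) −
z(t−dt)`, sign `sign(Δₓz·Δx)`. Integration links (flow f → stock S)
attribute `dt·f` of the stock's net change, signed by the flow's structural
sign in the stock equation; links into a smooth state factor into a rate
re-evaluation score times a rate-to-state integration score (equivalent to
modeling the smooth with an explicit flow and contracting the two-node
chain). When either increment falls below ε = 1e−12 the score is 0,
avoiding division blow-ups at turning points.

Loop scores are products of link scores around each simple cycle of the
causal graph (enumerated with Johnson's algorithm via networkx; nine cycles
for this model: the three majors plus three stock–flow minors and three
smooth-state self-loops). Normalization divides by the sum of absolute
scores over *all* loops and scales to −100…100%; the net score is the sum
(positive ⇒ reinforcing mechanisms drive the trend); the dominant set is
the smallest group of loops whose cumulative absolute normalized score
reaches the threshold (default 50%). A single loop above 50% is dominant
alone.

Loop-score series oscillate much faster than the stocks themselves near
pulse onsets. For robustness comparisons the package therefore reduces a
run to its *leading-major sequence*: the debounced (segments ≥ 0.5 year)
order in which R1/B1/B2 hold the largest absolute normalized score. Under
±1% perturbation of any headline parameter this sequence is unchanged for
every preset while the shift times move by a bounded amount — the behavior
expected of genuine dynamics rather than numerical artifact, which would
jump discretely. The smooth-table and smoothed-pulse variants are checked
at the trajectory-pattern level: each preset keeps its qualitative label.

## Trajectory classification

Per transition, with pre-pulse level `pre`: the transition *registers a
shock* if CV rises by ≥ 20 CVU (`shock_min`) within 1 year of onset, and
*recovers* if the trough before the next transition returns to within 5 CVU
(`recovery_tol`) of `pre`. Labels, in order of precedence: `recovery` (all
transitions recovered), `tipping_after_k` (transitions 1..k recovered, none
after), `post_transition_escalation` (no recovery, final CV ≥ 95
(`escalation_ceiling`), and CV rose ≤ 2 CVU in the year before the first
transition), `chronic_escalation` (no recovery, final CV ≥ 95, already
rising), `stabilizing` otherwise. All constants are invented, configurable
classifier thresholds; the shock requirement exists because near the 100
ceiling a clipped pulse produces no real shock, and a constant trajectory
should not count as "recovered".

No equation contains a threshold on CV: tipping in the presets is emergent.
With purely linear effects the deterministic system is monostable, so the
tipping cases are slow–fast transients, not bistability: a high initial
stock of family support pins CV early (full recoveries), the support steps
down toward its low indicated level over a long `fs_at`, maladaptive
behaviors ratchet upward through the onset delay, and escalation starts
when R1's inflow outruns the bounded drain. Which transition tips is set by
the race between these two slow processes.

## Presets and the scenario sweep

The six presets are calibrated by the package authors to exhibit the six
qualitative families (quick recovery; chronic escalation from a predisposed
start; post-transition escalation after an initially stable phase; tipping
after the second, first, and third transition respectively); their YAML
files state this provenance. The sweep generator draws parameters uniformly
and independently from per-parameter ranges (default ±50% around case1,
clipped to admissible bounds) with a seeded generator — identical seeds give
bit-identical cohorts. Cohort tables (scenario, time, CV, FS, label,
dominant loops) serve as a synthetic-population fixture.

What the generator emulates: heterogeneity of individual trait parameters
and initial conditions under a shared school-transition schedule. What it
does not: measurement error or observation noise, within-person parameter
drift, family-level covariates, or any real sampling design — passing tests
demonstrate internal consistency of the model and analysis, not fit to
empirical trajectories.

## Known limitations

* Effects are monotone by construction; polarity-reversing relationships
  (e.g., support that becomes harmful) are out of scope.
* Only first-order delays; higher-order delay families are not provided.
* The loop-score attribution at a pulse-onset step is heuristic: the
  impulse lands before the continuous rates act, so recorded flows at that
  single step under-attribute the stock's change (normalization is
  unaffected).
* Dominance near stationary points is sensitive to the ε guard; scores are
  defined as 0 there by convention.
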