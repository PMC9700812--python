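# Methods

## Model definition

The state of the cell-cycle control network is a septuplet of Boolean
activities `(Cdh1, SBF, Cln2, Clb5, Clb2_G, Clb2_M, Cdc20)`; printed
7-digit strings use this order throughout.  The target (candidate)
functions are:

```
Cdh1*   = ~(Cln2 | Clb5 | Clb2_G | Clb2_M) | (Cdc20 & ~(Cln2 | Clb5 | Clb2_M))
SBF*    = start_gate | (SBF & ~(Clb2_G | Clb2_M))
Cln2*   = SBF
Clb5*   = (Clb5 | SBF) & ~(Cdh1 | Cdc20)
Clb2_G* = Clb2_M | ((Clb5 | Clb2_G) & ~Cdh1)
Clb2_M* = (Clb2_G | Clb2_M) & ~Cdh1 & (~Cdc20 | Clb5) & ~Cln2
Cdc20*  = Clb2_M | (Clb2_G & Cdc20)
```

`start_gate` is true only in the newborn state `1000000`, and only when
`Size > S0` and a fresh uniform draw falls below `min(1, (Size − S0)²)`.
The probability is capped at 1 because cells can exceed `Size − S0 = 1`
near division; the gate is restricted literally to `1000000`, so SBF can
never (re)activate from any other state, consistent with the single Start
edge of the transition graph.  The gate's Bernoulli trial is redrawn at
every engine iteration in which it is evaluated.

Updating is a Boolean Gillespie loop: enabled variables (those with
`B*_i ≠ B_i`) carry propensities `P_i = p_i`; the flipped variable is the
smallest index whose cumulative propensity exceeds `r1·P0` and the waiting
time is `Δt = −log(r2)/P0`.  Size grows as `Size·e^{μΔt}` over every
interval.  Three additional rules:

1. **Mitotic activation delays.**  When the selected transition is the
   activation (0→1) of Clb2_M or of Cdc20, `Δt` is drawn
   `lognormal(meanlog = log t_M_mean, sdlog = t_M_CV)` instead.  The delay
   replaces only the time increment — selection probabilities are
   untouched — and applies to activations only; deactivations race
   exponentially.  The single `t_M_mean` is shared by both variables.
   Delays are non-pre-emptive: once selected, the transition fires.
2. **G1 waiting.**  When nothing is enabled (the newborn state with the
   gate shut), the cell idles for `Δt = −log(r2)/p_G1` and retries; Size
   keeps growing.  With `p_G1 = 1 min⁻¹` the gate is attempted roughly
   once a minute.
3. **Asymmetric division.**  A Clb2_G 1→0 flip divides the cell at its
   post-growth size.  The mother keeps fraction
   `f ~ lognormal(log f_mean, f_CV)` (redrawn in the rare tail outside
   (0,1)); the daughter receives `1 − f`.  Division is treated as the
   birth of both progeny: each draws a fresh critical size
   `S0 ~ lognormal(log S0_mean, S0_CV)` and resets its birth clock.

Default parameters: all switch rates 1 min⁻¹ except `p_Cln2 = 10 min⁻¹`;
`μ = 0.007 min⁻¹`; `t_M_mean = 30 min`, `t_M_CV = 0.30`; `S0_mean = 0.4`,
`S0_CV = 0.05`; `f_mean = 0.58`, `f_CV = 0.05`.  Sizes are dimensionless
"physiological" units; 61.4 fL per unit is used only when binning against
volume-calibrated axes.

Randomness uses one root `numpy` SeedSequence per run; every cell owns an
independent substream and daughters spawn theirs from the mother's, so
population results are reproducible regardless of scheduling order.
Cells do not interact, so lineages are simulated one at a time to the
horizon; an event that would overshoot the horizon is discarded, leaving
the cell at its last accepted state.

## State-transition graph

The 128-node graph connects each state to every single-variable flip with
`P_i > 0`, weighted by `p_i`.  Without the Start edge the wild-type graph
is a DAG (verified by an explicit Kahn topological sort) with one root
`1101010` and one sink `1000000`; with the Start edge the unique
attracting cycle is the 14-state highway.  Expected return steps to the
highway solve the first-step linear equations of the propensity-weighted
jump chain (one step = one Boolean update; branch probabilities
`P_i/P0`, so Cln2 edges are 10× likelier than rate-1 competitors).  The
mean is reported both uniformly over all 114 off-highway states and over
the largest weakly connected component of the off-highway subgraph; in
the wild-type graph that component contains all 114 states, so the two
averages coincide (2.878, i.e. "three steps on average").

## Perturbation screen

Each highway state is perturbed in the five components other than the one
just updated and the one due next (70 perturbations; flipping Clb2_M on
also forces Clb2_G on, since high mitotic cyclin implies the residual
level).  Recovery is simulated growth-free — the gate never opens, so the
graph is a DAG onto the G1 sink — and timing is irrelevant to the
order-based classification, so only the embedded jump chain is sampled.

A trajectory is classified at its first spontaneous Clb2_G 1→0 flip
(division); reaching the sink without dividing is a harmless reset
(normal).  Bookkeeping flags accumulate from the highway history before
the perturbed state, from the flip itself, and from spontaneous events:

* *bud* — Cln2 or Clb5 active (history, flip, or event);
* *replication* — Clb5 or Clb2_G turned on spontaneously or in history
  (a flipped-on cyclin does not count as executed S phase);
* *mitotic entry* — a flipped-on or spontaneously activated mitotic
  cyclin; a bud emerging only after mitotic entry does not count;
* *spindle* — Clb2_M active (history, flip, or event);
* *segregation* — Cdc20 activated this cycle (history, flip, or event).

At division: if segregation has occurred, the exit is genuine — missing
or late bud ⇒ *no_bud_exit*, missing spindle ⇒ *exit_without_Clb2M*,
otherwise normal.  If Cdc20 was never activated, the division is lethal
(*exit_without_Cdc20*) only when replication had taken place; otherwise
the cell has merely degraded a spurious Clb2 and restarts G1.

These rules were fixed by requiring consistency with the full published
outcome table (several rows are exact simple-race values: 1/2, 1/6, 5/6)
and are validated two ways: Monte-Carlo trajectories classified from
event traces, and an exact dynamic program over the flag-augmented jump
chain; the two agree within binomial error for all 70 perturbations.
Exactly 12 perturbations have lethal outcomes, the overall normal
fraction is 90.8%, and the pooled premature-Cdc20 and premature-Cdh1
groups give 51.9% and 41.7%.  One printed row (Cdh1 flipped on at
metaphase, `0001110`) is reported as 87.12% normal where the exact
analysis gives 5/6 = 83.33%; no self-consistent variant of the
classification or the jump chain reproduces that row without moving
other rows off their printed values, so the package keeps the exact
value and documents the difference.

## Population statistics

A cycle runs from birth (the division flip, state `1000001`) to the
cell's own next division; `T_G1` ends at SBF activation (state
`1100000`, the operational bud-emergence marker) and `T_bud` covers the
rest, so `T_c = T_G1 + T_bud` identically.  The brief `1000001 → 1000000`
Cdc20-off interval is inside `T_G1`.  Founders start unborn (their first
segment is discarded); a cell's first completed cycle after being spawned
is a daughter cycle, all later ones are mother cycles.

The steady-state sampling protocol simulates 40 founder lineages with all
progeny and pools cycles born after a 400-min burn-in.  The horizon is
1200 min at slow growth (mass-doubling time 150 min; ≈ 11,000 records)
and 700 min at the default growth rate, where exponential proliferation
already yields ≈ 2,000 post-burn-in records (≈ 3.5 × the 40-founder
count per doubling); both sizes keep full runs in seconds.

Size-control slopes regress per-bin means of `μ·T_G1` on per-bin means of
`ln(size-at-birth)`, with birth sizes binned in 2-fL intervals
(61.4 fL/unit) and bins weighted by the square root of their occupancy;
bins with fewer than three records are dropped.  Mothers are fitted with
a single line; daughters with a continuous two-piece (hinge) fit whose
breakpoint, restricted to bin boundaries with at least two bins per
branch, minimizes the weighted squared error.  Analytic limits are exact:
a perfect sizer (`T_G1 = (ln S_target − ln S_birth)/μ`) gives slope −1
and size-independent `T_G1` gives 0.  At the defaults the mother slope is
≈ −0.33 and the daughter large-cell branch ≈ −0.34.  The daughter
small-cell branch comes out ≈ −0.9 to −1.0: below the Start threshold
the gate acts as a hard sizer whose local slope saturates at −1, and it
crosses −0.79 only in the bins around the threshold, so this number is
dominated by where the (freely fitted) breakpoint falls rather than by
the dynamics.

Synchrony experiments start 20 size-selected cells (Size 0.65) and track
per-minute population averages of every variable and of Size, plus the
percent-budded curve per bud-scar cohort (budded = between SBF activation
and the next division).  Population growth is summarized by an
exponential fit to the live-cell count; the fitted number-doubling time
matches `ln 2/μ` within 5% over four or more doublings.

## What the simulations do and do not show

All data in the tests are generated by the model itself under the default
parameterization; there is no external input.  The generator emulates
asynchronous proliferating populations with mother/daughter size
asymmetry and growth-gated Start, but not nutrient feedback, cell death,
spatial structure, or the generation-wise volume increase of real mother
cells (the dimensionless "physiological size" of a mother can shrink
between divisions).  Passing tests therefore certify the internal
consistency of the stochastic model and its estimators — not the wet-lab
numbers, which enter only as published comparison values.

## Numerical notes

* Candidate tables are precomputed for all 128 states per rule set; only
  the Start gate is evaluated per iteration.
* Hitting-step equations are solved densely with `numpy.linalg.solve`
  (114 unknowns); the step-count distribution is iterated to a 40-step
  horizon (residual mass < 1e−9).
* The exact perturbation oracle memoizes on (state, flag-tuple); the
  growth-free chain is a DAG, so the recursion terminates.
* Lognormal draws use `numpy`'s generator directly
  (`meanlog = log(mean)`, `sdlog = CV`), matching the published
  parameterization rather than moment-matched lognormals.
* Monte-Carlo cross-checks in the tests use 3-sigma bounds widened to
  4 sigma where tens of comparisons run simultaneously, and
  √2-inflated binomial error where two independent finite-rep estimates
  are compared.

## Known limitations

* The CV of `T_G1` is larger than experimental estimates (a known
  behaviour of this model class); means and slopes are unaffected.
* Mutant rule sets cover the published strains (single-Clb strain, its
  methionine-repressed Cln variant, and the cln3 deletion via a raised
  `S0_mean`, default 0.68 and configurable); arbitrary strains can be
  declared in config via Boolean expression overrides, but knocking a
  variable out entirely is lethal in a 7-variable Boolean model even
  where redundancy would rescue the real strain.
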