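# Methods

## Model structure

`ambucea` is a deterministic Markov cohort model of an ambulance fleet.
The cohort is indexed by state — Functioning (F), Breakdown (B), Beyond
Economic Repair (E) — and by integer age in completed years. Counts are
expectations and may be fractional. One cycle is one year; the default
horizon is 20 cycles. Transition probabilities depend on the age band of
the vehicle at the start of the cycle:

| band | ages | F→F | F→B | F→E | B→F | B→B | B→E |
|---|---|---|---|---|---|---|---|
| `le5` | 1–5 | 0.980 | 0.020 | 0.000 | 0.375 | 0.250 | 0.375 |
| `y6to10` | 6–10 | 0.893 | 0.087 | 0.020 | 0.129 | 0.161 | 0.710 |
| `gt10` | ≥ 11 | 0.525 | 0.378 | 0.097 | 0.141 | 0.016 | 0.843 |

E→F is 1: every BER vehicle is replaced by a new one the following year.
Both outgoing rows sum to one in every band, so total fleet size is
conserved analytically; the engine additionally asserts conservation at
every step.

Within a cycle the order of operations is:

1. **Scheduled replacement** — every vehicle whose age has reached the
   strategy's replacement age `A`, in any state, becomes a new Functioning
   vehicle of age 1.
2. **BER re-entry** — every remaining BER vehicle likewise becomes a new
   Functioning vehicle of age 1.
3. **Transitions** — surviving F and B sub-cohorts move with their
   start-of-cycle band's probabilities and age by one year.

New entrants do not transition in the cycle they are bought; they first
transition the following year at age 1. Whether replacement at exactly age
`A` happens at the start of the year or after completing it is not
determined by the policy statement alone; the package defaults to
start-of-cycle (`replacement_timing: start`) and also implements
end-of-cycle timing, in which vehicles transition first and anything that
has then passed age `A` is replaced.

A new vehicle has age 1 in its first modelled year (there is no age-0 band),
so a fleet replaced every `A` years occupies ages 1..`A`.

The B→E recursion uses the product `B_{t-1}·TP_BE`. Nothing else is
dimensionally coherent with the rest of the state equations, and it is the
only reading under which the rows conserve the fleet.

## Costs

All costs are in 2019 MYR. Unit inputs (packaged defaults): ambulance price
C_a = 300,175; medical equipment C_e = 188,825; personnel C_p = 123.99 and
fuel C_f = 18.84 per trip; minor maintenance C_mi = 481.69 and major
maintenance C_ma = 1,408.48 per service; repair C_w = 5,550.98 per
breakdown-year; resale value S = 0.10 · C_a = 30,017.50.

Per cycle the ledger computes

* operating: band-wise `U · (C_p + C_f) · (F + 0.5·B)`;
* maintenance: `C_mi · M_mi + C_ma · M_ma` with minor count
  `M_mi = (F + 0.5·B) · N_mi` (N_mi = 3, 3, 5 per band) and major count
  `M_ma = F + B` (one major service per vehicle-year);
* repair: `C_w · B` with the **full** breakdown count — the half-cycle
  factor applies only where operation is time-proportional (trips and minor
  maintenance), not to the fact of having broken down;
* replacement: `R · (C_a + C_e)` over all replacements, scheduled and BER;
* resale credit: `S · E` for the BER vehicles retired in the cycle. The
  credit is deliberately asymmetric — scheduled (non-BER) retirements are
  not credited by default, mirroring the resale rule as published; the flag
  `resale_on_scheduled` extends the credit to every retired vehicle for
  users who consider the asymmetry an artefact.

The ledger identity `TC = TC_o + TC_m + TC_w + TC_r − TS` is validated to
the cent on construction. Ledgers are computed for cycles 1..n from the
state occupying each year (the state produced by that cycle's step);
cycle 0 is the initial placement and incurs no cost. Horizon summaries are
mean annual values over cycles 1..n. An annual discount rate can be applied
to both costs and effects; the default is 0 because the source analysis is
undiscounted, and the mean is then the plain average.

## Effectiveness

Every ambulance is expected to deliver the optimum utilization
U* = 555 trips/year — the utilization achieved by vehicles aged ≤ 5 years,
under the assumption that young vehicles meet all demand. Functioning
vehicles deliver their band's utilization (555 / 385 / 294 trips/year),
breakdowns deliver half of it, BER vehicles are immobile and deliver
nothing. Missed trips per cycle are `fleet_size · U* − trips delivered`;
with one patient per trip, each missed trip carries mortality risk `m` for
the unattended patient, so deaths = missed trips × m. Lives saved by an
intervention strategy are the deaths it averts versus the comparator, and
ICER = incremental cost / lives saved, reported only when lives saved is
positive (dominance and trade-off quadrants are labelled instead).

**Mortality presets.** The published sources are internally inconsistent:
the stated rate is 4.0 % ("the middle point" of a 2.5–6.1 % literature
range, though 4.0 % is not that midpoint), while the published worked
results' death counts equal missed trips × 3.5 % exactly. The package
defaults to the stated 0.040 and exposes a documented `table4` preset with
0.035; it does not guess which was intended. The choice scales deaths (and
hence inversely scales the ICER) linearly and does not change the decision
at the default threshold.

## Synthetic initial fleets

The real 1,891-vehicle fleet's age distribution is not available in
machine-readable form, so `ambucea.fleet.generate_fleet` synthesizes one:
uniform over ages 1..15 by default (a neutral stand-in), geometrically
young- or old-skewed profiles, custom per-age weights, and an optional
seeded Dirichlet jitter for scenario ensembles. All generated vehicles
start Functioning. `integerize` converts a fractional cohort to whole
vehicles by largest-remainder rounding for the per-ambulance
microsimulation used as an independent cross-check of the engine.

Because the initial age distribution is synthetic, the absolute per-strategy
cost levels are scenario-dependent and are not comparable to any particular
historical fleet; what the model preserves across reasonable initial
distributions is the decision structure (the 10-year policy costs more,
misses fewer trips, and buys lives below the threshold ICER). The generator
also does not emulate fleet growth, heterogeneous vehicle types, or
urban/rural utilization differences — none of which are in the model's
scope.

## Sensitivity analysis

**One-way DSA.** Each uncertain input is varied to base × (1 ± 0.20) in
isolation (the packaged `dsa_fraction`), the full two-strategy model is
re-run, and inputs are ranked by the absolute ICER swing (tornado order).
The varied set is every parameter with an uncertainty distribution —
six transition probabilities, three utilizations, the mortality rate and
eight unit costs — plus the optimum utilization. Probability perturbations
are clipped to [0, 1].

**Row renormalization.** Varying one probability in a transition row breaks
the simplex; the other two probabilities in the row are rescaled
proportionally so the row sums to one again. The same rule restores
validity after PSA draws.

**PSA.** Each iteration draws one joint parameter vector: Beta(α, β) for
the six transition probabilities with published Beta parameters, and Gamma
for utilizations, mortality and costs. The Gamma parameterization is not
published; the package moment-matches it from the only printed information,
treating the ±20 % range as a 95 % interval: sd = (high − low)/(2·1.96),
shape = (mean/sd)², scale = mean/shape. The same vector is applied to both
strategies (common random numbers — the model is deterministic given
parameters, so incrementals reflect parameter uncertainty only). The
optimum utilization has no published distribution; since it is defined as
the ≤ 5-year utilization, it follows the sampled `utilization_le5` draw
(`tie_optimum_to_le5`, on by default) rather than varying independently,
which keeps young-band missed trips non-negative. The CEAC is the fraction
of iterations with positive net monetary benefit `WTP·ΔE − ΔC` on a WTP
grid from 0 to MYR 120,000 (three times GDP per capita) in steps of 2,000.
CE-plane quadrants are labelled I–IV anticlockwise from the northeast
(I: costlier and more effective).

Default problem sizes: 10,000 PSA iterations; the engine cross-check uses
an integer fleet of 200 with 5,000 microsimulation replicates, which gives
Monte-Carlo standard errors small enough to detect band-level errors while
keeping the whole suite fast.

## Numerical and degenerate-input choices

* Row-sum validation tolerance 1e-9; fleet conservation asserted to 1e-6
  relative at every step; ledger identity to MYR 0.01.
* Negative missed trips (possible only if a band utilization exceeds the
  optimum, e.g. under an adversarial DSA perturbation of the optimum) are
  warned about and clamped to zero only when `clamp_missed_trips` is set;
  by default the negative value propagates so that the misconfiguration is
  visible.
* If proportional renormalization of a row is impossible because the other
  two entries are both zero, the remainder is assigned to the diagonal
  (stay-put) entry.
* ICERs for dominance/equivalence map to 0 for tornado ranking (the
  intervention wins at any WTP); genuinely undefined cases propagate NaN
  and sort last.
* Monetary outputs are written with two decimals; internal arithmetic is
  full precision.

## Known limitations

* The model is a cohort of expectations: it reports no stochastic
  between-year variability for a single fleet (the microsimulation exists
  as a verification oracle, not a results path).
* Transition probabilities are stationary within age bands over the whole
  horizon; fleet size is fixed; there is no within-year dynamics.
* The outcome unit is lives saved via a constant per-missed-trip mortality;
  no QALYs, no severity mix, no alternative-transport survival gradient.
* Absolute cost levels depend on the synthetic initial age distribution
  (see above); comparisons between strategies are the supported output.
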