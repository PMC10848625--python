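# ambucea

Cost-effectiveness analysis of ambulance-fleet replacement strategies with an
age-structured Markov cohort model.

Emergency medical services depend on a functioning ambulance fleet, but
ambulances age: they break down more often, deliver fewer trips, and
eventually become Beyond Economic Repair (BER). Health ministries weighing a
compulsory replacement policy — e.g. replace every ambulance at 10 years
versus 15 years — face a trade-off between the capital cost of replacing
vehicles more often and the missed emergency trips (and resulting deaths)
caused by an older, less reliable fleet. `ambucea` implements a tested,
reusable model of that trade-off for health-economics analysts, parameterised
by default with 2019 data for the Malaysian Ministry of Health fleet of 1,891
ambulances.

## The model

Each ambulance occupies one of three states — Functioning (F), Breakdown (B)
or BER (E) — and carries an integer age in years. Annual transition
probabilities depend on the age band (≤ 5, 6–10, > 10 years). The cohort
recursion per cycle is

```
F_t = F_{t-1}·TP_FF + B_{t-1}·TP_BF + E_{t-1} + R_sched
B_t = F_{t-1}·TP_FB + B_{t-1}·TP_BB
E_t = F_{t-1}·TP_FE + B_{t-1}·TP_BE
```

where `E_{t-1}` re-enters as new age-1 vehicles (all BER vehicles are
replaced the following year) and `R_sched` replaces every vehicle that has
reached the strategy's replacement age. The annual cost ledger is

```
TC = TC_o + TC_m + TC_w + TC_r − TS
TC_o = Σ_band U·(C_p + C_f)·(F + 0.5·B)        (operating)
TC_m = C_mi·M_mi + C_ma·M_ma                    (maintenance)
TC_w = C_w·B                                    (repair)
TC_r = R·(C_a + C_e)                            (replacement)
TS   = S·E                                      (resale credit, S = 0.10·C_a)
```

with the half-cycle factor `0.5·B` crediting broken-down vehicles half a
year's operation. Effectiveness is measured in lives saved: every ambulance
is expected to deliver the optimum utilization `U*` (the trips/year of a
young ambulance, 555); the fleet's shortfall is the number of missed trips,
each carrying a mortality risk `m` for the unattended patient. Two
strategies are compared by the incremental cost-effectiveness ratio
ICER = ΔC/ΔE in MYR per life saved against a willingness-to-pay threshold of
MYR 40,000 (one GDP per capita). One-way deterministic sensitivity analysis
(± 20 %, tornado ranking) and probabilistic sensitivity analysis (Beta
distributions where published, moment-matched Gammas elsewhere; CE plane and
CEAC) quantify parameter uncertainty.

See `docs/methods.md` for assumptions, parameter tables and numerical
choices.

## Worked example

The initial age distribution of the real fleet is not publicly available, so
the example spreads 1,891 ambulances uniformly over ages 1–15 (the package
can synthesize skewed or custom distributions instead):

```sh
ambucea run --strategies 15 10 --scheme uniform --max-age 15 --out-dir out/
```

prints

```
replace-at-10y vs replace-at-15y: incremental cost MYR 37,947,389.47/yr,
lives saved 4,112.2/yr, ICER MYR 9,228.05 per life saved -> cost-effective
at WTP 40,000
```

Replacing at 10 years costs an extra MYR 37.9 million per year (mostly
additional replacement and operating cost), but the younger fleet misses
about 102,800 fewer trips per year; at a 4 % mortality risk per missed trip
that averts about 4,112 deaths per year, so each life saved costs about
MYR 9,228 — well under the MYR 40,000 threshold, making the 10-year policy
cost-effective. `out/` also receives the per-cycle cost ledgers, traces,
outcome tables and a manifest recording every assumption flag in force.

Sensitivity analyses:

```sh
ambucea dsa --out-dir out-dsa/            # tornado table (tornado.csv)
ambucea psa --n-iter 10000 --out-dir out-psa/   # CE plane samples + CEAC
```

The tornado is led by the non-conveyance mortality rate and the ambulance
utilization inputs, while fuel, maintenance and repair unit costs barely
move the ICER. In the PSA every iteration shows a positive incremental
cost, essentially all iterations land in the northeast quadrant of the CE
plane, and the CEAC passes 50 % near the base-case ICER, far below the
threshold.

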