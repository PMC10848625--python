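# Default parameter set: Malaysian MOH ambulance fleet, valued in 2019 MYR.
# Transition probabilities and effectiveness inputs by ambulance age band;
# unit costs per ambulance service component; uncertainty distributions for
# sensitivity analysis.

transition_probabilities:
  le5:      {ff: 0.980, fb: 0.020, fe: 0.000, bf: 0.375, bb: 0.250, be: 0.375}
  y6to10:   {ff: 0.893, fb: 0.087, fe: 0.020, bf: 0.129, bb: 0.161, be: 0.710}
  gt10:     {ff: 0.525, fb: 0.378, fe: 0.097, bf: 0.141, bb: 0.016, be: 0.843}

effectiveness:
  utilization:          # trips per ambulance per year, by age band
    le5: 555
    y6to10: 385
    gt10: 294
  optimum_utilization: 555          # demand target: trips/year a young ambulance delivers
  mortality_without_ambulance: 0.040  # probability of death per missed trip

maintenance_schedule:
  minor_per_year: {le5: 3, y6to10: 3, gt10: 5}
  major_per_year: 1

costs:                    # MYR
  ambulance_price: 300175.00
  equipment_price: 188825.00
  personnel_per_trip: 123.99
  fuel_per_trip: 18.84
  minor_maintenance: 481.69
  major_maintenance: 1408.48
  repair_per_breakdown_year: 5550.98
  resale_fraction: 0.10
  resale_value: 30017.50

model:
  n_cycles: 20
  fleet_size: 1891
  wtp: 40000.0
  discount_rate: 0.0
  seed: 0
  replacement_timing: start     # "start" or "end" of cycle
  resale_on_scheduled: false    # credit resale for scheduled (non-BER) retirements too
  clamp_missed_trips: false
  tie_optimum_to_le5: true      # optimum utilization follows the le5 utilization when varied

uncertainty:
  dsa_fraction: 0.20
  parameters:
    tp_fb_le5:    {dist: beta,  alpha: 24.480, beta: 1199.520, range: [0.016, 0.024]}
    tp_be_le5:    {dist: beta,  alpha: 15.250, beta: 25.417,   range: [0.300, 0.450]}
    tp_fb_y6to10: {dist: beta,  alpha: 22.738, beta: 238.618,  range: [0.070, 0.104]}
    tp_be_y6to10: {dist: beta,  alpha: 6.540,  beta: 2.671,    range: [0.568, 0.852]}
    tp_fb_gt10:   {dist: beta,  alpha: 15.172, beta: 24.966,   range: [0.302, 0.454]}
    tp_be_gt10:   {dist: beta,  alpha: 3.082,  beta: 0.574,    range: [0.674, 1.000]}
    utilization_le5:    {dist: gamma, range: [444, 666]}
    utilization_y6to10: {dist: gamma, range: [308, 462]}
    utilization_gt10:   {dist: gamma, range: [235, 353]}
    mortality_without_ambulance: {dist: gamma, range: [0.032, 0.048]}
    ambulance_price:    {dist: gamma, range: [240140.00, 360210.00]}
    equipment_price:    {dist: gamma, range: [151060.00, 226590.00]}
    personnel_per_trip: {dist: gamma, range: [99.19, 148.79]}
    fuel_per_trip:      {dist: gamma, range: [15.07, 22.61]}
    minor_maintenance:  {dist: gamma, range: [385.35, 578.03]}
    major_maintenance:  {dist: gamma, range: [1126.78, 1690.18]}
    repair_per_breakdown_year: {dist: gamma, range: [4440.78, 6661.18]}
    resale_value:       {dist: gamma, range: [24014.00, 36021.00]}
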