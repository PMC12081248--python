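# Posaconazole: triazole antifungal; UGT1A4 glucuronidation plus P-gp
# efflux; suspension shows Weibull dissolution-limited absorption with a
# large positive food effect (fed exposure 2.5-3x fasted); strong CYP3A4
# and P-gp inhibitor.
schema_version: 1
name: posaconazole
mw: 700.8
logp: 4.6
fu: 0.02
blood_plasma_ratio: 1.0
absorption:          # default: oral suspension, fasted
  model: weibull
  ka: 0.4
  f_abs: 0.35
  shape: 1.2
  scale: 4.0         # h
formulations:
  tablet:            # delayed-release tablet, food-insensitive
    model: first_order
    ka: 0.5
    f_abs: 0.6
fed_state:
  dissolution_scale: 0.8
  f_abs_factor: 2.7  # high-fat meal multiplies suspension bioavailability
pathways:
  - enzyme: UGT1A4
    clint_specific: 2510000.0   # uL/min/umol; lumped glucuronidation
  - enzyme: P-gp
    clint_specific: 1045000.0   # efflux/biliary component
renal_clearance: 0.0
interactions:
  - kind: inhibition
    target: CYP3A4
    type: competitive
    ki: 0.02       # umol/L unbound (potent at low unbound exposure)
  - kind: inhibition
    target: P-gp
    type: competitive
    ki: 0.5
therapeutic_window:
  metric: Cmin
  lower: 0.7
  upper: null       # prophylaxis target has no upper bound
  unit: ug/mL
  evaluation: trough at steady state
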