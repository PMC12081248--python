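# Cyclosporine: calcineurin-inhibitor immunosuppressant; CYP3A4 metabolism
# (liver + gut first pass) with a P-gp efflux component; inhibits CYP3A4
# and efflux/uptake transporters.
schema_version: 1
name: cyclosporine
mw: 1202.6
logp: 2.9
fu: 0.07
blood_plasma_ratio: 1.36
absorption:
  model: first_order
  ka: 0.6
  f_abs: 0.5
pathways:
  - enzyme: CYP3A4
    clint_specific: 960000.0
  - enzyme: P-gp
    clint_specific: 980000.0
renal_clearance: 0.0
interactions:
  - kind: inhibition
    target: CYP3A4
    type: competitive
    ki: 1.0
  - kind: inhibition
    target: P-gp
    type: competitive
    ki: 0.5
  - kind: inhibition
    target: OATP1B1
    type: competitive
    ki: 0.2
  - kind: inhibition
    target: BCRP
    type: competitive
    ki: 0.5
therapeutic_window:
  metric: Cmin
  lower: 200.0
  upper: 400.0
  unit: ng/mL
  evaluation: trough on day 6 of twice-daily dosing
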