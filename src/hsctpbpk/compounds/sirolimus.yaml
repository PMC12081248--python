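# Sirolimus: mTOR-inhibitor immunosuppressant; CYP3A4 metabolism with a
# P-gp efflux component; long half-life, low oral bioavailability.
schema_version: 1
name: sirolimus
mw: 914.2
logp: 4.3
fu: 0.08
blood_plasma_ratio: 1.0
absorption:
  model: first_order
  ka: 0.3
  f_abs: 0.15
pathways:
  - enzyme: CYP3A4
    clint_specific: 279000.0
  - enzyme: P-gp
    clint_specific: 181000.0
renal_clearance: 0.0
therapeutic_window:
  metric: Cmin
  lower: 3.0
  upper: 8.0
  unit: ng/mL
  evaluation: trough at steady state
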