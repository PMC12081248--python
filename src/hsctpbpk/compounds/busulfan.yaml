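# Busulfan: alkylating conditioning agent, GST-mediated conjugation.
# Values are curated literature-typical estimates (clearance back-calculated
# from adult systemic CL ~13 L/h), treated as fixtures.
schema_version: 1
name: busulfan
mw: 246.3          # g/mol
logp: -0.52        # hydrophilic
fu: 0.68           # ~32% protein bound
blood_plasma_ratio: 1.0
pathways:
  - enzyme: GSTA1
    clint_specific: 20800.0   # uL/min/umol; yields ~13 L/h systemic CL at reference GSTA1
renal_clearance: 0.0
# conditioning dosing is a 2 h iv infusion, 0.8 mg/kg q6h
therapeutic_window:
  metric: AUC
  lower: 900.0
  upper: 1350.0
  unit: uM*min
  evaluation: per 6 h dosing interval at steady state
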