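# Fosaprepitant: iv phosphoramide prodrug of aprepitant, converted by
# ubiquitous phosphatases with a half-life of minutes; modeled as
# first-order conversion in the blood pools. Interaction specs ride on
# aprepitant, the active species.
schema_version: 1
name: fosaprepitant
mw: 614.4
logp: -1.0
fu: 0.05
blood_plasma_ratio: 1.0
pathways: []
renal_clearance: 0.5    # minor urinary loss of intact prodrug
prodrug_to:
  target: aprepitant
  rate: 12.0            # 1/h, fast conversion
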