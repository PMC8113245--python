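name: gpcv2-fluor
version: v2
description: >
  Three-unit v2 tandem cascade switching BFP -> GFP -> mCherry -> iRFP720
  under alternating GA4 / ABA / GA4 treatment; all payloads PEST-tagged so
  fluorescence tracks the current stage.
schedule:
  stage_hours: 48.0
  gap_hours: 12.0
kinetics: paper-2021
gpcs:
  - recombinase: Cre
    ligand: GIB
    payloads:
      - {kind: protein, name: BFP, tags: [PEST]}
  - recombinase: Flp
    ligand: ABA
    payloads:
      - {kind: protein, name: GFP, tags: [PEST]}
  - recombinase: PhiC31
    ligand: GIB
    payloads:
      - {kind: protein, name: mCherry, tags: [PEST]}
terminal_payloads:
  - {kind: protein, name: iRFP720, tags: [PEST]}
att_wrapper: false
itr_flanks: true
notes:
  payload_order: four fluorescent reporters expressed sequentially, one per stage
  schedule: 48 h per stage with a 12 h gap, set by ligand washout kinetics
  ligand_reuse: GIB drives both stage 1 (Cre) and stage 3 (PhiC31); expression
    gating makes this safe because the downstream unit is silent until exposed
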