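name: gpcv2-crispra
version: v2
description: >
  Sequential transcription-activation cascade: Csy4-flanked sgRNAs recruit
  dCas9-VPR to four activation targets, one stage at a time (first-order
  activation model; targets are generic reporters).
schedule:
  stage_hours: 96.0
  gap_hours: 12.0
kinetics: paper-2021
gpcs:
  - recombinase: Cre
    ligand: GIB
    payloads:
      - {kind: sgRNA, name: sgACT1, tags: [Csy4_20nt_core, MALAT1_triple_helix]}
  - recombinase: Flp
    ligand: ABA
    payloads:
      - {kind: sgRNA, name: sgACT2, tags: [Csy4_20nt_core, MALAT1_triple_helix]}
  - recombinase: PhiC31
    ligand: GIB
    payloads:
      - {kind: sgRNA, name: sgACT3, tags: [Csy4_20nt_core, MALAT1_triple_helix]}
terminal_payloads:
  - {kind: sgRNA, name: sgACT4, tags: [Csy4_20nt_core, MALAT1_triple_helix]}
  - {kind: protein, name: dCas9-VPR, tags: []}
att_wrapper: false
itr_flanks: true
notes:
  targets: generic activation targets ACT1..ACT4; the published activation
    targets are interchangeable under the first-order activation model
  schedule: 96 h per stage, as for the editing cascade
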