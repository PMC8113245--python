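name: gpcv2-crispr
version: v2
description: >
  Sequential genome-editing cascade: Csy4-flanked sgRNAs against the
  colorectal tumor-suppressor loci APC, MLH1, SMAD4 and TP53, expressed one
  stage at a time from a Pol II transcript alongside the recombinase.
schedule:
  stage_hours: 96.0
  gap_hours: 12.0
kinetics: paper-2021
gpcs:
  - recombinase: Cre
    ligand: GIB
    payloads:
      - {kind: sgRNA, name: sgAPC, tags: [Csy4_20nt_core, MALAT1_triple_helix]}
  - recombinase: Flp
    ligand: ABA
    payloads:
      - {kind: sgRNA, name: sgMLH1, tags: [Csy4_20nt_core, MALAT1_triple_helix]}
  - recombinase: PhiC31
    ligand: GIB
    payloads:
      - {kind: sgRNA, name: sgSMAD4, tags: [Csy4_20nt_core, MALAT1_triple_helix]}
terminal_payloads:
  - {kind: sgRNA, name: sgTP53, tags: [Csy4_20nt_core, MALAT1_triple_helix]}
  - {kind: protein, name: Cas9, tags: []}
att_wrapper: false
itr_flanks: true
notes:
  loci: sgRNA cascade APC -> MLH1 -> SMAD4 -> TP53, the canonical sequential
    colorectal-cancer driver order
  schedule: 96 h per stage; sgRNA cascades need longer stages for editing to
    approach equilibrium
  sgRNA_format: 20-nt Csy4 core flanks release the sgRNA from the Pol II
    transcript; MALAT1 triple helix stabilizes the poly(A)-less mRNA
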