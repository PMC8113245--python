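name: attp-gpcv2-crispr
version: v2
description: >
  All-in-one self-deleting editing circuit: sgAPC -> sgMLH1 ->
  PuroR-sgSMAD4, with an att wrapper spanning the whole circuit so the
  stage-3 PhiC31 integrase deletes everything between the piggyBac ITRs,
  and a puromycin-resistance payload at stage 3 for synchronization.
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
      - {kind: protein, name: PuroR, tags: [PuroR, P2A]}
      - {kind: sgRNA, name: sgSMAD4, tags: [Csy4_20nt_core, MALAT1_triple_helix]}
terminal_payloads:
  - {kind: protein, name: Cas9, tags: []}
att_wrapper: true
itr_flanks: true
notes:
  cascade: sgAPC -> MLH1 -> PuroR-sgSMAD4; puromycin selection at stage 3
    synchronizes the population before self-deletion
  self_deletion: GIB at stage 3 activates PhiC31, which recombines the att
    wrapper and removes the whole circuit, leaving only the ITRs and an att
    scar (qPCR denominator)
  copy_number: deliberately limited to ~1 copy per cell; multi-copy cells
    can escape synchronization because one resistant copy suffices
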