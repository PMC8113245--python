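# tandemgpc

A compiler and stochastic population simulator for **tandem
gene-perturbation-cassette (GPC) circuits** — site-specific recombinase
state machines that walk mammalian cells through a programmed gene
expression cascade using just two alternating small-molecule ligands.

A GPC is a self-excising DNA unit: a split recombinase reconstituted by
chemically induced dimerization (gibberellin, GIB, or abscisic acid, ABA),
one or more payloads on the same Pol II transcript, and a terminator, all
flanked by the recombinase's own recognition sites (loxP, FRT, attB/attP).
Placed in tandem behind one promoter, only the promoter-proximal unit is
transcribed (*expression gating*), so adding the cognate ligand excises
exactly that unit, exposes the next one, and leaves a growing scar of
recognition sites behind. Two orthogonal ligands therefore suffice for an
arbitrarily long cascade, with ligand reuse at non-adjacent stages.

The package is for circuit designers and modelers who want to ask, before
cloning anything: what DNA does each stage of my design look like, how
synchronized will a population be under a given ligand schedule, how much
leak and memory loss should I expect, and what will the downstream assays
(flow cytometry, scar-amplicon NGS, indel NGS, qPCR) actually read out?

## The model

Each circuit copy is a continuous-time pure-birth Markov chain over stages
`1..N+1` (plus an absorbing DELETED state for att-wrapped self-deleting
circuits). The proximal unit's transition hazard is

```
λ(t) = h_exc · a(t) + h_leak · (1 − a(t))        [per hour]
```

where `a(t) ∈ [0,1]` is the cognate ligand's intracellular activity under
the exposure schedule and its washout pharmacokinetics (instant for
GA4/ABA, first-order with a 4 h half-life for trapped GA3-AM). Ligand
windows make hazards piecewise constant / piecewise exponential, so
simulation is event-driven and exact (exponential inversion inside
constant segments, thinning inside washout tails); `expected_occupancy`
propagates the same chain analytically with matrix exponentials. Payload
proteins follow production-while-proximal with first-order PEST decay;
sgRNAs keep editing after excision until they decay (the post-excision
editing lag); scar-amplicon sequencing applies an exponential per-cycle
PCR length bias `weight(L) = (1 + E(L))^C` with `E(L) = e_max − k_len·L`,
and inverts it for bias-corrected stage fractions.

## Worked example

```python
import tandemgpc as tg

preset = tg.load_preset("gpcv2-fluor")        # BFP→GFP→mCherry→iRFP720
params = tg.KineticParams(excision_hazard=0.087, leak_hazard=5e-4)
schedule = tg.LigandSchedule.alternating(preset.design.ligand_order(),
                                         stage_hours=48, gap_hours=12)
traj = tg.simulate_population(preset.design, params, preset.pk,
                              preset.copy_model, schedule, n=10_000, seed=1)
print(traj.occupancy.iloc[-1])
```

prints the stage occupancy at t = 168 h (end of the GA4→ABA→GA4 schedule):

```
stage_1    0.0001
stage_2    0.0294
stage_3    0.0145
stage_4    0.9560
```

95.6% of cells completed the cascade to the terminal iRFP720 stage; the
analytic twin `tg.expected_occupancy(...)` gives 0.9565 for the same
configuration. The ~3% left at stage 2 are cells whose Flp window passed
without excision; the 1.5% at stage 3 are awaiting the final payload
switch or leaked ahead early.

The compiler side turns the same preset into annotated per-stage
constructs (`gpc compile --preset gpcv2-fluor --out-dir out/` writes four
GenBank/FASTA pairs and a stage table with scar lengths and reading-frame
status). All bundled part sequences are seeded synthetic placeholders at
canonical lengths — the tool reasons about architecture, not about any
particular plasmid.

`scripts/demo_synchronization.py` is a documented demo of the
self-deleting editing circuit: puromycin selection at the PuroR stage,
scar-amplicon sequencing under the calibrated PCR length bias
(raw stage-3 read fraction 0.792 vs bias-corrected 0.887 — the raw
readout understates synchronization because the short stage-1 amplicon is
overamplified ~2.8-fold), and a Cas9/ITR qPCR ratio of 0.303 after one
48 h self-deletion window.

## Command line

```
gpc compile   (design.yaml | --preset NAME) --out-dir DIR
gpc validate  (design.yaml | --preset NAME)
gpc simulate  --preset NAME -n 10000 --seed 1 --out RUNDIR
gpc assay     flow|scarseq|editing|qpcr ...
gpc presets   list | show NAME
```

Exit codes: 0 ok, 1 input error, 2 design-validation failure. Every
simulation writes a JSON run manifest (design hash, parameters, schedule,
seed); re-running with the same seed reproduces outputs byte-for-byte.

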