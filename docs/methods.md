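# Methods

## Circuit compilation

A design is an ordered list of GPC units behind one constitutive
promoter. The stage-1 layout is

```
[ITR_L] [attP_wrap] promoter · leader · [ left · pad · 2A · recombinase ·
payloads · terminator · right ]×N · terminal payloads [attB_wrap] [ITR_R]
```

Excision is modeled as pure string rewriting: everything from the
proximal unit's left site through its right site is replaced by exactly
one scar site (the site itself for symmetric loxP/FRT pairs, an
attL-like hybrid for attB×attP). Excised circles are assumed lost; the
event is irreversible and re-integration is not modeled. Coordinates are
0-based half-open on the top strand; GenBank export converts to 1-based
inclusive via Biopython.

**Scar translation and frame padding (v2).** In the v2 architecture the
leader (Kozak context + ATG) puts the accumulated scar inside the coding
region, ahead of each unit's self-cleaving 2A. How the published
constructs keep the frame intact is not described anywhere we could
check, so the compiler adopts the simplest consistent rule: every site
and scar is padded 3' with `3 − (len mod 3)` neutral G bases. Each padded
scar is then a codon multiple, so codons never span scar junctions and
one stop-free check per scar suffices. This is an explicit assumption;
`frame_padding=False` disables it, and the validator then reports frame
breaks (e.g. a bare 34 bp loxP scar at stage 2). `scar_peptide` reports
the translated leader+scar peptide and a `frame_ok` flag at every stage.

**Self-deletion wrapper.** The att wrapper spans everything between the
piggyBac ITRs. Deletion is modeled as a single excision from the wrapper's
upstream att site through its downstream partner, leaving only the ITRs
and one att scar — the exact junction of the published circuit is not
specified, so the wrapper uses its own synthetic att pair distinct from
any in-cascade PhiC31 sites. At the PhiC31-proximal stage of a wrapped
design the self-deletion event *replaces* ordinary unit excision (the
integrase sees the wrapper, and the circuit ends there by design); leak
at that stage also routes to deletion, as it is the same recombination
event at basal rate.

**Scar amplicons.** Stage-identifying amplicons pair one forward primer
at the promoter 3' end with a reverse primer at the start of the
proximal recombinase ORF (unique per stage because recombinases differ).
Lengths grow with the accumulated scar across stages 1..N, mirroring the
156/195/198 bp stage ladder used by the scar-seq assay; those printed
lengths are used directly as inputs to the sequencing model.

**Part sequences.** The published plasmid sequences are not available, so
all bundled parts are deterministic seeded placeholders at canonical
lengths (34 bp loxP/FRT, 50/54 bp attB/attP, short stand-in ORFs),
labeled NON_PHYSIOLOGICAL in GenBank comments. Scar sites are
rejection-sampled to be stop-free when frame-padded so the v2 presets
translate cleanly. Nothing downstream depends on the particular strings:
all length and frame logic is computed from the part sequences at hand.

## Population dynamics

Each copy is a continuous-time pure-birth chain over stages `1..N+1`
plus DELETED. Only the proximal unit can fire (expression gating), with
hazard `h_exc·a(t) + h_leak·(1 − a(t))` where `a(t)` is the cognate
ligand activity. The CID assembly and recombination sub-steps are lumped
into this single first-order event, since only window-level completion is
observable. When both ligands are present, each unit still sees only its
cognate ligand; no interference is modeled. Leak advances exactly one
stage per event, after which the newly exposed unit leaks independently.

**Ligand activity.** 1 inside an exposure window; after washout either 0
(instant; GA4 and ABA presets, both cleared well within the 12 h schedule
gap) or `exp(−ln2·Δt/t½)` (first-order; the GA3-AM preset uses t½ = 4 h,
so complete clearance takes ~27 h — longer than the 12 h gap, which is
why the alternating schedules assume GA4). Activities below 0.01 are
floored to zero; the floor-crossing time is a breakpoint so the
simulation and the analytic solution see identical hazards.

**Simulation.** Event-driven within activity segments: exact exponential
inversion where hazards are constant, thinning against the segment's
hazard envelope inside washout tails. There is no time discretization
error. A single seeded NumPy generator drives all draws in a fixed
vectorized order, which makes runs bit-reproducible for a given seed;
per-cell substreams were considered and dropped as unnecessary for
reproducibility under this draw order. Stage entry times are stored per
copy, so occupancy, payload levels and exposure integrals at arbitrary
times are computed exactly from the event times rather than from saved
snapshots.

**Analytic twin.** `expected_occupancy` propagates the single-copy
distribution segment-by-segment: matrix exponential of the generator in
constant segments, stiff ODE integration (LSODA, rtol 1e-10) through
washout tails. Tests require Monte-Carlo agreement within 3 binomial
standard errors at n = 10,000 for every stage and time.

**Calibration (preset `paper-2021`).** All overridable:

| parameter | default | unit | rationale |
|---|---|---|---|
| excision_hazard | 0.2 | 1/h | ~99% single-copy excision within 24 h of ligand |
| leak_hazard | 5e-4 | 1/h | ~10% stage loss over 8 ligand-free days |
| payload_protein_halflife | 2 | h | PEST-tagged reporters track the current stage |
| sgRNA_halflife | 12 | h | editing approaches equilibrium by ~96 h |
| self_deletion_hazard | 0.0315 | 1/h | 78% circuit removal per 48 h window |

The headline cascade runs instead use an excision hazard of 0.087/h
(98.5% completion per 48 h window), the regime in which per-window
completion, not speed, is the binding constraint; both values are plain
parameters.

**Copy number and selection.** The copy-number model defaults to exactly
one copy per cell (the circuits are integrated at limiting transposon
dose). Selection survival depends on whether *any* copy carries the
marker stage — one resistant copy suffices, which is why multi-copy cells
escape synchronization. Inter-copy recombination (translocation risk) is
not simulated; multi-copy populations should be interpreted with that
caveat.

**Hazard fitting.** `fit_hazard_from_timecourse` fits `exp(−qt)` (leak)
or `1 − exp(−qt)` (excision) by least squares (the binomial MLE for the
per-cell exponential model when all time points share the same n), with
a percentile bootstrap CI over resampled time points. Non-monotone input
produces a warning, not an error.

## Assay models

**Flow cytometry.** Payload levels are deterministic ODE means
(steady-state normalized to 1) with optional multiplicative log-normal
cell-to-cell noise, CV 0.3 by default — the published distributions are
shown but never fitted, so the noise model is a stand-in shape. Gating
is single-channel with a default threshold of 0.1; the switching metric
is `%A+ / (%A+ or %B+)` and is NaN (with a warning) when no cell is
positive for either channel.

**Editing kinetics.** Indels accumulate per allele (ploidy 2 by default)
with probability `1 − exp(−h·∫g dt)`, where the cognate sgRNA abundance
`g` is 1 while its unit is proximal and decays with the sgRNA half-life
after excision — this produces the observed editing lag after each stage
transition. Monte-Carlo alleles carry fixed Exp(1) thresholds, so every
simulated path is monotone non-decreasing. The default demo hazard is
0.012/h per allele, which puts terminal frequencies in the 0.65–0.85
band over 96 h stages; per-gene rates are otherwise free, and NGS
frequency is taken to be the allele-level indel fraction. Cas9
availability is folded into the hazard (the nuclease is co-delivered and
constitutive; it is carried as a terminal payload only so the qPCR assay
has a cargo to count).

**PCR length bias.** Per-cycle efficiency `E(L) = clip(e_max − k_len·L,
0, 1)`, weight `(1+E)^C`. The preset fixes `e_max = 0.9`, `C = 25` (cycle
count for scar amplicons is unreported, so C is a free preset parameter)
and solves `k_len` from the calibration point that a 156 bp amplicon
out-amplifies a 196 bp one 1.042-fold per cycle (≈2.8-fold over 25
cycles, matching the 2.72–2.84-fold overrepresentation observed at
equimolar input; a linear E(L) cannot reproduce both printed endpoints
exactly). `bias_correct` divides counts by the weights — the exact
inverse of the observation expectation — and bootstraps a percentile CI
over multinomial resampling (1,000 resamples by default).

**qPCR.** The Cas9/ITR ratio is the fraction of copies (in alive cells)
not yet self-deleted: ITRs persist after deletion and serve as the
denominator.

## What the synthetic presets do and do not show

The bundled circuits reproduce the *architecture* of the three published
designs — unit order, ligand gating, payload identities, wrapper and ITR
placement, stage schedules (48 h fluorescent stages, 96 h sgRNA stages,
12 h gaps) — with placeholder DNA. The generator emulates single-copy
integration, expression gating, leak, washout kinetics, selection escape
and PCR bias. It does not emulate cell division or growth competition,
resource burden, recombinase protein dynamics, position effects of the
integration site, indel spectra, or inter-copy recombination. Passing
tests therefore demonstrate internal consistency of the model with its
calibration, not wet-lab accuracy of any particular number.

The activation-cascade preset (`gpcv2-crispra`) uses generic target names
ACT1–ACT4 under a first-order activation view, since the specific
activation targets are interchangeable at this level of abstraction. The
fluorescent preset omits the stage-1 zeocin marker: its position within
the 2A chain is unspecified and it affects no modeled readout.

## Numerical choices and degenerate inputs

Problem sizes: acceptance runs use 10,000 cells (binomial SE ≤ 0.5
percentage points on any fraction); tests use 100–10,000 depending on the
tolerance being exercised. Zero hazards give infinite waiting times
(handled as no-event); an empty cascade compiles to a single stage;
selection on an all-dead population and bias correction on all-zero
counts raise errors rather than returning silent zeros. Bootstrap
resamples that collapse to fewer than two distinct time points are
skipped. The activity floor (0.01) trades a ≤1% hazard truncation for a
finite breakpoint set shared exactly between the simulator and the
analytic solution.
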