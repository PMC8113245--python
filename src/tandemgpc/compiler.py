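"""Compile tandem GPC designs into annotated constructs and excise stages.

The compiler lays the design out as ``promoter . leader . [left_site .
(2A.)recombinase . payloads . terminator . right_site] x N . terminal
payloads`` (optionally wrapped by an att pair and piggyBac ITRs) and then
models every post-excision stage by string rewriting: excision removes
everything between the proximal unit's recognition sites and leaves exactly
one scar site.  In the v2 architecture the scar is translated (the leader
supplies the initiation codon), so the compiler frame-pads every site and
scar with neutral bases 3' of the site, keeping the reading frame intact as
scars accumulate.

Coordinates are 0-based, half-open, top strand throughout; GenBank export
converts to the 1-based inclusive convention.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

from . import parts as _parts
from .circuit import CircuitDesign, PayloadBlock
from .errors import (
    AmbiguousPrimer,
    DesignValidationError,
    NoMoreStages,
    UnsupportedVersion,
)

DELETED = "DELETED"


@dataclass(frozen=True)
class Segment:
    """One labeled piece of the construct sequence."""

    role: str      # e.g. "site_left", "recombinase", "scar", "promoter"
    label: str     # display name, e.g. "loxP", "Cre", "BFP"
    seq: str
    gpc_index: int = 0  # 1-based GPC the segment belongs to; 0 = shared


@dataclass(frozen=True)
class ScarRecord:
    """Bookkeeping of scars accumulated across completed stages.

    ``segments`` holds one entry per completed excision (scar site plus any
    frame padding), in genomic order.  The cumulative scar therefore only
    ever grows as the cascade advances.
    """

    segments: tuple[str, ...] = ()

    @property
    def cumulative(self) -> str:
        return "".join(self.segments)

    def extended(self, scar_seq: str) -> "ScarRecord":
        return ScarRecord(self.segments + (scar_seq,))


@dataclass(frozen=True)
class CompiledConstruct:
    """One stage of the compiled circuit: sequence, features, scar state."""

    design: CircuitDesign
    stage: object  # 1..N+1 or DELETED
    segments: tuple[Segment, ...]
    scar: ScarRecord

    @property
    def sequence(self) -> str:
        return "".join(s.seq for s in self.segments)

    @property
    def features(self) -> list[tuple[str, int, int, int]]:
        """(label, start, end, strand) in 0-based half-open coordinates."""
        feats, pos = [], 0
        for s in self.segments:
            if s.seq:
                feats.append((s.label, pos, pos + len(s.seq), 1))
            pos += len(s.seq)
        return feats

    @property
    def expressed(self) -> set[str]:
        """Names of elements expressed at this stage (proximal unit only)."""
        d = self.design
        if self.stage == DELETED:
            return set()
        if self.stage <= d.n_gpcs:
            g = d.gpcs[self.stage - 1]
            return {g.recombinase.name} | {p.name for p in g.payloads}
        return {p.name for p in d.terminal_payloads}

    @property
    def remaining_gpc_indices(self) -> list[int]:
        return sorted({s.gpc_index for s in self.segments
                       if s.role == "site_left"})


def _pad_for(design: CircuitDesign, site_seq: str) -> str:
    if design.version == "v2" and design.frame_padding:
        return _parts.frame_pad(site_seq)
    return ""


def compile(design: CircuitDesign) -> CompiledConstruct:
    """Build the stage-1 construct for a validated design."""
    violations = validate_design(design)
    if violations:
        raise DesignValidationError(violations)
    return _compile_unchecked(design)


def _compile_unchecked(design: CircuitDesign) -> CompiledConstruct:
    segs: list[Segment] = []
    if design.itr_flanks:
        segs.append(Segment("itr", "ITR_L", design.itr_left))
    if design.att_wrapper is not None:
        segs.append(Segment("att_left", design.att_wrapper.name + "_P",
                            design.att_wrapper.left_site))
    segs.append(Segment("promoter", design.promoter_name, design.promoter))
    if design.leader:
        segs.append(Segment("leader", "Kozak-ATG leader", design.leader))
    for g in design.gpcs:
        sp = g.recombinase.site_pair
        segs.append(Segment("site_left", sp.name, sp.left_site, g.index))
        pad = _pad_for(design, sp.left_site)
        if pad:
            segs.append(Segment("pad", "frame pad", pad, g.index))
        if design.version == "v2" and design.p2a:
            segs.append(Segment("p2a", "2A", design.p2a, g.index))
        segs.append(Segment("recombinase", g.recombinase.name,
                            "".join(g.recombinase.split_halves), g.index))
        for p in g.payloads:
            segs.append(Segment("payload", p.name, p.sequence, g.index))
        segs.append(Segment("terminator", "terminator", g.terminator, g.index))
        segs.append(Segment("site_right", sp.name, sp.right_site, g.index))
    for p in design.terminal_payloads:
        segs.append(Segment("terminal_payload", p.name, p.sequence))
    if design.att_wrapper is not None:
        segs.append(Segment("att_right", design.att_wrapper.name + "_B",
                            design.att_wrapper.right_site))
    if design.itr_flanks:
        segs.append(Segment("itr", "ITR_R", design.itr_right))
    return CompiledConstruct(design=design, stage=1, segments=tuple(segs),
                             scar=ScarRecord())


def excise_stage(construct: CompiledConstruct) -> CompiledConstruct:
    """Excise the promoter-proximal GPC, leaving a single scar site."""
    if construct.stage == DELETED:
        raise NoMoreStages("construct has been self-deleted")
    remaining = construct.remaining_gpc_indices
    if not remaining:
        raise NoMoreStages(
            f"stage {construct.stage} construct has no GPC left to excise"
        )
    k = remaining[0]
    segs = list(construct.segments)
    i_left = next(i for i, s in enumerate(segs)
                  if s.role == "site_left" and s.gpc_index == k)
    i_right = next(i for i, s in enumerate(segs)
                   if s.role == "site_right" and s.gpc_index == k)
    design = construct.design
    sp = design.gpcs[k - 1].recombinase.site_pair
    scar_pad = _pad_for(design, sp.scar_site)
    scar_segs = [Segment("scar", sp.name + " scar", sp.scar_site, k)]
    if scar_pad:
        scar_segs.append(Segment("scar_pad", "frame pad", scar_pad, k))
    segs[i_left:i_right + 1] = scar_segs
    return CompiledConstruct(
        design=design,
        stage=construct.stage + 1,
        segments=tuple(segs),
        scar=construct.scar.extended(sp.scar_site + scar_pad),
    )


def self_delete_construct(construct: CompiledConstruct) -> CompiledConstruct:
    """Excise across the att wrapper, leaving only ITR flanks and an att scar."""
    design = construct.design
    if design.att_wrapper is None:
        raise ValueError("design has no att wrapper; self-deletion impossible")
    if construct.stage == DELETED:
        raise NoMoreStages("construct already self-deleted")
    segs = list(construct.segments)
    i_left = next(i for i, s in enumerate(segs) if s.role == "att_left")
    i_right = next(i for i, s in enumerate(segs) if s.role == "att_right")
    scar = Segment("att_scar", design.att_wrapper.name + " scar",
                   design.att_wrapper.scar_site)
    segs[i_left:i_right + 1] = [scar]
    return CompiledConstruct(
        design=design, stage=DELETED, segments=tuple(segs),
        scar=ScarRecord((design.att_wrapper.scar_site,)),
    )


def enumerate_stages(design: CircuitDesign) -> list[CompiledConstruct]:
    """All post-excision stages in order (plus the self-deleted variant).

    Element ``k`` (0-based) equals ``k`` applications of
    :func:`excise_stage` to the compiled stage-1 construct; with an att
    wrapper a final DELETED construct is appended.
    """
    out = [compile(design)]
    for _ in range(design.n_gpcs):
        out.append(excise_stage(out[-1]))
    if design.att_wrapper is not None:
        out.append(self_delete_construct(out[-1]))
    return out


def scar_peptide(design: CircuitDesign, stage: int) -> tuple[str, bool]:
    """Peptide translated from the leader ATG through the accumulated scar.

    Only meaningful for v2 designs, where the scar is inside the coding
    region (v1 scars sit in the 5'UTR).  Returns ``(peptide, frame_ok)``;
    ``frame_ok`` is False if the cumulative scar is not a codon multiple or
    translation hits a stop before the 2A junction.
    """
    if design.version != "v2":
        raise UnsupportedVersion("scar translation applies to v2 designs only")
    if not 1 <= stage <= design.n_stages:
        raise ValueError(f"stage {stage} out of range 1..{design.n_stages}")
    construct = _compile_unchecked(design)  # frame breaks are reported, not fatal
    for _ in range(stage - 1):
        construct = excise_stage(construct)
    scar = construct.scar.cumulative
    peptide = "M" + _parts.translate(scar)
    frame_ok = (len(scar) % 3 == 0) and ("*" not in peptide)
    return peptide, frame_ok


def predict_amplicon(construct: CompiledConstruct, fwd_primer: str,
                     rev_primer: str) -> tuple[int, str]:
    """Predict the PCR product for a primer pair on one stage construct.

    Both primers must anneal exactly once, on opposite strands, with the
    forward primer upstream; otherwise :class:`AmbiguousPrimer` is raised.
    Returns ``(length, amplicon_sequence)`` inclusive of both primers.
    """
    seq = construct.sequence
    rc_rev = _parts.reverse_complement(rev_primer)
    n_f, n_r = seq.count(fwd_primer), seq.count(rc_rev)
    if n_f != 1:
        raise AmbiguousPrimer(
            f"forward primer found {n_f} times on the top strand (need 1)")
    if n_r != 1:
        raise AmbiguousPrimer(
            f"reverse primer found {n_r} times on the bottom strand (need 1)")
    start = seq.index(fwd_primer)
    r_start = seq.index(rc_rev)
    if r_start < start:
        raise AmbiguousPrimer("forward primer does not lie upstream of reverse")
    end = r_start + len(rc_rev)
    amplicon = seq[start:end]
    return len(amplicon), amplicon


def scar_amplicons(design: CircuitDesign, primer_len: int = 20
                   ) -> list[tuple[int, str]]:
    """Stage-identifying scar amplicons for stages 1..N.

    For each GPC stage the forward primer is the 3' end of the promoter and
    the reverse primer anneals at the start of the proximal recombinase ORF
    (unique per stage since recombinases differ).  Amplicon length grows
    with the accumulated scar, so it identifies the stage.
    """
    out = []
    stages = enumerate_stages(design)
    fwd = design.promoter[-primer_len:]
    for k in range(1, design.n_gpcs + 1):
        rec = "".join(design.gpcs[k - 1].recombinase.split_halves)
        rev = _parts.reverse_complement(rec[:primer_len])
        out.append(predict_amplicon(stages[k - 1], fwd, rev))
    return out


# --- validation -----------------------------------------------------------

def validate_design(design: CircuitDesign) -> list[str]:
    """Collect design violations (empty list = valid).

    Checks: adjacent units sharing both ligand and recombinase (premature
    co-excision), duplicate site pairs anywhere (cross-reaction), a v2
    leader without the initiation codon, sgRNA payloads missing Csy4 20-nt
    core flanks, and v2 scar frame breaks.  Ligand alternation is *not*
    enforced: expression gating lets non-adjacent units reuse a ligand.
    """
    v: list[str] = []
    if design.version == "v2" and "ATG" not in design.leader:
        v.append("v2 leader missing ATG initiation codon")
    for a, b in itertools.pairwise(design.gpcs):
        if (a.recombinase.name == b.recombinase.name
                and a.recombinase.ligand == b.recombinase.ligand):
            v.append(
                f"same recombinase in consecutive stages {a.index},{b.index}: "
                "premature co-excision")
    seen: dict[str, int] = {}
    for g in design.gpcs:
        sp = g.recombinase.site_pair.name
        if sp in seen and seen[sp] != g.index - 1:
            v.append(f"duplicate site pair {sp!r} in stages {seen[sp]} and "
                     f"{g.index}: cross-reaction risk")
        seen[sp] = g.index
    all_payloads = [(g.index, p) for g in design.gpcs for p in g.payloads]
    all_payloads += [(design.n_stages, p) for p in design.terminal_payloads]
    for idx, p in all_payloads:
        if p.kind == "sgRNA" and "Csy4_20nt_core" not in p.tags:
            v.append(f"sgRNA payload {p.name!r} (stage {idx}) missing "
                     "Csy4_20nt_core flanks")
    if design.version == "v2":
        cum = ""
        for g in design.gpcs:
            sp = g.recombinase.site_pair
            cum += sp.scar_site + _pad_for(design, sp.scar_site)
            stage_after = g.index + 1
            if len(cum) % 3 != 0:
                v.append(f"scar frame break at stage {stage_after}: cumulative "
                         f"scar length {len(cum)} not a codon multiple")
            elif _parts.has_stop_in_frame(cum):
                v.append(f"scar frame break at stage {stage_after}: stop codon "
                         "in translated scar")
    return v


# --- GenBank / FASTA export ----------------------------------------------

def to_seqrecord(construct: CompiledConstruct):
    """Convert a construct to a Biopython SeqRecord with annotated features."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    stage = construct.stage
    name = f"{construct.design.name}_stage{stage}"
    rec = SeqRecord(
        Seq(construct.sequence),
        id=name[:16].replace(" ", "_"),
        name=name[:16].replace(" ", "_"),
        description=f"{construct.design.name} stage {stage}",
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["comment"] = _parts.NON_PHYSIOLOGICAL_NOTE
    expressed = construct.expressed
    for label, start, end, strand in construct.features:
        quals = {"label": [label]}
        if label in expressed:
            quals["note"] = ["expressed"]
        rec.features.append(SeqFeature(
            SimpleLocation(start, end, strand=strand),
            type="misc_feature", qualifiers=quals,
        ))
    return rec
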