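"""Declarative description of tandem GPC circuits.

A gene perturbation cassette (GPC) is a self-excising DNA unit: a split
recombinase activated by chemically induced dimerization (CID), one or more
payload blocks on the same transcript, and a terminator, all flanked by the
recombinase's own recognition sites.  A :class:`CircuitDesign` is an ordered
tandem array of such units behind one constitutive promoter; because only
the promoter-proximal unit is transcribed, alternating exposure to just two
ligands (gibberellin and abscisic acid) can walk the array through an
arbitrarily long expression cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

LIGANDS = ("GIB", "ABA")

#: recombinase name -> expected recognition-site family
SITE_FAMILY = {"Cre": "loxP", "Flp": "FRT", "PhiC31": "att"}


@dataclass(frozen=True)
class SitePair:
    """Left/right recombinase recognition sites and the scar left by excision.

    Symmetric pairs (loxP, FRT) have identical left, right and scar
    sequences; asymmetric pairs (attB x attP) leave an attL/attR-like hybrid
    scar.
    """

    name: str
    left_site: str
    right_site: str
    scar_site: str
    symmetric: bool = True

    def __post_init__(self):
        if not self.scar_site:
            raise ValueError("scar_site must be non-empty")
        if self.symmetric and not (
            self.left_site == self.right_site == self.scar_site
        ):
            raise ValueError(
                f"symmetric site pair {self.name!r} requires "
                "left == right == scar"
            )


@dataclass(frozen=True)
class RecombinaseModule:
    """A ligand-gated split recombinase and its cognate site pair."""

    name: str
    ligand: str
    site_pair: SitePair
    split_halves: tuple[str, str] = ("", "")
    nls: bool = True

    def __post_init__(self):
        if self.ligand not in LIGANDS:
            raise ValueError(f"unknown ligand {self.ligand!r}; expected one of {LIGANDS}")
        fam = SITE_FAMILY.get(self.name)
        if fam is not None and fam not in self.site_pair.name:
            raise ValueError(
                f"recombinase {self.name} requires a {fam}-family site pair, "
                f"got {self.site_pair.name!r}"
            )


@dataclass(frozen=True)
class PayloadBlock:
    """One payload on a GPC transcript: a protein ORF or an sgRNA spacer.

    sgRNA payloads are cut out of the Pol II transcript by Csy4 acting on
    flanking 20-nt core sequences, and the residual poly(A)-less mRNA is
    stabilized by a MALAT1 triple-helix element; those facts are carried as
    tags and enforced by the design validator.
    """

    kind: str  # "protein" | "sgRNA"
    name: str
    sequence: str
    tags: frozenset = frozenset()

    def __post_init__(self):
        if self.kind not in ("protein", "sgRNA"):
            raise ValueError(f"payload kind must be protein or sgRNA, got {self.kind!r}")
        object.__setattr__(self, "tags", frozenset(self.tags))
        if self.kind == "protein" and len(self.sequence) % 3 != 0:
            raise ValueError(
                f"protein payload {self.name!r} length {len(self.sequence)} "
                "is not a codon multiple"
            )


@dataclass(frozen=True)
class GPCUnit:
    """One stage of the tandem array."""

    index: int
    recombinase: RecombinaseModule
    payloads: tuple[PayloadBlock, ...]
    terminator: str

    def __post_init__(self):
        object.__setattr__(self, "payloads", tuple(self.payloads))
        if not self.terminator:
            raise ValueError(f"GPC {self.index}: terminator must be non-empty")


@dataclass(frozen=True)
class CircuitDesign:
    """Ordered tandem GPC array plus the fixed flanking elements.

    ``version`` selects the scar architecture: v1 leaves scars in the
    5'UTR; v2 puts an initiation codon and Kozak sequence upstream of the
    array so accumulated scars are translated (each recombinase carries a
    5' self-cleaving 2A), which requires scars to preserve reading frame.
    ``att_wrapper`` spans the whole circuit for PhiC31-mediated
    self-deletion; ``itr_flanks`` adds piggyBac inverted terminal repeats,
    which persist after self-deletion.
    """

    name: str
    version: str  # "v1" | "v2"
    promoter_name: str
    promoter: str
    leader: str
    gpcs: tuple[GPCUnit, ...]
    terminal_payloads: tuple[PayloadBlock, ...] = ()
    att_wrapper: Optional[SitePair] = None
    itr_flanks: bool = False
    frame_padding: bool = True
    p2a: str = ""
    itr_left: str = ""
    itr_right: str = ""

    def __post_init__(self):
        if self.version not in ("v1", "v2"):
            raise ValueError(f"version must be v1 or v2, got {self.version!r}")
        object.__setattr__(self, "gpcs", tuple(self.gpcs))
        object.__setattr__(self, "terminal_payloads", tuple(self.terminal_payloads))

    @property
    def n_gpcs(self) -> int:
        return len(self.gpcs)

    @property
    def n_stages(self) -> int:
        """Number of expression stages (GPC stages plus the terminal stage)."""
        return len(self.gpcs) + 1

    def stage_payloads(self, stage: int) -> tuple[PayloadBlock, ...]:
        """Payloads expressed while ``stage`` (1-based) is proximal."""
        if not 1 <= stage <= self.n_stages:
            raise ValueError(f"stage {stage} out of range 1..{self.n_stages}")
        if stage <= self.n_gpcs:
            return self.gpcs[stage - 1].payloads
        return self.terminal_payloads

    def ligand_order(self) -> list[str]:
        return [g.recombinase.ligand for g in self.gpcs]


# --- dict round-trip (YAML schema) ---------------------------------------

def design_to_dict(design: CircuitDesign) -> dict:
    d = asdict(design)
    for g in d["gpcs"]:
        for p in g["payloads"]:
            p["tags"] = sorted(p["tags"])
        g["recombinase"]["split_halves"] = list(g["recombinase"]["split_halves"])
    for p in d["terminal_payloads"]:
        p["tags"] = sorted(p["tags"])
    return d


def design_from_dict(d: dict) -> CircuitDesign:
    def payload(p):
        return PayloadBlock(
            kind=p["kind"], name=p["name"], sequence=p["sequence"],
            tags=frozenset(p.get("tags", ())),
        )

    def site_pair(s):
        return SitePair(
            name=s["name"], left_site=s["left_site"], right_site=s["right_site"],
            scar_site=s["scar_site"], symmetric=s.get("symmetric", True),
        )

    gpcs = []
    for g in d.get("gpcs", ()):
        r = g["recombinase"]
        gpcs.append(GPCUnit(
            index=g["index"],
            recombinase=RecombinaseModule(
                name=r["name"], ligand=r["ligand"],
                site_pair=site_pair(r["site_pair"]),
                split_halves=tuple(r.get("split_halves", ("", ""))),
                nls=r.get("nls", True),
            ),
            payloads=tuple(payload(p) for p in g["payloads"]),
            terminator=g["terminator"],
        ))
    return CircuitDesign(
        name=d.get("name", "unnamed"),
        version=d["version"],
        promoter_name=d.get("promoter_name", "promoter"),
        promoter=d["promoter"],
        leader=d.get("leader", ""),
        gpcs=tuple(gpcs),
        terminal_payloads=tuple(payload(p) for p in d.get("terminal_payloads", ())),
        att_wrapper=site_pair(d["att_wrapper"]) if d.get("att_wrapper") else None,
        itr_flanks=d.get("itr_flanks", False),
        frame_padding=d.get("frame_padding", True),
        p2a=d.get("p2a", ""),
        itr_left=d.get("itr_left", ""),
        itr_right=d.get("itr_right", ""),
    )
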