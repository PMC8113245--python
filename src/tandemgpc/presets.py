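"""Bundled circuit presets and parameter calibrations.

The three tandem circuits (fluorescent cascade, editing cascade and the
self-deleting att-wrapped editing circuit) ship with placeholder part
sequences (see :mod:`tandemgpc.parts`) so every other module is testable
without external data.  Kinetic defaults are the "paper-2021" calibration:
rates chosen so that window-level completion, ligand-free memory decay and
self-deletion match the qualitative completion statements the circuits
were characterized by (near-complete excision within 24 h of ligand, about
10% stage leak over 8 ligand-free days, 78% circuit removal per deletion
window).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import parts as _parts
from .assays import BiasModel
from .circuit import (
    CircuitDesign, GPCUnit, PayloadBlock, RecombinaseModule, SitePair,
)
from .compiler import validate_design
from .dynamics import CopyNumberModel, KineticParams, PKLigand, PKParams
from .errors import PresetError

PRESET_NAMES = ("gpcv2-fluor", "gpcv2-crispra", "gpcv2-crispr",
                "attp-gpcv2-crispr")

#: hazard giving 78% self-deletion over one 48-h ligand window
SELF_DELETION_HAZARD = float(-np.log(1.0 - 0.78) / 48.0)


def kinetic_preset(name: str = "paper-2021") -> KineticParams:
    """Named kinetic calibration.

    ``paper-2021``: excision 0.2/h (~99% completion in 24 h of ligand),
    leak 5e-4/h (~10% stage loss over 8 ligand-free days), PEST protein
    half-life 2 h, sgRNA half-life 12 h, self-deletion hazard set for 78%
    removal per 48-h window.
    """
    if name != "paper-2021":
        raise PresetError(f"unknown kinetic preset {name!r}; available: paper-2021")
    return KineticParams(
        excision_hazard=0.2,
        leak_hazard=5e-4,
        payload_protein_halflife=2.0,
        sgRNA_halflife=12.0,
        self_deletion_hazard=SELF_DELETION_HAZARD,
    )


def pk_preset(gib: str = "GA4") -> PKParams:
    """Ligand clearance presets.

    GA4 and ABA wash out effectively instantly on the schedule's 12-h
    timescale; GA3-AM is esterase-trapped and clears first-order with a
    4-h half-life (>12 h to complete washout).
    """
    if gib == "GA4":
        g = PKLigand("instant")
    elif gib == "GA3-AM":
        g = PKLigand("first_order", clearance_halflife=4.0, trapped=True)
    else:
        raise PresetError(f"unknown GIB ligand {gib!r}; available: GA4, GA3-AM")
    return PKParams(GIB=g, ABA=PKLigand("instant"))


def scarseq_bias_preset(name: str = "paper-2021-scarseq") -> BiasModel:
    """PCR length-bias calibration for scar-amplicon sequencing.

    ``e_max`` = 0.9 and 25 cycles; ``k_len`` solves the calibration
    equation that a 156-bp amplicon out-amplifies a 196-bp one by a
    per-cycle efficiency ratio of 1.042, i.e. ~2.8-fold over 25 cycles —
    the overrepresentation observed for stage-1 scar amplicons in
    equimolar mixtures.
    """
    if name != "paper-2021-scarseq":
        raise PresetError(
            f"unknown bias preset {name!r}; available: paper-2021-scarseq")
    ratio, short, long_ = 1.042, 156.0, 196.0
    e_max = 0.9
    # (1 + e_max - k*short) = ratio * (1 + e_max - k*long)
    k_len = (1.0 + e_max) * (ratio - 1.0) / (ratio * long_ - short)
    return BiasModel(e_max=e_max, k_len=k_len, cycles=25, read_depth=100_000)


@dataclass(frozen=True)
class Preset:
    """A bundled circuit plus its calibrated parameters."""

    name: str
    description: str
    design: CircuitDesign
    kinetics: KineticParams
    pk: PKParams
    copy_model: CopyNumberModel
    stage_hours: float
    gap_hours: float
    notes: dict = field(default_factory=dict)


def _site_pair(parts: dict, family: str, name: str | None = None) -> SitePair:
    s = parts["sites"][family]
    return SitePair(name=name or family, left_site=s["left"],
                    right_site=s["right"], scar_site=s["scar"],
                    symmetric=s["symmetric"])


def _materialize(spec: dict) -> CircuitDesign:
    """Turn a preset YAML structure into a full design with part sequences."""
    parts = _parts.standard_parts()
    fam_of = {"Cre": "loxP", "Flp": "FRT", "PhiC31": "att"}

    def payload(p):
        tags = frozenset(p.get("tags", ()))
        if p["kind"] == "sgRNA":
            seq = (parts["csy4_core"] + parts["spacers"][p["name"]]
                   + parts["csy4_core"])
        else:
            seq = parts["coding"][p["name"]]
        return PayloadBlock(kind=p["kind"], name=p["name"], sequence=seq,
                            tags=tags)

    gpcs = []
    for i, g in enumerate(spec["gpcs"], start=1):
        rec_name = g["recombinase"]
        gpcs.append(GPCUnit(
            index=i,
            recombinase=RecombinaseModule(
                name=rec_name, ligand=g["ligand"],
                site_pair=_site_pair(parts, fam_of[rec_name]),
                split_halves=(parts["coding"][f"{rec_name}_N"],
                              parts["coding"][f"{rec_name}_C"]),
            ),
            payloads=tuple(payload(p) for p in g["payloads"]),
            terminator=parts["terminator"],
        ))
    att_wrapper = None
    if spec.get("att_wrapper"):
        w = parts["sites"]["att_wrapper"]
        att_wrapper = SitePair(name="att_wrapper", left_site=w["left"],
                               right_site=w["right"], scar_site=w["scar"],
                               symmetric=False)
    return CircuitDesign(
        name=spec["name"],
        version=spec["version"],
        promoter_name="EFS",
        promoter=parts["promoter"],
        leader=_parts.kozak_leader() if spec["version"] == "v2" else "",
        gpcs=tuple(gpcs),
        terminal_payloads=tuple(payload(p)
                                for p in spec.get("terminal_payloads", ())),
        att_wrapper=att_wrapper,
        itr_flanks=spec.get("itr_flanks", False),
        p2a=parts["p2a"],
        itr_left=parts["itr_left"],
        itr_right=parts["itr_right"],
    )


def load_preset(name: str) -> Preset:
    """Load a bundled circuit preset by name (validated on load)."""
    if name not in PRESET_NAMES:
        raise PresetError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    ref = importlib.resources.files("tandemgpc") / "data" / f"{name}.yaml"
    spec = yaml.safe_load(ref.read_text())
    design = _materialize(spec)
    violations = validate_design(design)
    if violations:  # pragma: no cover - presets ship valid
        raise PresetError(f"preset {name} is invalid: {violations}")
    return Preset(
        name=name,
        description=spec.get("description", "").strip(),
        design=design,
        kinetics=kinetic_preset(spec.get("kinetics", "paper-2021")),
        pk=pk_preset(),
        copy_model=CopyNumberModel(),
        stage_hours=float(spec["schedule"]["stage_hours"]),
        gap_hours=float(spec["schedule"]["gap_hours"]),
        notes=spec.get("notes", {}),
    )


def random_design(seed: int, n_stages: int, version: str = "v2"
                  ) -> CircuitDesign:
    """Deterministic random valid design for property tests.

    ``n_stages`` GPC units with alternating ligands, unique synthetic
    recognition sites per unit, and one protein payload each; always
    passes :func:`validate_design`.
    """
    if not 1 <= n_stages <= 8:
        raise ValueError("n_stages must be in 1..8")
    rng = np.random.default_rng(seed)
    gpcs = []
    for i in range(1, n_stages + 1):
        site_len = int(rng.integers(8, 15)) * 2  # 16..28 bp
        site = _parts.random_site(rng, site_len)
        sp = SitePair(name=f"site{i}", left_site=site, right_site=site,
                      scar_site=site, symmetric=True)
        gpcs.append(GPCUnit(
            index=i,
            recombinase=RecombinaseModule(
                name=f"Rec{i}", ligand=("GIB", "ABA")[(i - 1) % 2],
                site_pair=sp,
                split_halves=(_parts.random_orf(rng, 10),
                              _parts.random_orf(rng, 10)),
            ),
            payloads=(PayloadBlock(kind="protein", name=f"P{i}",
                                   sequence=_parts.random_orf(rng, 8)),),
            terminator=_parts.random_dna(rng, 20),
        ))
    return CircuitDesign(
        name=f"random-{seed}-{n_stages}{version}",
        version=version,
        promoter_name="synthP",
        promoter=_parts.random_dna(rng, 40),
        leader=_parts.kozak_leader() if version == "v2" else "",
        gpcs=tuple(gpcs),
        terminal_payloads=(PayloadBlock(kind="protein", name="Pterm",
                                        sequence=_parts.random_orf(rng, 8)),),
        p2a=_parts.random_orf(rng, 7),
    )
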