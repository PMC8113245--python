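"""Deterministic synthetic DNA parts.

None of the sequences produced here are physiological: the published
constructs' plasmid sequences are not available, so every part is a
placeholder generated from a fixed seed at the canonical length for its
class (34 bp loxP/FRT-like sites, 50/54 bp attB/attP-like sites, short
stand-in coding sequences).  All length-dependent logic elsewhere in the
package is parameterized on the actual part strings, never on these
particular placeholders.
"""

from __future__ import annotations

import numpy as np

NON_PHYSIOLOGICAL_NOTE = (
    "NON_PHYSIOLOGICAL synthetic placeholder sequence (deterministic, seeded)"
)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}

#: Canonical recognition-site lengths (bp) used for placeholder parts.
SITE_LENGTHS = {"loxP": 34, "FRT": 34, "attB": 50, "attP": 54}


def part_rng(seed: int = 20210317) -> np.random.Generator:
    """The fixed-seed generator all bundled placeholder parts derive from."""
    return np.random.default_rng(seed)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def has_stop_in_frame(seq: str) -> bool:
    """True if any complete codon of ``seq`` (frame 0) is a stop codon."""
    return any(seq[i : i + 3] in _STOPS for i in range(0, len(seq) - 2, 3))


def frame_pad(seq: str, pad_base: str = "G") -> str:
    """Bases appended 3' of a scar/site so its total length is a codon multiple."""
    return pad_base * ((3 - len(seq) % 3) % 3)


def random_site(rng: np.random.Generator, n: int) -> str:
    """A synthetic recognition site that stays stop-free once frame-padded.

    Rejection-sampled so that ``site + frame_pad(site)`` read from frame 0
    contains no stop codon; this keeps v2 scar translation open for the
    bundled presets.
    """
    while True:
        s = random_dna(rng, n)
        if not has_stop_in_frame(s + frame_pad(s)):
            return s


def random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """A stop-free open reading frame of ``n_codons`` codons."""
    codons = []
    while len(codons) < n_codons:
        c = random_dna(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def translate(seq: str) -> str:
    """Translate complete codons of ``seq`` (frame 0); '*' marks stops."""
    from Bio.Seq import Seq

    usable = len(seq) - len(seq) % 3
    if usable == 0:
        return ""
    return str(Seq(seq[:usable]).translate())


# --- fixed bundled parts -------------------------------------------------

_KOZAK_LEADER = "GCCACCATG"  # Kozak context + initiation codon (v2 leader)


def kozak_leader() -> str:
    return _KOZAK_LEADER


def standard_parts() -> dict:
    """The bundled placeholder part library (deterministic).

    Returns a dict with site pairs, 2A/terminator/promoter/ITR placeholders
    and short stand-in coding sequences for the named recombinases and
    payloads used by the presets.
    """
    rng = part_rng()
    loxp = random_site(rng, SITE_LENGTHS["loxP"])
    frt = random_site(rng, SITE_LENGTHS["FRT"])

    def att_pair():
        # attL-like scar (half of each parent site), rejection-sampled so
        # the frame-padded hybrid stays stop-free like every other scar
        while True:
            b = random_site(rng, SITE_LENGTHS["attB"])
            p = random_site(rng, SITE_LENGTHS["attP"])
            scar = p[:27] + b[25:]
            if not has_stop_in_frame(scar + frame_pad(scar)):
                return b, p, scar

    attb, attp, att_scar = att_pair()
    w_attb, w_attp, w_scar = att_pair()
    parts = {
        "sites": {
            "loxP": {"left": loxp, "right": loxp, "scar": loxp, "symmetric": True},
            "FRT": {"left": frt, "right": frt, "scar": frt, "symmetric": True},
            "att": {"left": attb, "right": attp, "scar": att_scar, "symmetric": False},
            # separate pair for the whole-circuit self-deletion wrapper
            "att_wrapper": {"left": w_attp, "right": w_attb, "scar": w_scar,
                            "symmetric": False},
        },
        "promoter": random_dna(rng, 120),
        "p2a": random_orf(rng, 20),  # 60 bp self-cleaving 2A stand-in
        "terminator": random_dna(rng, 90),  # 3xBGHpA + 2xcHS4 stand-in
        "itr_left": random_dna(rng, 35),
        "itr_right": random_dna(rng, 35),
        "coding": {},
    }
    for name, n_codons in [
        ("Cre_N", 40), ("Cre_C", 40),
        ("Flp_N", 40), ("Flp_C", 40),
        ("PhiC31_N", 40), ("PhiC31_C", 40),
        ("BFP", 30), ("GFP", 30), ("mCherry", 30), ("iRFP720", 30),
        ("PuroR", 30), ("Zeo", 25), ("Cas9", 60), ("dCas9-VPR", 60),
    ]:
        parts["coding"][name] = random_orf(rng, n_codons)
    for name in ["sgAPC", "sgMLH1", "sgSMAD4", "sgTP53",
                 "sgACT1", "sgACT2", "sgACT3", "sgACT4"]:
        parts["spacers"] = parts.get("spacers", {})
        parts["spacers"][name] = random_dna(rng, 20)
    parts["csy4_core"] = random_dna(rng, 20)
    parts["malat1_th"] = random_dna(rng, 60)
    return parts
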