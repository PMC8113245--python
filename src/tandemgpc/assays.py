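"""In-silico counterparts of the circuit readouts.

Flow-cytometry payload fractions and the %BFP+/(%BFP+ or GFP+) switching
metric; scar-amplicon sequencing with exponential per-cycle PCR length
bias and its correction; sgRNA-driven indel accumulation with the
post-excision lag (the liberated sgRNA keeps cutting until it decays);
and the Cas9/ITR qPCR ratio quantifying circuit self-deletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import CircuitDesign
from .dynamics import Population, KineticParams, _LN2


# --------------------------------------------------------------------------
# flow cytometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GatingConfig:
    """Per-payload positivity thresholds (single-channel idealization)."""

    thresholds: dict = field(default_factory=dict)
    default_threshold: float = 0.1

    def threshold(self, payload: str) -> float:
        th = self.thresholds.get(payload, self.default_threshold)
        if th <= 0:
            raise ValueError("gating thresholds must be > 0")
        return th


@dataclass(frozen=True)
class FlowSummary:
    positive_fractions: dict
    stage_fractions: dict       # exclusive assignment to latest positive payload
    switching_metric: float     # %first+ / (%first+ or %second+)
    switching_payloads: tuple[str, str]


def flow_readout(levels: pd.DataFrame, gating: GatingConfig,
                 switching_pair: tuple[str, str] | None = None
                 ) -> FlowSummary:
    """Gate per-cell payload levels into positive fractions.

    ``levels`` is a cells x payloads frame (see
    :meth:`Population.payload_levels`).  The switching metric is the
    recombination readout ``%A+ / (%A+ or %B+)`` for the first two payload
    columns (or an explicit pair); NaN with a warning when no cell is
    positive for either.
    """
    cols = list(levels.columns)
    pos = {c: levels[c].to_numpy() >= gating.threshold(c) for c in cols}
    n = len(levels)
    positive_fractions = {c: float(pos[c].mean()) if n else 0.0 for c in cols}

    # exclusive assignment: cell belongs to its latest (highest-stage) positive payload
    stage_fractions = {}
    assigned = np.full(n, -1)
    for i, c in enumerate(cols):
        assigned[pos[c]] = i
    for i, c in enumerate(cols):
        stage_fractions[c] = float(np.mean(assigned == i)) if n else 0.0

    if switching_pair is None:
        switching_pair = (cols[0], cols[1]) if len(cols) >= 2 else (cols[0], cols[0])
    a, b = switching_pair
    either = pos[a] | pos[b]
    if either.sum() == 0:
        warnings.warn("no cell positive for either switching payload; "
                      "switching metric undefined", stacklevel=2)
        metric = float("nan")
    else:
        metric = float(pos[a].sum() / either.sum())
    return FlowSummary(positive_fractions=positive_fractions,
                       stage_fractions=stage_fractions,
                       switching_metric=metric,
                       switching_payloads=(a, b))


# --------------------------------------------------------------------------
# editing kinetics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EditingParams:
    """Per-locus editing hazards (per allele per hour of sgRNA exposure)."""

    hazards: dict            # locus -> hazard
    ploidy: int = 2

    def __post_init__(self):
        if any(h < 0 for h in self.hazards.values()):
            raise ValueError("editing hazards must be >= 0")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")


@dataclass(frozen=True)
class EditingResult:
    """Tidy per-locus, per-time allele-level indel frequencies."""

    frequencies: pd.DataFrame  # columns: locus, time_h, indel_fraction

    def at(self, locus: str, time_h: float) -> float:
        df = self.frequencies
        row = df[(df.locus == locus) & (df.time_h == time_h)]
        return float(row.indel_fraction.iloc[0])


def _sgrna_locus_map(design: CircuitDesign) -> dict:
    """stage -> (locus, payload name) for sgRNA payloads named sg<LOCUS>."""
    out = {}
    for k in range(1, design.n_stages + 1):
        for p in design.stage_payloads(k):
            if p.kind == "sgRNA":
                locus = p.name[2:] if p.name.startswith("sg") else p.name
                out[k] = (locus, p.name)
    return out


def sgrna_exposure_integral(population: Population, stage: int,
                            t: float) -> np.ndarray:
    """Per-copy integral of cognate sgRNA abundance up to time ``t``.

    Abundance is 1 while the sgRNA's GPC is proximal and decays
    exponentially (sgRNA half-life) after excision — the source of the
    editing lag seen after each stage transition.
    """
    entry = population.entry_times[:, stage - 1]
    n_stages = population.design.n_stages
    nxt = (population.entry_times[:, stage] if stage < n_stages
           else np.full(population.n_copies, np.inf))
    exit_t = np.minimum(nxt, population.deleted_time)
    delta = _LN2 / population.params.sgRNA_halflife
    I = np.zeros(population.n_copies)
    started = entry <= t
    end_on = np.minimum(exit_t, t)
    I[started] = end_on[started] - entry[started]
    after = started & (exit_t < t)
    I[after] += (1.0 - np.exp(-delta * (t - exit_t[after]))) / delta
    return I


def simulate_editing(population: Population, editing: EditingParams,
                     times, seed: int = 0,
                     design: CircuitDesign | None = None) -> EditingResult:
    """Monte-Carlo allele-level indel accumulation.

    Each allele carries an Exp(1) threshold; it flips once the integrated
    hazard ``h_locus * \\int g(t) dt`` crosses it, which makes every
    allele's path — and hence every per-locus frequency curve —
    non-decreasing in time.  Loci without a cognate sgRNA in the design
    are excluded with a warning.
    """
    design = design or population.design
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    stage_locus = _sgrna_locus_map(design)
    locus_stage = {loc: st for st, (loc, _) in stage_locus.items()}
    rows = []
    for locus, hazard in editing.hazards.items():
        if locus not in locus_stage:
            warnings.warn(f"locus {locus!r} has no cognate sgRNA in the "
                          "design; excluded", stacklevel=2)
            continue
        stage = locus_stage[locus]
        # aggregate exposure per cell (all copies contribute)
        thresholds = rng.exponential(
            1.0, size=(population.n_cells, editing.ploidy))
        for t in times:
            per_copy = sgrna_exposure_integral(population, stage, t)
            per_cell = np.zeros(population.n_cells)
            np.add.at(per_cell, population.cell_of_copy, per_copy)
            H = hazard * per_cell[population.alive]
            edited = thresholds[population.alive] <= H[:, None]
            rows.append((locus, float(t), float(edited.mean())))
    df = pd.DataFrame(rows, columns=["locus", "time_h", "indel_fraction"])
    return EditingResult(frequencies=df)


def expected_indel_frequency(population: Population, locus_stage: int,
                             hazard: float, t: float) -> float:
    """Closed-form allele indel probability, averaged over cells."""
    per_copy = sgrna_exposure_integral(population, locus_stage, t)
    per_cell = np.zeros(population.n_cells)
    np.add.at(per_cell, population.cell_of_copy, per_copy)
    return float(np.mean(1.0 - np.exp(-hazard * per_cell[population.alive])))


# --------------------------------------------------------------------------
# scar-amplicon sequencing with PCR length bias
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BiasModel:
    """Exponential PCR length bias: per-cycle efficiency E(L) falls with L.

    ``E(L) = clip(e_max - k_len * L, 0, 1)``; after ``cycles`` rounds an
    amplicon of length L is weighted by ``(1 + E(L))^cycles``, so shorter
    scar amplicons (earlier stages) are overrepresented.
    """

    e_max: float = 0.9
    k_len: float = 0.0       # per bp
    cycles: int = 25
    read_depth: int = 100_000

    def __post_init__(self):
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.k_len < 0:
            raise ValueError("k_len must be >= 0 (E non-increasing in length)")

    def efficiency(self, length_bp) -> np.ndarray:
        return np.clip(self.e_max - self.k_len * np.asarray(length_bp, float),
                       0.0, 1.0)

    def weight(self, length_bp) -> np.ndarray:
        return (1.0 + self.efficiency(length_bp)) ** self.cycles

    def fold_overrepresentation(self, short_bp: float, long_bp: float) -> float:
        """Expected read-count fold of the short over the long amplicon at
        equimolar input."""
        return float(self.weight(short_bp) / self.weight(long_bp))


@dataclass(frozen=True)
class ScarSeqResult:
    lengths_bp: np.ndarray
    observed_counts: np.ndarray
    estimates: np.ndarray       # bias-corrected molar fraction estimates
    ci_low: np.ndarray
    ci_high: np.ndarray
    stages: tuple | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "length_bp": self.lengths_bp,
            "count": self.observed_counts,
            "estimate": self.estimates,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        })
        if self.stages is not None:
            df.insert(0, "stage", list(self.stages))
        return df


def pcr_observe(molar_fractions, lengths_bp, bias: BiasModel,
                seed: int = 0) -> np.ndarray:
    """Simulate sequencing read counts under PCR length bias.

    Expected weights are ``m_i * (1 + E(L_i))^C`` and counts are a
    multinomial draw of ``bias.read_depth`` reads.
    """
    m = np.asarray(molar_fractions, dtype=float)
    L = np.asarray(lengths_bp, dtype=float)
    if np.any(L <= 0):
        raise ValueError("amplicon lengths must be > 0")
    if abs(m.sum() - 1.0) > 1e-6:
        raise ValueError("molar fractions must sum to 1")
    w = m * bias.weight(L)
    rng = np.random.default_rng(seed)
    return rng.multinomial(bias.read_depth, w / w.sum())


def bias_correct(counts, lengths_bp, bias: BiasModel, n_boot: int = 1000,
                 seed: int = 0, ci_level: float = 0.95):
    """Invert the PCR length bias on observed read counts.

    Estimates ``m_i \\propto count_i / (1 + E(L_i))^C`` (the exact inverse
    of the :func:`pcr_observe` expectation) with a percentile bootstrap CI
    over multinomial resampling of the reads.
    Returns ``(estimates, ci_low, ci_high)``.
    """
    c = np.asarray(counts, dtype=float)
    L = np.asarray(lengths_bp, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("zero total read count")
    w = bias.weight(L)

    def correct(cc):
        est = cc / w
        return est / est.sum()

    est = correct(c)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, c.size))
    p_obs = c / total
    for b in range(n_boot):
        boot[b] = correct(rng.multinomial(int(total), p_obs))
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(boot, [100 * alpha, 100 * (1 - alpha)], axis=0)
    return est, lo, hi


def estimate_stage_fractions(counts, lengths_bp, bias: BiasModel,
                             stages=None, n_boot: int = 1000,
                             seed: int = 0) -> ScarSeqResult:
    """Bias-corrected per-stage molar fractions from scar amplicon counts."""
    counts = np.asarray(counts)
    if stages is None:
        stages = tuple(range(1, counts.size + 1))
    est, lo, hi = bias_correct(counts, lengths_bp, bias, n_boot=n_boot,
                               seed=seed)
    return ScarSeqResult(
        lengths_bp=np.asarray(lengths_bp, dtype=float),
        observed_counts=counts, estimates=est, ci_low=lo, ci_high=hi,
        stages=tuple(stages))


# --------------------------------------------------------------------------
# qPCR circuit-removal assay
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class QPCRResult:
    """Cas9 abundance normalized to the piggyBac ITR (which survives
    self-deletion); 1.0 means no circuit removal, 0.0 complete removal."""

    ratio: float


def qpcr_excision_ratio(population: Population,
                        t: float | None = None) -> QPCRResult:
    """Fraction of circuit copies still carrying the internal cargo.

    ITR flanks persist after att-wrapper self-deletion, so the denominator
    is all copies (in alive cells) and the numerator those not deleted.
    """
    in_alive = population.alive[population.cell_of_copy]
    total = int(in_alive.sum())
    if total == 0:
        raise ValueError("population has no circuit copies in alive cells")
    deleted = (np.isfinite(population.deleted_time) if t is None
               else population.deleted_time <= t)
    retained = int((in_alive & ~deleted).sum())
    return QPCRResult(ratio=retained / total)
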