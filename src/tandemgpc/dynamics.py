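"""Stochastic population dynamics of tandem GPC circuits.

Each circuit copy is a continuous-time pure-birth process over stages
``1..N+1`` (plus an absorbing DELETED state when an att wrapper is
present).  Expression gating means only the promoter-proximal unit can
fire: its hazard is ``excision_hazard * a(t) + leak_hazard * (1 - a(t))``
where ``a(t)`` is the cognate ligand's intracellular activity under the
exposure schedule and pharmacokinetic clearance model.  Ligand windows and
first-order washout make the hazard piecewise constant / piecewise
exponential, so simulation is event-driven: exact exponential waiting
times inside constant segments and thinning inside decay segments — no
fixed time step and no discretization error.

:func:`expected_occupancy` is the analytic twin: it propagates the
single-copy stage distribution through the same piecewise-constant-rate
Markov chain with matrix exponentials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .circuit import CircuitDesign, LIGANDS
from .compiler import DELETED

#: intracellular activity below this is treated as zero (washout complete)
ACTIVITY_FLOOR = 0.01

_LN2 = float(np.log(2.0))


# --------------------------------------------------------------------------
# schedules and pharmacokinetics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LigandSchedule:
    """Piecewise ligand exposure program: (ligand, start_h, end_h) windows."""

    windows: tuple[tuple[str, float, float], ...]
    horizon: float

    def __post_init__(self):
        object.__setattr__(self, "windows", tuple(
            (str(l), float(a), float(b)) for l, a, b in self.windows))
        for lig, a, b in self.windows:
            if lig not in LIGANDS:
                raise ValueError(f"unknown ligand {lig!r}")
            if b <= a:
                raise ValueError(f"window end {b} <= start {a}")
        for lig in LIGANDS:
            w = sorted((a, b) for l, a, b in self.windows if l == lig)
            for (a1, b1), (a2, b2) in zip(w, w[1:]):
                if a2 < b1:
                    raise ValueError(f"overlapping {lig} windows")

    @classmethod
    def alternating(cls, ligand_order, stage_hours: float = 48.0,
                    gap_hours: float = 12.0, extra_hours: float = 0.0,
                    lead_hours: float = 0.0) -> "LigandSchedule":
        """Default builder: ``stage_hours`` per stage with ``gap_hours`` gaps.

        ``lead_hours`` inserts a ligand-free dwell before the first window
        (cells express the stage-1 payload from integration, not from the
        first treatment); ``extra_hours`` extends the horizon past the last
        window.
        """
        windows, t = [], float(lead_hours)
        for i, lig in enumerate(ligand_order):
            windows.append((lig, t, t + stage_hours))
            t += stage_hours
            if i < len(ligand_order) - 1:
                t += gap_hours
        return cls(tuple(windows), horizon=t + extra_hours)

    @classmethod
    def empty(cls, horizon: float) -> "LigandSchedule":
        return cls((), horizon=float(horizon))


@dataclass(frozen=True)
class PKLigand:
    """Clearance model of one ligand after washout."""

    clearance_mode: str = "instant"  # "instant" | "first_order"
    clearance_halflife: float = 0.0  # h, for first_order
    trapped: bool = False            # AM-ester intracellular trapping

    def __post_init__(self):
        if self.clearance_mode not in ("instant", "first_order"):
            raise ValueError(f"unknown clearance mode {self.clearance_mode!r}")
        if self.clearance_mode == "first_order" and self.clearance_halflife <= 0:
            raise ValueError("first_order clearance requires a positive half-life")


@dataclass(frozen=True)
class PKParams:
    """Per-ligand pharmacokinetics.

    Presets: GA4 and ABA are effectively cleared immediately on washout
    (well within the 12-h schedule gap); GA3-AM is trapped intracellularly
    by esterase de-esterification and needs >12 h to clear.
    """

    GIB: PKLigand = field(default_factory=PKLigand)
    ABA: PKLigand = field(default_factory=PKLigand)

    def for_ligand(self, ligand: str) -> PKLigand:
        if ligand not in LIGANDS:
            raise ValueError(f"unknown ligand {ligand!r}")
        return getattr(self, ligand)


@dataclass(frozen=True)
class KineticParams:
    """First-order hazards and half-lives of the lumped circuit kinetics.

    ``excision_hazard`` applies to the proximal unit while its cognate
    ligand is active; ``leak_hazard`` is spontaneous split-recombinase
    reconstitution without ligand; ``self_deletion_hazard`` drives the
    att-wrapper excision at the PhiC31 stage.  All per hour.
    """

    excision_hazard: float = 0.2
    leak_hazard: float = 5e-4
    payload_protein_halflife: float = 2.0
    sgRNA_halflife: float = 12.0
    self_deletion_hazard: float = 0.0

    def __post_init__(self):
        for name in ("excision_hazard", "leak_hazard", "self_deletion_hazard"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CopyNumberModel:
    """Distribution of circuit copies per cell (support >= 1)."""

    pmf: tuple[tuple[int, float], ...] = ((1, 1.0),)

    def __post_init__(self):
        ks = [k for k, _ in self.pmf]
        ps = [p for _, p in self.pmf]
        if min(ks) < 1:
            raise ValueError("copy-number support must be >= 1")
        if abs(sum(ps) - 1.0) > 1e-9:
            raise ValueError("copy-number probabilities must sum to 1")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        ks = np.array([k for k, _ in self.pmf])
        ps = np.array([p for _, p in self.pmf])
        return rng.choice(ks, size=n, p=ps)


# --------------------------------------------------------------------------
# ligand activity
# --------------------------------------------------------------------------

def ligand_activity(schedule: LigandSchedule, pk: PKParams, ligand: str,
                    t: float) -> float:
    """Intracellular activity of ``ligand`` at time ``t`` (0..1).

    1 inside an exposure window; after the window it is 0 under instant
    clearance or ``exp(-ln2 * dt / halflife)`` under first-order clearance,
    floored to 0 below :data:`ACTIVITY_FLOOR`.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    lp = pk.for_ligand(ligand)
    last_end = None
    for lig, a, b in schedule.windows:
        if lig != ligand:
            continue
        if a <= t < b:
            return 1.0
        if b <= t and (last_end is None or b > last_end):
            last_end = b
    if last_end is None:
        return 0.0
    if lp.clearance_mode == "instant":
        return 0.0
    a = float(np.exp(-_LN2 * (t - last_end) / lp.clearance_halflife))
    return a if a >= ACTIVITY_FLOOR else 0.0


def _activity_breakpoints(schedule: LigandSchedule, pk: PKParams,
                          horizon: float) -> np.ndarray:
    """Times where any ligand's activity changes functional form."""
    pts = {0.0, float(horizon)}
    for lig, a, b in schedule.windows:
        pts.add(a)
        pts.add(b)
        lp = pk.for_ligand(lig)
        if lp.clearance_mode == "first_order":
            cutoff = b + lp.clearance_halflife * np.log2(1.0 / ACTIVITY_FLOOR)
            pts.add(float(cutoff))
    out = np.array(sorted(p for p in pts if 0.0 <= p <= horizon))
    return out


def _segment_activity(schedule, pk, ligand, t0, t1):
    """Activity form of one ligand on [t0, t1): ('const', a) or ('decay', a0, r)."""
    a0 = ligand_activity(schedule, pk, ligand, t0)
    mid = ligand_activity(schedule, pk, ligand, 0.5 * (t0 + t1))
    lp = pk.for_ligand(ligand)
    if a0 in (0.0, 1.0) and mid == a0:
        return ("const", a0, 0.0)
    if lp.clearance_mode == "first_order" and (
            0.0 < a0 < 1.0 or (a0 == 1.0 and mid < 1.0)):
        if a0 <= ACTIVITY_FLOOR * (1 + 1e-9):
            # past the washout cutoff: treated as zero
            return ("const", 0.0, 0.0)
        # decaying tail: a(t) = a0 * exp(-r (t - t0))
        r = _LN2 / lp.clearance_halflife
        return ("decay", a0, r)
    return ("const", a0, 0.0)


# --------------------------------------------------------------------------
# hazards
# --------------------------------------------------------------------------

def _stage_ligand(design: CircuitDesign, stage: int) -> str | None:
    if 1 <= stage <= design.n_gpcs:
        return design.gpcs[stage - 1].recombinase.ligand
    return None


def _is_selfdel_stage(design: CircuitDesign, stage: int) -> bool:
    return (design.att_wrapper is not None
            and 1 <= stage <= design.n_gpcs
            and design.gpcs[stage - 1].recombinase.name == "PhiC31")


def transition_hazard(copy_stage, design: CircuitDesign, activities: dict,
                      params: KineticParams):
    """Hazard (per hour) and target state of the proximal unit.

    Only the promoter-proximal GPC contributes (expression gating);
    terminal-stage and DELETED copies have hazard 0.  At the PhiC31 stage
    of an att-wrapped design the event is self-deletion of the whole
    circuit rather than single-unit excision.
    Returns ``(hazard, target)`` with target the next stage or DELETED.
    """
    if copy_stage == DELETED or copy_stage > design.n_gpcs:
        return 0.0, None
    lig = _stage_ligand(design, copy_stage)
    a = float(activities[lig])
    if _is_selfdel_stage(design, copy_stage):
        return (params.self_deletion_hazard * a
                + params.leak_hazard * (1.0 - a)), DELETED
    return (params.excision_hazard * a
            + params.leak_hazard * (1.0 - a)), copy_stage + 1


def _hazard_coeffs(design, params, stage):
    """(base, slope, deletes): hazard = base + slope * a(cognate ligand)."""
    if _is_selfdel_stage(design, stage):
        return (params.leak_hazard,
                params.self_deletion_hazard - params.leak_hazard, True)
    return (params.leak_hazard,
            params.excision_hazard - params.leak_hazard, False)


# --------------------------------------------------------------------------
# population containers
# --------------------------------------------------------------------------

@dataclass
class Population:
    """Per-copy stage histories for a simulated cell population.

    ``entry_times[c, j]`` is the time copy ``c`` entered stage ``j + 1``
    (0 for stages occupied at t=0, +inf if never reached); monotonicity of
    each row is the no-reversal invariant.  ``deleted_time`` is +inf for
    copies never self-deleted.
    """

    design: CircuitDesign
    params: KineticParams
    cell_of_copy: np.ndarray   # (n_copies,) int
    entry_times: np.ndarray    # (n_copies, n_stages) float
    deleted_time: np.ndarray   # (n_copies,) float
    alive: np.ndarray          # (n_cells,) bool
    seed: int | None = None

    @property
    def n_cells(self) -> int:
        return self.alive.size

    @property
    def n_copies(self) -> int:
        return self.cell_of_copy.size

    def copy_stage_at(self, t: float) -> np.ndarray:
        """Per-copy stage index at time ``t`` (-1 encodes DELETED)."""
        stage = (self.entry_times <= t).sum(axis=1)
        stage = np.where(self.deleted_time <= t, -1, stage)
        return stage

    def cell_stage_at(self, t: float) -> np.ndarray:
        """Per-cell stage: furthest non-deleted copy; -1 if all deleted."""
        cs = self.copy_stage_at(t)
        out = np.full(self.n_cells, -1, dtype=int)
        live = cs > 0
        np.maximum.at(out, self.cell_of_copy[live], cs[live])
        return out

    def occupancy_at(self, t: float) -> np.ndarray:
        """Fractions of alive cells per stage (last entry = DELETED)."""
        cs = self.cell_stage_at(t)[self.alive]
        n_stages = self.design.n_stages
        counts = np.zeros(n_stages + 1)
        for k in range(1, n_stages + 1):
            counts[k - 1] = np.sum(cs == k)
        counts[-1] = np.sum(cs == -1)
        return counts / max(len(cs), 1)

    def payload_levels(self, t: float, noise_cv: float = 0.0,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
        """Per-cell payload protein/sgRNA levels at time ``t``.

        Levels follow production-while-proximal with first-order decay
        (PEST-tagged proteins / sgRNA half-life), normalized to a
        steady-state of 1.  Optional log-normal cell-to-cell noise of the
        given CV is applied multiplicatively.
        """
        d = self.design
        levels = {}
        for k in range(1, d.n_stages + 1):
            entry = self.entry_times[:, k - 1]
            nxt = (self.entry_times[:, k] if k < d.n_stages
                   else np.full(self.n_copies, np.inf))
            exit_t = np.minimum(nxt, self.deleted_time)
            for p in d.stage_payloads(k):
                hl = (self.params.sgRNA_halflife if p.kind == "sgRNA"
                      else self.params.payload_protein_halflife)
                delta = _LN2 / hl
                lv = np.zeros(self.n_copies)
                during = (entry <= t) & (t < exit_t)
                lv[during] = 1.0 - np.exp(-delta * (t - entry[during]))
                # copies deleted before ever reaching this stage never express
                after = (exit_t <= t) & (entry <= exit_t)
                peak = 1.0 - np.exp(-delta * (exit_t[after] - entry[after]))
                lv[after] = peak * np.exp(-delta * (t - exit_t[after]))
                cell_lv = np.zeros(self.n_cells)
                np.add.at(cell_lv, self.cell_of_copy, lv)
                levels[p.name] = levels.get(p.name, 0.0) + cell_lv
        df = pd.DataFrame(levels)
        if noise_cv > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            sigma = np.sqrt(np.log1p(noise_cv ** 2))
            noise = np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=df.shape))
            df = df * noise
        return df


@dataclass(frozen=True)
class Trajectory:
    """Aggregated occupancy and mean payload levels over sample times."""

    times: np.ndarray
    occupancy: pd.DataFrame      # columns stage_1..stage_K, deleted
    payload_means: pd.DataFrame  # mean level per payload
    seed: int | None
    n_cells: int
    population: Population

    def to_frame(self) -> pd.DataFrame:
        df = pd.concat(
            [pd.Series(self.times, name="time_h"),
             self.occupancy.reset_index(drop=True),
             self.payload_means.add_suffix("_mean").reset_index(drop=True)],
            axis=1)
        return df


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def simulate_population(design: CircuitDesign, params: KineticParams,
                        pk: PKParams, copy_model: CopyNumberModel,
                        schedule: LigandSchedule, n: int, seed: int,
                        sample_times=None, init_stage: int = 1) -> Trajectory:
    """Simulate ``n`` cells through the ligand schedule.

    Event-driven and exact: inside segments where every ligand activity is
    constant, waiting times are sampled by exponential inversion; inside
    first-order washout tails, by thinning against the segment's hazard
    envelope.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    horizon = schedule.horizon
    if sample_times is None:
        sample_times = np.arange(0.0, horizon + 1e-9, 1.0)
    sample_times = np.asarray(sample_times, dtype=float)

    rng = np.random.default_rng(seed)
    copies_per_cell = copy_model.sample(rng, n)
    cell_of_copy = np.repeat(np.arange(n), copies_per_cell)
    n_copies = cell_of_copy.size
    n_stages = design.n_stages
    N = design.n_gpcs

    entry_times = np.full((n_copies, n_stages), np.inf)
    entry_times[:, :init_stage] = 0.0
    deleted_time = np.full(n_copies, np.inf)
    stage = np.full(n_copies, init_stage, dtype=int)

    base = np.zeros(N + 2)
    slope = np.zeros(N + 2)
    deletes = np.zeros(N + 2, dtype=bool)
    lig_idx = np.zeros(N + 2, dtype=int)  # 0 = GIB, 1 = ABA
    for k in range(1, N + 1):
        base[k], slope[k], deletes[k] = _hazard_coeffs(design, params, k)
        lig_idx[k] = LIGANDS.index(_stage_ligand(design, k))

    bps = _activity_breakpoints(schedule, pk, horizon)
    t_cur = np.zeros(n_copies)
    for t0, t1 in zip(bps[:-1], bps[1:]):
        forms = [_segment_activity(schedule, pk, lig, t0, t1)
                 for lig in LIGANDS]
        while True:
            act = ((stage >= 1) & (stage <= N)
                   & (deleted_time == np.inf) & (t_cur < t1))
            idx = np.flatnonzero(act)
            if idx.size == 0:
                break
            st = stage[idx]
            li = lig_idx[st]
            b, sl = base[st], slope[st]
            kinds = np.array([f[0] for f in forms])
            a0s = np.array([f[1] for f in forms])
            rates = np.array([f[2] for f in forms])
            is_decay = kinds[li] == "decay"
            a_now = np.where(
                is_decay,
                a0s[li] * np.exp(-rates[li] * (t_cur[idx] - t0)),
                a0s[li])
            a_end = np.where(
                is_decay, a0s[li] * np.exp(-rates[li] * (t1 - t0)), a0s[li])
            lam_now = b + sl * a_now
            lam_end = b + sl * a_end
            lam_ub = np.maximum(lam_now, lam_end)
            with np.errstate(divide="ignore"):
                wait = rng.exponential(1.0, size=idx.size) / lam_ub
            t_prop = t_cur[idx] + wait
            beyond = t_prop >= t1
            t_cur[idx] = np.where(beyond, t1, t_prop)
            cand = ~beyond
            if is_decay.any():
                a_prop = np.where(
                    is_decay,
                    a0s[li] * np.exp(-rates[li] * (t_prop - t0)),
                    a0s[li])
                lam_prop = b + sl * a_prop
                accept = rng.random(idx.size) * lam_ub <= lam_prop
                cand &= accept
            fire = idx[cand]
            if fire.size:
                tf = t_prop[cand]
                del_mask = deletes[stage[fire]]
                deleted_time[fire[del_mask]] = tf[del_mask]
                adv = fire[~del_mask]
                stage[adv] += 1
                entry_times[adv, stage[adv] - 1] = tf[~del_mask]
        t_cur[:] = t1

    pop = Population(design=design, params=params,
                     cell_of_copy=cell_of_copy, entry_times=entry_times,
                     deleted_time=deleted_time,
                     alive=np.ones(n, dtype=bool), seed=seed)

    occ = np.stack([pop.occupancy_at(t) for t in sample_times])
    occ_df = pd.DataFrame(
        occ, columns=[f"stage_{k}" for k in range(1, n_stages + 1)]
        + ["deleted"])
    payload_names = []
    for k in range(1, n_stages + 1):
        for p in design.stage_payloads(k):
            if p.name not in payload_names:
                payload_names.append(p.name)
    means = []
    for t in sample_times:
        lv = pop.payload_levels(t)
        means.append([lv[nm].mean() if nm in lv else 0.0
                      for nm in payload_names])
    means_df = pd.DataFrame(means, columns=payload_names)
    return Trajectory(times=sample_times, occupancy=occ_df,
                      payload_means=means_df, seed=seed, n_cells=n,
                      population=pop)


# --------------------------------------------------------------------------
# analytic twin
# --------------------------------------------------------------------------

def expected_occupancy(design: CircuitDesign, params: KineticParams,
                       pk: PKParams, schedule: LigandSchedule,
                       times, init_stage: int = 1) -> np.ndarray:
    """Single-copy stage-probability matrix from the piecewise Markov chain.

    States are stages ``1..N+1`` plus DELETED (last column).  Within
    segments of constant ligand activity the pure-birth chain is propagated
    with a matrix exponential; first-order washout tails are integrated
    with a stiff ODE step.  Rows sum to 1.
    """
    from scipy.linalg import expm
    from scipy.integrate import solve_ivp

    times = np.asarray(times, dtype=float)
    horizon = max(schedule.horizon, times.max() if times.size else 0.0)
    N = design.n_gpcs
    M = design.n_stages + 1  # + DELETED column

    def generator(acts):
        Q = np.zeros((M, M))
        for k in range(1, N + 1):
            b, sl, dele = _hazard_coeffs(design, params, k)
            lam = b + sl * acts[_stage_ligand(design, k)]
            tgt = M - 1 if dele else k  # 0-based target column
            Q[k - 1, k - 1] -= lam
            Q[k - 1, tgt] += lam
        return Q

    bps = list(_activity_breakpoints(schedule, pk, horizon))
    if bps[-1] < horizon:
        bps.append(horizon)
    p = np.zeros(M)
    p[init_stage - 1] = 1.0
    out = np.zeros((times.size, M))
    done = np.zeros(times.size, dtype=bool)
    if np.any(times == 0.0):
        out[times == 0.0] = p
        done[times == 0.0] = True

    for t0, t1 in zip(bps[:-1], bps[1:]):
        forms = {lig: _segment_activity(schedule, pk, lig, t0, t1)
                 for lig in LIGANDS}
        is_const = all(f[0] == "const" for f in forms.values())
        sel = np.flatnonzero(~done & (times > t0) & (times <= t1))

        if is_const:
            acts = {lig: forms[lig][1] for lig in LIGANDS}
            Q = generator(acts)
            for i in sel:
                out[i] = p @ expm(Q * (times[i] - t0))
            p = p @ expm(Q * (t1 - t0))
        else:
            def acts_at(t):
                return {
                    lig: (f[1] if f[0] == "const"
                          else f[1] * np.exp(-f[2] * (t - t0)))
                    for lig, f in forms.items()}

            def rhs(t, y):
                return y @ generator(acts_at(t))

            t_eval = sorted(set(times[sel].tolist() + [t1]))
            sol = solve_ivp(rhs, (t0, t1), p, t_eval=t_eval,
                            rtol=1e-10, atol=1e-12, method="LSODA")
            for i in sel:
                j = t_eval.index(times[i])
                out[i] = sol.y[:, j]
            p = sol.y[:, -1]
        done[sel] = True
    out[~done] = p  # times beyond horizon: frozen (no further windows)
    return out


# --------------------------------------------------------------------------
# selection, self-deletion, hazard fitting
# --------------------------------------------------------------------------

def apply_selection(population: Population, marker_stage: int,
                    survival_with: float, survival_without: float,
                    t: float, seed: int = 0) -> Population:
    """Antibiotic synchronization: survival depends on the marker stage.

    A cell survives with probability ``survival_with`` if *any* of its
    copies is at ``marker_stage`` at time ``t`` (one resistant copy is
    enough), else ``survival_without``.  Returns a population with updated
    ``alive`` flags; already-dead cells stay dead.
    """
    if not (0 <= survival_with <= 1 and 0 <= survival_without <= 1):
        raise ValueError("survival probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cs = population.copy_stage_at(t)
    has_marker = np.zeros(population.n_cells, dtype=bool)
    np.logical_or.at(has_marker, population.cell_of_copy, cs == marker_stage)
    p_surv = np.where(has_marker, survival_with, survival_without)
    alive = population.alive & (rng.random(population.n_cells) < p_surv)
    return replace(population, alive=alive)


def integrated_activity(schedule: LigandSchedule, pk: PKParams, ligand: str,
                        t_start: float, t_end: float, n_grid: int = 4097
                        ) -> float:
    """Integral of ligand activity over [t_start, t_end] (trapezoid on the
    piecewise form; exact up to quadrature of the smooth washout tails)."""
    ts = np.linspace(t_start, t_end, n_grid)
    a = np.array([ligand_activity(schedule, pk, ligand, t) for t in ts])
    return float(np.trapezoid(a, ts))


def self_delete(population: Population, params: KineticParams,
                pk: PKParams, schedule: LigandSchedule, seed: int,
                t_start: float = 0.0) -> Population:
    """Apply att-wrapper self-deletion to copies at the PhiC31 stage.

    Each eligible copy deletes with hazard ``self_deletion_hazard`` times
    the GIB activity over the given schedule; deleted copies express
    nothing thereafter.
    """
    design = population.design
    if design.att_wrapper is None:
        raise ValueError("design has no att wrapper")
    phi_stages = [g.index for g in design.gpcs
                  if g.recombinase.name == "PhiC31"]
    if not phi_stages:
        raise ValueError("design has no PhiC31 stage")
    rng = np.random.default_rng(seed)
    H = params.self_deletion_hazard * integrated_activity(
        schedule, pk, "GIB", t_start, schedule.horizon)
    cs = population.copy_stage_at(t_start)
    eligible = np.isin(cs, phi_stages) & (population.deleted_time == np.inf)
    p_del = 1.0 - np.exp(-H)
    hit = eligible & (rng.random(population.n_copies) < p_del)
    deleted_time = population.deleted_time.copy()
    # inversion of the (time-rescaled) exponential within the window
    u = rng.random(hit.sum())
    frac = -np.log1p(-u * p_del) / max(H, 1e-300)
    deleted_time[hit] = t_start + frac * (schedule.horizon - t_start)
    return replace(population, deleted_time=deleted_time)


def fit_hazard_from_timecourse(times, fractions, model: str = "leak",
                               n_boot: int = 1000, seed: int = 0):
    """Maximum-likelihood exponential rate from a stage-fraction time course.

    ``model="leak"`` fits the fraction *remaining* at a stage,
    ``f(t) = exp(-q t)``; ``model="excision"`` fits the accumulated
    fraction ``f(t) = 1 - exp(-q t)``.  Returns ``(q_hat, (lo, hi))`` with
    a percentile bootstrap CI over resampled time points.
    """
    from scipy.optimize import curve_fit

    times = np.asarray(times, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 time points")
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("fractions must be in [0, 1]")
    if model not in ("leak", "excision"):
        raise ValueError("model must be 'leak' or 'excision'")

    sign = -1.0 if model == "leak" else 1.0
    order = np.argsort(times)
    monotone_viol = (np.diff(fractions[order]) * sign < -1e-9).any()
    if monotone_viol:
        warnings.warn(
            f"time course is not monotone for the {model} model; "
            "returning the best fit anyway", stacklevel=2)

    if model == "leak":
        def f(t, q):
            return np.exp(-q * t)
    else:
        def f(t, q):
            return 1.0 - np.exp(-q * t)

    def fit(ts, fs):
        pos = ts > 0
        inner = np.clip(fs[pos] if model == "leak" else 1 - fs[pos],
                        1e-12, 1.0)
        q0 = float(np.mean(-np.log(inner) / ts[pos])) if pos.any() else 0.0
        popt, _ = curve_fit(f, ts, fs, p0=[max(q0, 1e-12)],
                            bounds=(0.0, np.inf), maxfev=10000)
        return float(popt[0])

    q_hat = fit(times, fractions)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        i = rng.integers(0, times.size, size=times.size)
        if np.unique(times[i]).size < 2:
            continue
        try:
            boots.append(fit(times[i], fractions[i]))
        except Exception:
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = q_hat
    return q_hat, (float(lo), float(hi))
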