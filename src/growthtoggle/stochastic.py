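"""Exact stochastic lineage simulation of the toggle switch.

A single daughter cell is followed through growing volume, scheduled
replication of each gene locus (which releases any promoter-bound repressor
and renders the new copies active), division with binomial partitioning of
free molecules, and the ten reaction channel types of the toggle (gene
activation/repression, transcription, mRNA decay, translation,
dimerization, dimer dissociation — protein monomers are lost only by
dilution).  The heavy loop lives in a numba kernel (:mod:`._ssa`); this
module provides the user-facing state/trajectory types, pure-Python
reference implementations of the propensity vector and of the replication
and division updates, and ensemble drivers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from . import _ssa
from .cell_cycle import (
    CellCycleParams,
    LocusSpec,
    VolumeModel,
    copies_at_birth,
    replication_age,
    volume_at_age,
)
from .model_params import EffectiveRates, RateConstants, effective_rates
from .deterministic import (
    DEFAULT_ORI_LOCUS,
    DEFAULT_TER_LOCUS,
    dominant_initial_state,
    relax_to_steady_state,
)

__all__ = [
    "CHANNELS",
    "StochasticCellState",
    "SimulationConfig",
    "Trajectory",
    "EnsembleSummary",
    "propensities",
    "replicate_locus",
    "partition_at_division",
    "advance",
    "initial_state",
    "simulate_lineage",
    "first_passage_time",
    "run_ensemble",
    "simulate_frozen",
]

#: Reaction channel order used by :func:`propensities` and the kernel.
CHANNELS = (
    "activate_ori", "repress_ori", "activate_ter", "repress_ter",
    "transcribe_ori", "transcribe_ter", "mrna_decay_ori", "mrna_decay_ter",
    "translate_ori", "translate_ter", "dimerize_ori", "dimerize_ter",
    "dissociate_ori", "dissociate_ter",
)


@dataclass
class StochasticCellState:
    """Discrete cell state with per-copy gene activities.

    ``gene_states_*`` hold one entry per gene copy (1 active, 0 repressed; a
    repressed copy implicitly carries one bound repressor dimer of the
    opposing gene).  ``D_*`` count free dimers only.  ``age`` and ``time``
    are in minutes, the volume is the scaled cell volume.
    """

    gene_states_ori: np.ndarray
    gene_states_ter: np.ndarray
    M_ori: int = 0
    M_ter: int = 0
    P_ori: int = 0
    P_ter: int = 0
    D_ori: int = 0
    D_ter: int = 0
    age: float = 0.0
    time: float = 0.0
    volume: float = 1.0

    def __post_init__(self) -> None:
        self.gene_states_ori = np.asarray(self.gene_states_ori, dtype=np.int8)
        self.gene_states_ter = np.asarray(self.gene_states_ter, dtype=np.int8)
        for arr in (self.gene_states_ori, self.gene_states_ter):
            if arr.size and not np.isin(arr, (0, 1)).all():
                raise ValueError("gene copy states must be 0 (repressed) or 1 (active)")
        for name in ("M_ori", "M_ter", "P_ori", "P_ter", "D_ori", "D_ter"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative molecule count {name}")

    @property
    def n_ori(self) -> int:
        return int(self.gene_states_ori.size)

    @property
    def n_ter(self) -> int:
        return int(self.gene_states_ter.size)

    @property
    def active_ori(self) -> int:
        return int(self.gene_states_ori.sum())

    @property
    def active_ter(self) -> int:
        return int(self.gene_states_ter.sum())

    def to_counts(self) -> np.ndarray:
        """Kernel count vector [n_o, a_o, n_t, a_t, M_o, M_t, P_o, P_t, D_o, D_t]."""
        return np.array(
            [self.n_ori, self.active_ori, self.n_ter, self.active_ter,
             self.M_ori, self.M_ter, self.P_ori, self.P_ter,
             self.D_ori, self.D_ter], dtype=np.int64)

    @classmethod
    def from_counts(cls, counts: np.ndarray, age: float = 0.0,
                    time: float = 0.0, volume: float = 1.0) -> "StochasticCellState":
        n_o, a_o, n_t, a_t, m_o, m_t, p_o, p_t, d_o, d_t = (int(v) for v in counts)
        gs_o = np.zeros(n_o, np.int8)
        gs_o[:a_o] = 1
        gs_t = np.zeros(n_t, np.int8)
        gs_t[:a_t] = 1
        return cls(gs_o, gs_t, m_o, m_t, p_o, p_t, d_o, d_t, age, time, volume)


def propensities(s: StochasticCellState, er: EffectiveRates) -> np.ndarray:
    """Per-second rates of the 14 reaction channels (order in CHANNELS).

    Activation releases the bound dimer back to the free pool, repression
    removes a free dimer of the opposing gene; dimerization uses the
    ``k_d p (p - 1)`` combinatorial form, so a single monomer cannot
    dimerize; there is no protein degradation channel.
    """
    n_o, a_o = s.n_ori, s.active_ori
    n_t, a_t = s.n_ter, s.active_ter
    return np.array([
        er.k_g * (n_o - a_o),
        er.r_g * s.D_ter * a_o,
        er.k_g * (n_t - a_t),
        er.r_g * s.D_ori * a_t,
        er.k_m * a_o,
        er.k_m * a_t,
        er.r_m * s.M_ori,
        er.r_m * s.M_ter,
        er.k_p * s.M_ori,
        er.k_p * s.M_ter,
        er.k_d * s.P_ori * (s.P_ori - 1),
        er.k_d * s.P_ter * (s.P_ter - 1),
        er.r_d * s.D_ori,
        er.r_d * s.D_ter,
    ])


def replicate_locus(s: StochasticCellState, which: str) -> StochasticCellState:
    """Replicate every copy of one locus: counts double, all copies active.

    Replication forks strip DNA-bound proteins, so each bound repressor
    dimer returns to the free pool of the opposing gene's dimers.
    """
    s = _copy_state(s)
    if which == "ori":
        released = s.n_ori - s.active_ori
        s.D_ter += released
        s.gene_states_ori = np.ones(2 * s.n_ori, np.int8)
    elif which == "ter":
        released = s.n_ter - s.active_ter
        s.D_ori += released
        s.gene_states_ter = np.ones(2 * s.n_ter, np.int8)
    else:
        raise ValueError("which must be 'ori' or 'ter'")
    return s


def partition_at_division(s: StochasticCellState, rng: np.random.Generator,
                          replicate_at_division: tuple[bool, bool] = (False, False),
                          ) -> StochasticCellState:
    """Divide the cell and return the followed daughter.

    Free molecules are split binomially with p = 1/2; of each replicated
    pair of gene copies the daughter keeps one, chosen uniformly at random,
    together with its activity state (a discarded repressed copy takes its
    bound dimer out of the lineage).  Loci whose replication coincides with
    division (``replicate_at_division``) are replicated first — releasing
    bound repressors — and keep a constant copy count.
    """
    s = _copy_state(s)
    # a locus replicating exactly at division: bound repressors released,
    # copies double and one of each pair is kept, so the count is unchanged
    # and every kept copy is active
    if replicate_at_division[0]:
        s.D_ter += s.n_ori - s.active_ori
        s.gene_states_ori = np.ones(s.n_ori, np.int8)
    if replicate_at_division[1]:
        s.D_ori += s.n_ter - s.active_ter
        s.gene_states_ter = np.ones(s.n_ter, np.int8)
    # otherwise: one copy of each replicated pair, uniformly at random
    for attr, flag in (("gene_states_ori", replicate_at_division[0]),
                       ("gene_states_ter", replicate_at_division[1])):
        if flag:
            continue
        states = getattr(s, attr)
        if states.size % 2:
            raise ValueError("odd copy count at division: locus not yet replicated")
        pick = rng.integers(0, 2, size=states.size // 2)
        kept = states.reshape(-1, 2)[np.arange(states.size // 2), pick]
        setattr(s, attr, kept.astype(np.int8))
    for name in ("M_ori", "M_ter", "P_ori", "P_ter", "D_ori", "D_ter"):
        setattr(s, name, int(rng.binomial(getattr(s, name), 0.5)))
    s.age = 0.0
    return s


def _copy_state(s: StochasticCellState) -> StochasticCellState:
    return StochasticCellState(
        s.gene_states_ori.copy(), s.gene_states_ter.copy(),
        s.M_ori, s.M_ter, s.P_ori, s.P_ter, s.D_ori, s.D_ter,
        s.age, s.time, s.volume)


_UPDATES = {
    "activate_ori": (("D_ter", +1),),
    "repress_ori": (("D_ter", -1),),
    "activate_ter": (("D_ori", +1),),
    "repress_ter": (("D_ori", -1),),
    "transcribe_ori": (("M_ori", +1),),
    "transcribe_ter": (("M_ter", +1),),
    "mrna_decay_ori": (("M_ori", -1),),
    "mrna_decay_ter": (("M_ter", -1),),
    "translate_ori": (("P_ori", +1),),
    "translate_ter": (("P_ter", +1),),
    "dimerize_ori": (("P_ori", -2), ("D_ori", +1)),
    "dimerize_ter": (("P_ter", -2), ("D_ter", +1)),
    "dissociate_ori": (("D_ori", -1), ("P_ori", +2)),
    "dissociate_ter": (("D_ter", -1), ("P_ter", +2)),
}


def advance(s: StochasticCellState, rc: RateConstants, cc: CellCycleParams,
            rng: np.random.Generator,
            ori: LocusSpec = DEFAULT_ORI_LOCUS,
            ter: LocusSpec = DEFAULT_TER_LOCUS) -> tuple[StochasticCellState, str]:
    """Apply the next event (reaction, replication or division); reference path.

    Draws the waiting time from the propensities at the current volume; if
    the drawn reaction would occur after the next scheduled event (locus
    replication at its fixed cell age, or division at age T) the scheduled
    event executes instead and the clock is resampled afterwards.  Returns
    the new state and an event label.  This pure-Python implementation
    mirrors the numba kernel one event at a time and is used for
    semantic tests; long simulations should use :func:`simulate_lineage`.
    """
    if rng is None:
        raise ValueError("an explicitly seeded numpy Generator is required")
    er = effective_rates(rc, cc, s.age)
    props = propensities(s, er)
    total = props.sum()
    tau_min = math.inf if total <= 0 else rng.exponential(1.0 / total) / 60.0

    rep_o = replication_age(ori, cc)
    rep_t = replication_age(ter, cc)
    sched_age = cc.T
    for rep in (rep_o, rep_t):
        if rep < cc.T and s.age < rep:
            sched_age = min(sched_age, rep)
    dt_sched = sched_age - s.age

    if tau_min < dt_sched:
        new = _copy_state(s)
        new.age += tau_min
        new.time += tau_min
        new.volume = volume_at_age(VolumeModel(cc), new.age)
        ch = CHANNELS[rng.choice(len(CHANNELS), p=props / total)]
        if ch == "activate_ori":
            idx = np.flatnonzero(new.gene_states_ori == 0)
            new.gene_states_ori[rng.choice(idx)] = 1
        elif ch == "repress_ori":
            idx = np.flatnonzero(new.gene_states_ori == 1)
            new.gene_states_ori[rng.choice(idx)] = 0
        elif ch == "activate_ter":
            idx = np.flatnonzero(new.gene_states_ter == 0)
            new.gene_states_ter[rng.choice(idx)] = 1
        elif ch == "repress_ter":
            idx = np.flatnonzero(new.gene_states_ter == 1)
            new.gene_states_ter[rng.choice(idx)] = 0
        for attr, delta in _UPDATES.get(ch, ()):
            setattr(new, attr, getattr(new, attr) + delta)
        return new, ch

    # scheduled event wins; SSA clock is resampled on the next call
    new = _copy_state(s)
    new.time += dt_sched
    new.age = sched_age
    if sched_age < cc.T:
        if sched_age == rep_o:
            new = replicate_locus(new, "ori")
        if sched_age == rep_t:
            new = replicate_locus(new, "ter")
        new.volume = volume_at_age(VolumeModel(cc), new.age)
        return new, "replication"
    new = partition_at_division(
        new, rng, replicate_at_division=(rep_o >= cc.T, rep_t >= cc.T))
    new.volume = VolumeModel(cc).V0
    return new, "division"


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of a lineage / ensemble simulation.

    ``seed`` must be set explicitly — stochastic runs refuse to start
    without one.  ``burn_in_h`` hours are simulated before sampling starts;
    the window averages cover [burn_in, t_end].  ``init`` is one of
    ``"all_active_empty"`` (all gene copies active, no molecules),
    ``"ori_dominant"`` / ``"ter_dominant"`` (counts rounded from the
    corresponding deterministic branch, opposing copies repressed), or an
    explicit :class:`StochasticCellState`.
    """

    T: float = 40.0
    rc: RateConstants = field(default_factory=RateConstants)
    ori: LocusSpec = DEFAULT_ORI_LOCUS
    ter: LocusSpec = DEFAULT_TER_LOCUS
    t_end_h: float = 30.0
    burn_in_h: float = 0.0
    record_dt_s: float = 60.0
    seed: int | None = None
    init: str | StochasticCellState = "all_active_empty"
    cc_kwargs: dict = field(default_factory=dict)

    @property
    def cc(self) -> CellCycleParams:
        return CellCycleParams(T=self.T, **self.cc_kwargs)

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError("stochastic simulation requires an explicit seed")
        return int(self.seed)


@dataclass
class Trajectory:
    """Sampled lineage records plus run metadata."""

    samples: pd.DataFrame
    final_state: StochasticCellState
    fpt_h: float | None
    window_means: dict[str, float]
    birth_means: dict[str, float] | None
    n_births: int
    counters: np.ndarray
    config: SimulationConfig

    def total_protein_means(self) -> tuple[float, float]:
        """Window-averaged total protein (P + 2D) of each gene."""
        w = self.window_means
        return (w["P_ori"] + 2.0 * w["D_ori"], w["P_ter"] + 2.0 * w["D_ter"])

    def total_protein_birth_means(self) -> tuple[float, float]:
        """Newborn-cell mean total protein (P + 2D) of each gene.

        Sampling just after division removes the cell-cycle phase: the
        expected newborn content is the protein produced over one cycle,
        proportional to the cycle-averaged gene dosage.
        """
        if self.birth_means is None:
            raise ValueError("no divisions recorded in the averaging window")
        b = self.birth_means
        return (b["P_ori"] + 2.0 * b["D_ori"], b["P_ter"] + 2.0 * b["D_ter"])


def initial_state(cfg: SimulationConfig) -> StochasticCellState:
    """Materialise the configured initial condition as a cell state at age 0."""
    if isinstance(cfg.init, StochasticCellState):
        return cfg.init
    cc = cfg.cc
    n_o = copies_at_birth(cfg.ori, cc)
    n_t = copies_at_birth(cfg.ter, cc)
    v0 = VolumeModel(cc).V0
    if cfg.init == "all_active_empty":
        return StochasticCellState(np.ones(n_o, np.int8), np.ones(n_t, np.int8),
                                   volume=v0)
    if cfg.init in ("ori_dominant", "ter_dominant"):
        dom = cfg.init.split("_")[0]
        counts = _dominant_branch_counts(cfg.rc, cfg.T, cfg.ori, cfg.ter, dom,
                                         tuple(sorted(cfg.cc_kwargs.items())))
        gs_o = np.full(n_o, 1 if dom == "ori" else 0, np.int8)
        gs_t = np.full(n_t, 1 if dom == "ter" else 0, np.int8)
        return StochasticCellState(gs_o, gs_t, *counts, volume=v0)
    raise ValueError(f"unknown initial condition mode {cfg.init!r}")


@lru_cache(maxsize=64)
def _dominant_branch_counts(rc: RateConstants, T: float, ori: LocusSpec,
                            ter: LocusSpec, dom: str, cc_items: tuple):
    """Deterministic dominant-branch molecule levels, rounded to counts."""
    cc = CellCycleParams(T=T, **dict(cc_items))
    det, _ = relax_to_steady_state(
        dominant_initial_state(rc, cc, dom, ori, ter),
        rc, cc, ori, ter, raise_on_failure=False)
    return (round(det.M_ori), round(det.M_ter), round(det.P_ori),
            round(det.P_ter), round(det.D_ori), round(det.D_ter))


def _kernel_args(cfg: SimulationConfig):
    cc = cfg.cc
    er = effective_rates(cfg.rc, cc, 0.0)
    return (cc.T_seconds, VolumeModel(cc).V0,
            replication_age(cfg.ori, cc) * 60.0,
            replication_age(cfg.ter, cc) * 60.0,
            cfg.rc.k_g, cfg.rc.r_g_scale, er.k_m, er.k_p,
            cfg.rc.k_d_scale, cfg.rc.r_d, cfg.rc.r_m)


def _run(cfg: SimulationConfig, detect: int = 0,
         record: bool = True) -> Trajectory:
    seed = cfg.require_seed() % (2 ** 31)
    T_s, V0, rep_o, rep_t, kg, rgs, km, kp, kds, rd, rm = _kernel_args(cfg)
    s0 = initial_state(cfg)
    t_end = cfg.t_end_h * 3600.0
    t_rec0 = cfg.burn_in_h * 3600.0
    record_dt = cfg.record_dt_s if record else 0.0
    samples, state, age, fpt, sums, counters = _ssa.run_lineage(
        seed, T_s, V0, rep_o, rep_t, kg, rgs, km, kp, kds, rd, rm,
        False, s0.to_counts(), s0.age * 60.0, t_end, record_dt, t_rec0, detect)
    window = max(t_end - t_rec0, 1e-300)
    species = ("M_ori", "M_ter", "P_ori", "P_ter", "D_ori", "D_ter")
    means = dict(zip(species, (sums[:6] / window).tolist()))
    n_births = int(sums[12])
    birth_means = (dict(zip(species, (sums[6:12] / n_births).tolist()))
                   if n_births > 0 else None)
    df = pd.DataFrame(samples, columns=list(_ssa.SAMPLE_COLUMNS))
    final = StochasticCellState.from_counts(
        state, age=age / 60.0, time=t_end / 60.0,
        volume=V0 * 2.0 ** ((age / 60.0) / cfg.T))
    return Trajectory(samples=df, final_state=final,
                      fpt_h=None if fpt < 0 else fpt / 3600.0,
                      window_means=means, birth_means=birth_means,
                      n_births=n_births, counters=counters, config=cfg)


def simulate_lineage(cfg: SimulationConfig) -> Trajectory:
    """Simulate one lineage for ``cfg.t_end_h`` hours (deterministic per seed)."""
    return _run(cfg, detect=0, record=True)


def first_passage_time(cfg: SimulationConfig, direction: str) -> float | None:
    """Hours until the initially repressed gene overtakes the dominant one.

    ``direction`` is ``"ori_to_ter"`` (start ori-dominant, wait for the ter
    gene's monomers AND free dimers to strictly exceed the ori gene's) or
    ``"ter_to_ori"``.  Returns None when no transition occurs within
    ``cfg.t_end_h`` (censored).
    """
    detect = {"ori_to_ter": 1, "ter_to_ori": 2}[direction]
    return _run(cfg, detect=detect, record=False).fpt_h


@dataclass
class EnsembleSummary:
    """Population summary over independent lineages.

    ``per_lineage`` holds one row per lineage with window-averaged molecule
    counts and total proteins; the time-series means (over lineages, on the
    common sampling grid) support relaxation analyses; R_protein is the
    ratio of the population means of total protein content.
    """

    per_lineage: pd.DataFrame
    time_s: np.ndarray
    mean_tot_ori: np.ndarray
    mean_tot_ter: np.ndarray
    R_protein: float
    R_protein_birth: float
    hist2d: tuple[np.ndarray, np.ndarray, np.ndarray] | None
    config: SimulationConfig
    n_cells: int
    base_seed: int

    def ratio_se(self, birth: bool = False) -> float:
        """Delta-method standard error of R_protein over lineages."""
        suffix = "_birth" if birth else ""
        x = self.per_lineage["tot_ori" + suffix].to_numpy()
        y = self.per_lineage["tot_ter" + suffix].to_numpy()
        n = len(x)
        mx, my = x.mean(), y.mean()
        vx = x.var(ddof=1) / n
        vy = y.var(ddof=1) / n
        cxy = np.cov(x, y, ddof=1)[0, 1] / n
        r = mx / my
        return abs(r) * math.sqrt(vx / mx ** 2 + vy / my ** 2 - 2 * cxy / (mx * my))


def run_ensemble(cfg: SimulationConfig, n_cells: int,
                 base_seed: int | None = None,
                 timeseries: bool = False,
                 hist_bins: int = 40) -> EnsembleSummary:
    """Run ``n_cells`` independent lineages (seeds ``base_seed + i``).

    Window averages use [burn_in, t_end] of every lineage; the 2-D final
    histogram of total protein contents diagnoses bimodality.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    base = cfg.require_seed() if base_seed is None else int(base_seed)
    rows = []
    ts_o = ts_t = time_s = None
    finals = np.empty((n_cells, 2))
    for i in range(n_cells):
        sub = replace(cfg, seed=(base + i) % (2 ** 31))
        traj = _run(sub, record=timeseries or True)
        w = traj.window_means
        tot_o, tot_t = traj.total_protein_means()
        if traj.birth_means is not None:
            tot_ob, tot_tb = traj.total_protein_birth_means()
        else:
            tot_ob = tot_tb = np.nan
        rows.append({**w, "tot_ori": tot_o, "tot_ter": tot_t,
                     "tot_ori_birth": tot_ob, "tot_ter_birth": tot_tb,
                     "seed": sub.seed})
        sm = traj.samples
        finals[i, 0] = sm["P_ori"].iloc[-1] + 2 * sm["D_ori"].iloc[-1]
        finals[i, 1] = sm["P_ter"].iloc[-1] + 2 * sm["D_ter"].iloc[-1]
        if timeseries:
            tot_o_ts = sm["P_ori"].to_numpy() + 2 * sm["D_ori"].to_numpy()
            tot_t_ts = sm["P_ter"].to_numpy() + 2 * sm["D_ter"].to_numpy()
            if ts_o is None:
                time_s = sm["time_s"].to_numpy().copy()
                ts_o = np.zeros_like(tot_o_ts)
                ts_t = np.zeros_like(tot_t_ts)
            m = min(len(ts_o), len(tot_o_ts))
            ts_o[:m] += tot_o_ts[:m]
            ts_t[:m] += tot_t_ts[:m]
    per = pd.DataFrame(rows)
    R = per["tot_ori"].mean() / per["tot_ter"].mean()
    R_birth = per["tot_ori_birth"].mean() / per["tot_ter_birth"].mean()
    if timeseries:
        ts_o = ts_o / n_cells
        ts_t = ts_t / n_cells
    else:
        time_s = np.empty(0)
        ts_o = ts_t = np.empty(0)
    H, ex, ey = np.histogram2d(finals[:, 0], finals[:, 1], bins=hist_bins)
    return EnsembleSummary(per_lineage=per, time_s=time_s,
                           mean_tot_ori=ts_o, mean_tot_ter=ts_t,
                           R_protein=float(R), R_protein_birth=float(R_birth),
                           hist2d=(H, ex, ey),
                           config=cfg, n_cells=n_cells, base_seed=base)


def simulate_frozen(rates: dict[str, float], volume: float,
                    state0: StochasticCellState, t_end_s: float,
                    seed: int, record_dt_s: float = 0.0,
                    burn_in_s: float = 0.0):
    """Reduced-model run: frozen volume, no replication, no division.

    ``rates`` maps k_g, r_g_scale, k_m, k_p, k_d_scale, r_d, r_m to raw
    per-second values (k_m and k_p are used as given; the two ``_scale``
    entries are divided by ``volume``).  Used to cross-check the simulator
    against direct chemical-master-equation solutions on tiny state spaces.
    Returns (samples matrix, final count vector, sums, counters).
    """
    samples, state, age, fpt, sums, counters = _ssa.run_lineage(
        int(seed) % (2 ** 31), 1e12, volume, 1e13, 1e13,
        rates.get("k_g", 0.0), rates.get("r_g_scale", 0.0),
        rates.get("k_m", 0.0), rates.get("k_p", 0.0),
        rates.get("k_d_scale", 0.0), rates.get("r_d", 0.0),
        rates.get("r_m", 0.0),
        True, state0.to_counts(), 0.0, float(t_end_s),
        float(record_dt_s), float(burn_in_s), 0)
    return samples, state, sums, counters
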