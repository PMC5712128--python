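"""Estimators for the toggle's growth-rate response.

* ``protein_ratio`` / ``equilibrium_ratio`` — R_protein, the ratio of the
  population-average total protein contents (monomers + 2·dimers) of the
  two competing genes.
* ``detect_switch`` — first time the initially repressed gene's monomer AND
  free-dimer counts both strictly exceed those of the initially dominant
  gene (conjunctive criterion).
* ``mfpt_fit`` — state-to-state mean first-passage time from the
  exponential tail of first-passage durations.  Transition-time histograms
  are exponential except at the shortest times (fluctuations around the
  unstable saddle), so 1/λ is estimated as the mean excess over a
  truncation threshold (the maximum-likelihood fit of a·exp(-λx) to the
  tail) and reported at the plateau in the threshold.
* ``response_time`` — characteristic time τ of the relaxation of
  log2(R_protein) after a doubling-time shift, by fitting
  y(t) = y∞ + (y0 - y∞) exp(-t/τ).
* ``sensitivity_scan`` — two-fold perturbation of each kinetic parameter
  with four summary metrics (switching time, deterministic bistability
  range, sensitivity R(30 min)/R(60 min), response time) and their log-log
  correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .cell_cycle import LocusSpec
from .model_params import RateConstants
from .deterministic import DEFAULT_ORI_LOCUS, DEFAULT_TER_LOCUS, hysteresis_scan
from .stochastic import (
    EnsembleSummary,
    SimulationConfig,
    Trajectory,
    first_passage_time,
    run_ensemble,
    simulate_lineage,
)

__all__ = [
    "TransitionTimes",
    "MfptFit",
    "SensitivityReport",
    "protein_ratio",
    "equilibrium_ratio",
    "detect_switch",
    "collect_transitions",
    "mfpt_fit",
    "switching_time",
    "response_time",
    "response_time_scalar",
    "sensitivity_scan",
]


def protein_ratio(summary: EnsembleSummary, birth_phase: bool = False) -> float:
    """R_protein from an ensemble: mean(P_ori+2D_ori)/mean(P_ter+2D_ter).

    With ``birth_phase`` the newborn-cell averages are used, which removes
    the within-cycle accumulation phase from the ratio (the expectation
    then equals the cycle-averaged dosage ratio in the uncoupled case).
    """
    return summary.R_protein_birth if birth_phase else summary.R_protein


def equilibrium_ratio(rc: RateConstants, T: float, n_cells: int = 200,
                      t_end_h: float = 40.0, burn_in_h: float = 10.0,
                      seed: int = 0,
                      ori: LocusSpec = DEFAULT_ORI_LOCUS,
                      ter: LocusSpec = DEFAULT_TER_LOCUS,
                      record_dt_s: float = 600.0,
                      birth_phase: bool = False) -> EnsembleSummary:
    """Equilibrated-ensemble R_protein at a fixed doubling time."""
    cfg = SimulationConfig(T=T, rc=rc, ori=ori, ter=ter, t_end_h=t_end_h,
                           burn_in_h=burn_in_h, seed=seed,
                           record_dt_s=record_dt_s)
    return run_ensemble(cfg, n_cells)


def detect_switch(traj: Trajectory | pd.DataFrame, initial_state: str) -> float | None:
    """First passage time (hours) on a recorded trajectory, or None.

    ``initial_state`` is ``"ori-dominant"`` or ``"ter-dominant"``.  The
    switch is the first sample at which BOTH the monomer count and the free
    dimer count of the initially repressed gene strictly exceed those of
    the initially dominant gene.
    """
    df = traj.samples if isinstance(traj, Trajectory) else traj
    if initial_state in ("ori-dominant", "ori_dominant"):
        hit = (df["P_ter"] > df["P_ori"]) & (df["D_ter"] > df["D_ori"])
    elif initial_state in ("ter-dominant", "ter_dominant"):
        hit = (df["P_ori"] > df["P_ter"]) & (df["D_ori"] > df["D_ter"])
    else:
        raise ValueError("initial_state must be 'ori-dominant' or 'ter-dominant'")
    idx = np.flatnonzero(hit.to_numpy())
    if idx.size == 0:
        return None
    return float(df["time_s"].iloc[idx[0]] / 3600.0)


@dataclass(frozen=True)
class TransitionTimes:
    """First-passage durations (hours) and the number of censored runs."""

    durations_h: np.ndarray
    n_censored: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.durations_h, dtype=float)
        if d.size and (d <= 0).any():
            raise ValueError("transition durations must be positive")
        object.__setattr__(self, "durations_h", d)


class InsufficientTransitionsError(RuntimeError):
    """Too few uncensored transitions for a tail fit.

    Raise the per-run time limit or the number of runs, or lower
    ``min_transitions`` at the cost of a noisier MFPT estimate.
    """


@dataclass(frozen=True)
class MfptFit:
    """Exponential-tail fit of first-passage durations.

    ``estimates[i]`` is the mean excess of the durations over
    ``thresholds[i]`` (the MLE of 1/λ for a shifted exponential);
    ``mfpt_h`` is the estimate at the plateau threshold, i.e. the first
    threshold at which successive estimates change by less than
    ``rel_tol``.
    """

    thresholds: np.ndarray
    estimates: np.ndarray
    n_tail: np.ndarray
    mfpt_h: float
    plateau_threshold: float


def mfpt_fit(tt: TransitionTimes | np.ndarray | Sequence[float],
             truncation_grid: np.ndarray | None = None,
             rel_tol: float = 0.05,
             min_transitions: int = 100) -> MfptFit:
    """Estimate the MFPT 1/λ from the exponential tail of the durations.

    For each truncation threshold c the estimate is mean(x - c | x > c) —
    the maximum-likelihood exponential fit to the tail, which needs no
    histogram binning.  The default threshold grid spans 0 to the sample
    mean in 11 steps.  Short-duration contamination (recrossings near the
    unstable state) biases the c = 0 estimate; the reported value is taken
    at the first threshold where the estimate has stabilised.
    """
    if not isinstance(tt, TransitionTimes):
        tt = TransitionTimes(np.asarray(tt, dtype=float))
    x = tt.durations_h
    if x.size < min_transitions:
        raise InsufficientTransitionsError(
            f"{x.size} uncensored transitions < required {min_transitions}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all durations identical")
    if truncation_grid is None:
        truncation_grid = np.linspace(0.0, x.mean(), 11)
    thresholds = np.asarray(truncation_grid, dtype=float)
    estimates = np.empty(len(thresholds))
    n_tail = np.empty(len(thresholds), dtype=int)
    for i, c in enumerate(thresholds):
        tail = x[x > c]
        n_tail[i] = tail.size
        estimates[i] = (tail - c).mean() if tail.size else np.nan
    plateau_i = len(thresholds) - 1
    for i in range(len(thresholds) - 1):
        if (np.isfinite(estimates[i]) and np.isfinite(estimates[i + 1])
                and abs(estimates[i + 1] - estimates[i]) < rel_tol * estimates[i]):
            plateau_i = i
            break
    return MfptFit(thresholds=thresholds, estimates=estimates, n_tail=n_tail,
                   mfpt_h=float(estimates[plateau_i]),
                   plateau_threshold=float(thresholds[plateau_i]))


def collect_transitions(rc: RateConstants, T: float, direction: str,
                        n_runs: int, t_max_h: float, seed: int,
                        ori: LocusSpec = DEFAULT_ORI_LOCUS,
                        ter: LocusSpec = DEFAULT_TER_LOCUS) -> TransitionTimes:
    """Run ``n_runs`` lineages from the dominant state; collect switch times.

    ``direction`` is ``"ori_to_ter"`` or ``"ter_to_ori"``.  Each lineage
    starts from the corresponding deterministic-branch state (rounded
    counts) and runs until the conjunctive switch criterion fires or
    ``t_max_h`` hours elapse (censored).
    """
    init = "ori_dominant" if direction == "ori_to_ter" else "ter_dominant"
    durations = []
    censored = 0
    for i in range(n_runs):
        cfg = SimulationConfig(T=T, rc=rc, ori=ori, ter=ter, t_end_h=t_max_h,
                               seed=(seed + i) % (2 ** 31), init=init,
                               record_dt_s=0.0)
        fpt = first_passage_time(cfg, direction)
        if fpt is None:
            censored += 1
        elif fpt > 0:
            durations.append(fpt)
    return TransitionTimes(np.array(durations), n_censored=censored)


def switching_time(rc: RateConstants, T: float = 40.0,
                   direction: str = "ori_to_ter",
                   min_transitions: int = 100, seed: int = 0,
                   t_max_h: float = 400.0,
                   ori: LocusSpec = DEFAULT_ORI_LOCUS,
                   ter: LocusSpec = DEFAULT_TER_LOCUS,
                   ) -> tuple[float, MfptFit, TransitionTimes]:
    """State-to-state MFPT (hours) at doubling time ``T``.

    Runs lineages in batches until at least ``min_transitions`` uncensored
    transitions are collected, then fits the exponential tail.  At T = 40
    min with the default design the toggle is symmetric and the two
    directions are statistically equivalent.
    """
    batch = int(math.ceil(min_transitions * 1.15))
    tt = collect_transitions(rc, T, direction, batch, t_max_h, seed, ori, ter)
    next_seed = seed + batch
    while tt.durations_h.size < min_transitions:
        extra = collect_transitions(
            rc, T, direction, max(batch // 4, 10), t_max_h, next_seed, ori, ter)
        next_seed += max(batch // 4, 10)
        tt = TransitionTimes(
            np.concatenate([tt.durations_h, extra.durations_h]),
            tt.n_censored + extra.n_censored)
        if next_seed - seed > 50 * batch:
            raise InsufficientTransitionsError(
                f"only {tt.durations_h.size} transitions after "
                f"{next_seed - seed} runs of {t_max_h} h")
    fit = mfpt_fit(tt, min_transitions=min_transitions)
    return fit.mfpt_h, fit, tt


def _exp_relax(t, y_inf, y0, tau):
    return y_inf + (y0 - y_inf) * np.exp(-t / tau)


def response_time(time_h: np.ndarray, log2_ratio: np.ndarray) -> float:
    """Characteristic time τ (hours) of an exponential relaxation.

    Fits y(t) = y∞ + (y0 - y∞)·exp(-t/τ) to the ensemble-mean log2 protein
    ratio after a doubling-time shift.  A flat signal (no relaxation) is
    flagged as ill-defined.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(log2_ratio, dtype=float)
    if np.ptp(y) < 1e-12:
        raise ValueError("flat signal: relaxation time is ill-defined")
    # initial τ from a log-linear regression of |y - y_end|
    dy = np.abs(y - y[-1])
    mask = dy > max(dy.max() * 1e-3, 1e-12)
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], np.log(dy[mask]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3.0
    else:
        tau0 = (t[-1] - t[0]) / 3.0
    tau0 = min(max(tau0, 1e-3), 10 * (t[-1] - t[0]))
    popt, _ = curve_fit(_exp_relax, t, y, p0=(y[-1], y[0], tau0),
                        maxfev=20000)
    tau = float(popt[2])
    if tau <= 0:
        raise ValueError("fit returned a non-positive relaxation time")
    return tau


def response_time_scalar(taus: Sequence[float]) -> float:
    """Geometric mean of relaxation times (e.g. of the 40→30 and 40→60 shifts)."""
    taus = np.asarray(taus, dtype=float)
    if (taus <= 0).any():
        raise ValueError("relaxation times must be positive")
    return float(np.exp(np.mean(np.log(taus))))


def shifted_ensemble_log2_ratio(rc: RateConstants, T_from: float, T_to: float,
                                n_cells: int, hours: float, seed: int,
                                burn_in_generations: int = 20,
                                record_dt_s: float = 600.0,
                                ori: LocusSpec = DEFAULT_ORI_LOCUS,
                                ter: LocusSpec = DEFAULT_TER_LOCUS,
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble-mean log2 R_protein after a doubling-time shift.

    Each lineage equilibrates at ``T_from`` for ``burn_in_generations``
    cell cycles, is divided one last time, re-seeded on the ``T_to``
    replication schedule (copy counts set to the new age-0 values, added
    copies active, dropped repressed copies release their bound dimer) and
    followed for ``hours``.  Returns (time in hours, mean log2 ratio).
    """
    from .cell_cycle import CellCycleParams, copies_at_birth, replication_age

    rng = np.random.default_rng(seed)
    cc_to = CellCycleParams(T=T_to)
    sum_o = sum_t = None
    time_h = None
    for i in range(n_cells):
        pre_cfg = SimulationConfig(
            T=T_from, rc=rc, ori=ori, ter=ter,
            t_end_h=(burn_in_generations * T_from - 1.0) / 60.0,
            seed=(seed + 7919 * (i + 1)) % (2 ** 31), record_dt_s=0.0)
        pre = simulate_lineage(pre_cfg)
        state = _shift_division(pre.final_state, pre_cfg, cc_to, ori, ter, rng)
        cfg = SimulationConfig(
            T=T_to, rc=rc, ori=ori, ter=ter, t_end_h=hours,
            seed=(seed + 104729 * (i + 1)) % (2 ** 31), init=state,
            record_dt_s=record_dt_s)
        traj = simulate_lineage(cfg)
        sm = traj.samples
        tot_o = sm["P_ori"].to_numpy() + 2 * sm["D_ori"].to_numpy()
        tot_t = sm["P_ter"].to_numpy() + 2 * sm["D_ter"].to_numpy()
        if sum_o is None:
            time_h = sm["time_s"].to_numpy() / 3600.0
            sum_o = np.zeros_like(tot_o)
            sum_t = np.zeros_like(tot_t)
        m = min(len(sum_o), len(tot_o))
        sum_o[:m] += tot_o[:m]
        sum_t[:m] += tot_t[:m]
    return time_h, np.log2(sum_o / sum_t)


def _shift_division(state, pre_cfg: SimulationConfig, cc_to, ori, ter, rng):
    """Divide once and re-map the daughter onto the new replication schedule."""
    from .cell_cycle import replication_age
    from .stochastic import partition_at_division

    cc_from = pre_cfg.cc
    rep_flags = (replication_age(ori, cc_from) >= cc_from.T,
                 replication_age(ter, cc_from) >= cc_from.T)
    # the burn-in stops just short of a division; complete it here
    if state.n_ori % 2 and not rep_flags[0] or state.n_ter % 2 and not rep_flags[1]:
        raise RuntimeError("shift point is not at a division boundary")
    daughter = partition_at_division(state, rng, replicate_at_division=rep_flags)
    return _remap_copies(daughter, cc_to, ori, ter, rng)


def _remap_copies(state, cc_to, ori, ter, rng):
    """Adjust copy counts to the new schedule's age-0 values."""
    from .cell_cycle import copies_at_birth
    import numpy as _np

    for attr, locus, dimer_attr in (("gene_states_ori", ori, "D_ter"),
                                    ("gene_states_ter", ter, "D_ori")):
        want = copies_at_birth(locus, cc_to)
        gs = getattr(state, attr)
        if want > gs.size:
            gs = _np.concatenate([gs, _np.ones(want - gs.size, _np.int8)])
        elif want < gs.size:
            keep = rng.choice(gs.size, size=want, replace=False)
            dropped_bound = int((1 - gs).sum() - (1 - gs[keep]).sum())
            setattr(state, dimer_attr, getattr(state, dimer_attr) + dropped_bound)
            gs = gs[keep]
        setattr(state, attr, gs)
    state.age = 0.0
    return state


@dataclass(frozen=True)
class SensitivityReport:
    """Per-perturbation metrics and their log-log correlations.

    ``table`` has one row per (parameter, factor) with columns
    switching_time_h, bistability_range_ratio, sensitivity, response_time_h
    (NaN where a perturbation destroys bistability and a metric does not
    apply); correlations are Pearson coefficients on log10 metric values
    against log10 switching time.
    """

    table: pd.DataFrame
    corr_sensitivity: float
    corr_response_time: float


DEFAULT_SCAN_PARAMETERS = ("k_g", "r_g_scale", "k_m_scale", "k_p_scale",
                           "k_d_scale", "r_d", "r_m")


def default_metrics(rc: RateConstants, seed: int = 0,
                    min_transitions: int = 100,
                    n_cells: int = 100,
                    hysteresis_step: float = 1.0,
                    response_hours: float = 24.0) -> dict[str, float]:
    """The four summary metrics for one parameter set.

    switching_time_h: MFPT at T = 40 min (symmetric point);
    bistability_range_ratio: fold-T ratio of the deterministic hysteresis;
    sensitivity: equilibrium R_protein(T=30)/R_protein(T=60);
    response_time_h: geometric mean of τ(40→30) and τ(40→60).
    Metrics that require bistability are NaN when the deterministic scan is
    monostable.
    """
    hyst = hysteresis_scan(rc, step=hysteresis_step)
    out = {"bistability_range_ratio": hyst.range_ratio if hyst.bistable else np.nan}
    if not hyst.bistable:
        out.update(switching_time_h=np.nan, sensitivity=np.nan,
                   response_time_h=np.nan)
        return out
    st, _, _ = switching_time(rc, min_transitions=min_transitions, seed=seed)
    out["switching_time_h"] = st
    r30 = equilibrium_ratio(rc, 30.0, n_cells=n_cells, seed=seed + 1).R_protein
    r60 = equilibrium_ratio(rc, 60.0, n_cells=n_cells, seed=seed + 2).R_protein
    out["sensitivity"] = r30 / r60
    taus = []
    for T_to, s in ((30.0, seed + 3), (60.0, seed + 4)):
        t_h, y = shifted_ensemble_log2_ratio(rc, 40.0, T_to, n_cells,
                                             response_hours, s)
        taus.append(response_time(t_h, y))
    out["response_time_h"] = response_time_scalar(taus)
    return out


def sensitivity_scan(base: RateConstants,
                     parameters: Sequence[str] = DEFAULT_SCAN_PARAMETERS,
                     factors: Sequence[float] = (2.0, 0.5),
                     metric_fn: Callable[[RateConstants], dict[str, float]] | None = None,
                     seed: int = 0,
                     **metric_kwargs) -> SensitivityReport:
    """Two-fold parameter scan of the four toggle metrics.

    Each parameter is separately multiplied by each factor; metrics are
    evaluated with ``metric_fn`` (default :func:`default_metrics`, which is
    simulation-heavy — pass reduced settings through ``metric_kwargs`` for
    desk-scale scans).  Correlations pair log10 switching time with log10
    sensitivity and log10 response time over the perturbations where both
    are defined.
    """
    if metric_fn is None:
        metric_fn = lambda rc: default_metrics(rc, seed=seed, **metric_kwargs)
    rows = [{"parameter": "base", "factor": 1.0, **metric_fn(base)}]
    for name in parameters:
        for f in factors:
            rows.append({"parameter": name, "factor": f,
                         **metric_fn(base.perturbed(name, f))})
    table = pd.DataFrame(rows)

    def _corr(col: str) -> float:
        sub = table[["switching_time_h", col]].dropna()
        sub = sub[(sub > 0).all(axis=1)]
        if len(sub) < 3:
            return float("nan")
        return float(pearsonr(np.log10(sub["switching_time_h"]),
                              np.log10(sub[col]))[0])

    return SensitivityReport(table=table,
                             corr_sensitivity=_corr("sensitivity"),
                             corr_response_time=_corr("response_time_h"))
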