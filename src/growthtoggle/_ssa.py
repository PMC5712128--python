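"""Numba kernel for the exact stochastic lineage simulation.

The kernel implements a Gillespie algorithm over 14 reaction channels
(activation, repression, transcription, mRNA decay, translation,
dimerization and dimer dissociation, for each of the two genes) with
volume-dependent bimolecular propensities, interrupted by the scheduled
replication of each gene locus and by cell division.  The cell volume is
re-evaluated after every step (the volume changes slowly compared with the
fastest reaction, so the waiting time drawn from the instantaneous
propensities is an accurate approximation).

State layout (int64 vector of length 10)::

    0 n_ori   total copies of the ori-proximal gene (incl. inserted repeats)
    1 a_ori   active copies (a repressed copy holds one bound repressor dimer)
    2 n_ter   total copies of the ter-proximal gene
    3 a_ter   active copies
    4 m_ori   5 m_ter   mRNA counts
    6 p_ori   7 p_ter   free protein monomers
    8 d_ori   9 d_ter   FREE protein dimers (bound dimers are implicit in n-a)

Event-accounting counters (int64 vector of length 16)::

    0 dim_ori        1 dim_ter        dimerization events
    2 dis_ori        3 dis_ter        dimer dissociation events
    4 repress_ori    5 repress_ter    repression events (consume a free dimer
                                      of the *opposing* gene)
    6 act_ori        7 act_ter        activation events (release that dimer)
    8 repl_rel_ori   9 repl_rel_ter   bound dimers released when the locus
                                      replicates
    10 divloss_d_ori 11 divloss_d_ter free dimers lost to the sibling at
                                      division
    12 bndloss_d_ori 13 bndloss_d_ter bound dimers lost with discarded copies
    14 n_divisions   15 n_events
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["run_lineage", "N_COUNTERS", "SAMPLE_COLUMNS"]

N_COUNTERS = 16

#: Column order of the sample matrix returned by :func:`run_lineage`.
SAMPLE_COLUMNS = (
    "time_s", "age_s", "N_ori", "G_active_ori", "N_ter", "G_active_ter",
    "M_ori", "M_ter", "P_ori", "P_ter", "D_ori", "D_ter", "V",
)

_LN2 = 0.6931471805599453
_INF = 1.0e30


@njit(cache=True)
def _partition_copies(n_pre, a_pre):
    """Keep one copy of each replicated pair, chosen uniformly at random.

    The repressed copies form a uniformly random subset of the 2*pairs
    copies (repression hits exchangeable copies), so repressed labels are
    shuffled over slots and pair members drawn at random.  Returns
    (copies kept, active kept, bound dimers lost with discarded copies).
    """
    pairs = n_pre // 2
    r = n_pre - a_pre
    arr = np.zeros(n_pre, np.int64)
    for i in range(r):
        arr[i] = 1
    for i in range(n_pre - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = arr[i]
        arr[i] = arr[j]
        arr[j] = tmp
    kept_rep = 0
    for i in range(pairs):
        idx = 2 * i
        if np.random.random() < 0.5:
            idx += 1
        kept_rep += arr[idx]
    return pairs, pairs - kept_rep, r - kept_rep


@njit(cache=True)
def run_lineage(seed, T_s, V0, rep_o, rep_t,
                kg, rg_scale, km, kp, kd_scale, rd, rm,
                frozen, state0, age0, t_end, record_dt, t_rec0, detect):
    """Simulate one daughter lineage for ``t_end`` seconds of model time.

    Parameters
    ----------
    seed : int
        Seed for the per-lineage RNG (mandatory; reruns are bit-identical).
    T_s, V0 : float
        Doubling time (seconds) and scaled birth volume.
    rep_o, rep_t : float
        Cell age (seconds) at which each locus replicates; a value >= T_s
        means the replication coincides with division (constant copy count).
    kg .. rm : float
        Per-second rate constants; ``rg_scale`` and ``kd_scale`` are divided
        by the current volume.
    frozen : bool
        Freeze the volume at V0 and disable replication and division
        (reduced-model mode used for master-equation cross-checks).
    state0 : int64[10]
        Initial state (see module docstring).
    age0 : float
        Initial cell age in seconds.
    record_dt, t_rec0 : float
        Sampling interval (0 disables sampling) and the time at which both
        sampling and window-averaging start (burn-in end).
    detect : int
        0: none; 1: stop when the ter gene's monomers AND free dimers both
        strictly exceed the ori gene's; 2: the mirror condition; 3: stop
        when the ter gene's total protein content P + 2D strictly exceeds
        the ori gene's (summed reading); 4: its mirror.

    Returns
    -------
    samples, state, age, fpt, sums, counters
        ``samples`` has one row per sampling time (columns in
        ``SAMPLE_COLUMNS``); ``fpt`` is the first-passage time in seconds or
        -1.0; ``sums[0:6]`` holds time-integrals of (M_ori, M_ter, P_ori,
        P_ter, D_ori, D_ter) over [t_rec0, end of run] — divide by the
        window length for time averages; ``sums[6:12]`` accumulates the same
        species sampled just after each division in the window (newborn
        cells) and ``sums[12]`` counts those divisions.  Newborn sampling
        removes the cell-cycle phase from equilibrium ratios: the expected
        newborn protein content equals the protein produced over one cycle,
        which is proportional to the cycle-averaged gene copy number.
    """
    np.random.seed(seed)
    n_o = state0[0]
    a_o = state0[1]
    n_t = state0[2]
    a_t = state0[3]
    m_o = state0[4]
    m_t = state0[5]
    p_o = state0[6]
    p_t = state0[7]
    d_o = state0[8]
    d_t = state0[9]
    age = age0
    t = 0.0
    counters = np.zeros(N_COUNTERS, np.int64)
    sums = np.zeros(13)
    if record_dt > 0.0:
        n_max = int((t_end - t_rec0) / record_dt) + 2
        next_s = t_rec0
    else:
        n_max = 1
        next_s = _INF
    samples = np.zeros((n_max, 13))
    n_rec = 0
    fpt = -1.0

    if detect == 1 and p_t > p_o and d_t > d_o:
        fpt = 0.0
    elif detect == 2 and p_o > p_t and d_o > d_t:
        fpt = 0.0
    elif detect == 3 and p_t + 2 * d_t > p_o + 2 * d_o:
        fpt = 0.0
    elif detect == 4 and p_o + 2 * d_o > p_t + 2 * d_t:
        fpt = 0.0

    while t < t_end and fpt < 0.0:
        if frozen:
            V = V0
        else:
            V = V0 * math.exp(_LN2 * age / T_s)
        rg = rg_scale / V
        kd = kd_scale / V
        c0 = kg * (n_o - a_o)
        c1 = rg * d_t * a_o
        c2 = kg * (n_t - a_t)
        c3 = rg * d_o * a_t
        c4 = km * a_o
        c5 = km * a_t
        c6 = rm * m_o
        c7 = rm * m_t
        c8 = kp * m_o
        c9 = kp * m_t
        c10 = kd * p_o * (p_o - 1)
        c11 = kd * p_t * (p_t - 1)
        c12 = rd * d_o
        c13 = rd * d_t
        a_tot = (c0 + c1 + c2 + c3 + c4 + c5 + c6 + c7
                 + c8 + c9 + c10 + c11 + c12 + c13)

        if frozen:
            sched_age = _INF
        else:
            sched_age = T_s
            if rep_o < T_s and age < rep_o and rep_o < sched_age:
                sched_age = rep_o
            if rep_t < T_s and age < rep_t and rep_t < sched_age:
                sched_age = rep_t
        dt_sched = sched_age - age
        if a_tot > 0.0:
            tau = -math.log(np.random.random()) / a_tot
        else:
            tau = _INF
        dt_stop = t_end - t

        is_stop = dt_stop <= tau and dt_stop <= dt_sched
        is_reaction = (not is_stop) and tau < dt_sched
        if is_stop:
            dt = dt_stop
        elif is_reaction:
            dt = tau
        else:
            dt = dt_sched
        t_new = t + dt

        # sampling: the state is constant on [t, t_new); samples falling at
        # t_new record the pre-event state (left limit)
        while next_s <= t_new and n_rec < n_max:
            age_s = age + (next_s - t)
            if frozen:
                Vs = V0
            else:
                Vs = V0 * math.exp(_LN2 * age_s / T_s)
            samples[n_rec, 0] = next_s
            samples[n_rec, 1] = age_s
            samples[n_rec, 2] = n_o
            samples[n_rec, 3] = a_o
            samples[n_rec, 4] = n_t
            samples[n_rec, 5] = a_t
            samples[n_rec, 6] = m_o
            samples[n_rec, 7] = m_t
            samples[n_rec, 8] = p_o
            samples[n_rec, 9] = p_t
            samples[n_rec, 10] = d_o
            samples[n_rec, 11] = d_t
            samples[n_rec, 12] = Vs
            n_rec += 1
            next_s += record_dt

        ov = t_new - max(t, t_rec0)
        if ov > 0.0:
            sums[0] += m_o * ov
            sums[1] += m_t * ov
            sums[2] += p_o * ov
            sums[3] += p_t * ov
            sums[4] += d_o * ov
            sums[5] += d_t * ov

        t = t_new
        if is_stop:
            age += dt
            break

        if is_reaction:
            age += dt
            counters[15] += 1
            u = np.random.random() * a_tot
            if u < c0:
                a_o += 1
                d_t += 1
                counters[6] += 1
            elif u < c0 + c1:
                a_o -= 1
                d_t -= 1
                counters[4] += 1
            elif u < c0 + c1 + c2:
                a_t += 1
                d_o += 1
                counters[7] += 1
            elif u < c0 + c1 + c2 + c3:
                a_t -= 1
                d_o -= 1
                counters[5] += 1
            elif u < c0 + c1 + c2 + c3 + c4:
                m_o += 1
            elif u < c0 + c1 + c2 + c3 + c4 + c5:
                m_t += 1
            elif u < c0 + c1 + c2 + c3 + c4 + c5 + c6:
                m_o -= 1
            elif u < c0 + c1 + c2 + c3 + c4 + c5 + c6 + c7:
                m_t -= 1
            elif u < c0 + c1 + c2 + c3 + c4 + c5 + c6 + c7 + c8:
                p_o += 1
            elif u < c0 + c1 + c2 + c3 + c4 + c5 + c6 + c7 + c8 + c9:
                p_t += 1
            elif u < c0 + c1 + c2 + c3 + c4 + c5 + c6 + c7 + c8 + c9 + c10:
                p_o -= 2
                d_o += 1
                counters[0] += 1
            elif u < (c0 + c1 + c2 + c3 + c4 + c5 + c6 + c7 + c8 + c9
                      + c10 + c11):
                p_t -= 2
                d_t += 1
                counters[1] += 1
            elif u < (c0 + c1 + c2 + c3 + c4 + c5 + c6 + c7 + c8 + c9
                      + c10 + c11 + c12):
                d_o -= 1
                p_o += 2
                counters[2] += 1
            else:
                d_t -= 1
                p_t += 2
                counters[3] += 1
        else:
            # scheduled event(s) at the current cell age
            age = sched_age
            if rep_o < T_s and sched_age == rep_o:
                rel = n_o - a_o
                d_t += rel
                counters[8] += rel
                n_o *= 2
                a_o = n_o
            if rep_t < T_s and sched_age == rep_t:
                rel = n_t - a_t
                d_o += rel
                counters[9] += rel
                n_t *= 2
                a_t = n_t
            if sched_age == T_s:
                # division; a locus replicating exactly at division first
                # releases its bound repressors and keeps a constant count
                if rep_o >= T_s:
                    rel = n_o - a_o
                    d_t += rel
                    counters[8] += rel
                    a_o = n_o
                else:
                    n_o, a_o, lost = _partition_copies(n_o, a_o)
                    counters[13] += lost
                if rep_t >= T_s:
                    rel = n_t - a_t
                    d_o += rel
                    counters[9] += rel
                    a_t = n_t
                else:
                    n_t, a_t, lost = _partition_copies(n_t, a_t)
                    counters[12] += lost
                m_o = np.random.binomial(m_o, 0.5)
                m_t = np.random.binomial(m_t, 0.5)
                p_o = np.random.binomial(p_o, 0.5)
                p_t = np.random.binomial(p_t, 0.5)
                keep = np.random.binomial(d_o, 0.5)
                counters[10] += d_o - keep
                d_o = keep
                keep = np.random.binomial(d_t, 0.5)
                counters[11] += d_t - keep
                d_t = keep
                counters[14] += 1
                age = 0.0
                if t >= t_rec0:
                    sums[6] += m_o
                    sums[7] += m_t
                    sums[8] += p_o
                    sums[9] += p_t
                    sums[10] += d_o
                    sums[11] += d_t
                    sums[12] += 1.0

        if detect == 1 and p_t > p_o and d_t > d_o:
            fpt = t
        elif detect == 2 and p_o > p_t and d_o > d_t:
            fpt = t
        elif detect == 3 and p_t + 2 * d_t > p_o + 2 * d_o:
            fpt = t
        elif detect == 4 and p_o + 2 * d_o > p_t + 2 * d_t:
            fpt = t

    state = np.empty(10, np.int64)
    state[0] = n_o
    state[1] = a_o
    state[2] = n_t
    state[3] = a_t
    state[4] = m_o
    state[5] = m_t
    state[6] = p_o
    state[7] = p_t
    state[8] = d_o
    state[9] = d_t
    return samples[:n_rec], state, age, fpt, sums, counters
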