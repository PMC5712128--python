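"""Direct chemical-master-equation solution of the reduced toggle.

Reduced model: one copy of each gene, frozen unit volume, no replication,
no division, no translation.  Each gene's protein pool (monomers + 2·free
dimers + 2·bound dimers) is then conserved, and with transcription capped
at a small mRNA count the state space is finite:

    state = (g_ori, g_ter, m_ori, m_ter, d_ori, d_ter)

with the monomer counts implied by conservation,
``p_i = tot_i - 2 d_i - 2 (1 - g_j)`` (the dimer repressing gene j is made
of protein i).  The stationary distribution solves pi Q = 0 for the
generator assembled from the same ten channel types the simulator uses.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import null_space


def enumerate_states(tot_o: int, tot_t: int, m_cap: int):
    """Feasible states and their index map."""
    states = []
    for g_o, g_t in itertools.product((0, 1), repeat=2):
        for d_o in range(tot_o // 2 + 1):
            if tot_o - 2 * d_o - 2 * (1 - g_t) < 0:
                continue
            for d_t in range(tot_t // 2 + 1):
                if tot_t - 2 * d_t - 2 * (1 - g_o) < 0:
                    continue
                for m_o in range(m_cap + 1):
                    for m_t in range(m_cap + 1):
                        states.append((g_o, g_t, m_o, m_t, d_o, d_t))
    return states, {s: i for i, s in enumerate(states)}


def stationary_distribution(rates: dict[str, float], tot_o: int, tot_t: int,
                            m_cap: int) -> tuple[list[tuple], np.ndarray]:
    """Stationary law of the reduced model (transcription reflected at m_cap)."""
    k_g = rates.get("k_g", 0.0)
    r_g = rates.get("r_g_scale", 0.0)      # volume = 1
    k_m = rates.get("k_m", 0.0)
    r_m = rates.get("r_m", 0.0)
    k_d = rates.get("k_d_scale", 0.0)
    r_d = rates.get("r_d", 0.0)
    states, index = enumerate_states(tot_o, tot_t, m_cap)
    n = len(states)
    Q = np.zeros((n, n))

    def add(i, dest, rate):
        if rate <= 0.0:
            return
        j = index[dest]
        Q[i, j] += rate
        Q[i, i] -= rate

    for i, (g_o, g_t, m_o, m_t, d_o, d_t) in enumerate(states):
        p_o = tot_o - 2 * d_o - 2 * (1 - g_t)
        p_t = tot_t - 2 * d_t - 2 * (1 - g_o)
        if g_o == 0:
            add(i, (1, g_t, m_o, m_t, d_o, d_t + 1), k_g)
        else:
            add(i, (0, g_t, m_o, m_t, d_o, d_t - 1), r_g * d_t)
        if g_t == 0:
            add(i, (g_o, 1, m_o, m_t, d_o + 1, d_t), k_g)
        else:
            add(i, (g_o, 0, m_o, m_t, d_o - 1, d_t), r_g * d_o)
        if m_o < m_cap:
            add(i, (g_o, g_t, m_o + 1, m_t, d_o, d_t), k_m * g_o)
        if m_t < m_cap:
            add(i, (g_o, g_t, m_o, m_t + 1, d_o, d_t), k_m * g_t)
        add(i, (g_o, g_t, m_o - 1, m_t, d_o, d_t), r_m * m_o if m_o else 0.0)
        add(i, (g_o, g_t, m_o, m_t - 1, d_o, d_t), r_m * m_t if m_t else 0.0)
        if p_o >= 2:
            add(i, (g_o, g_t, m_o, m_t, d_o + 1, d_t), k_d * p_o * (p_o - 1))
        if d_o >= 1:
            add(i, (g_o, g_t, m_o, m_t, d_o - 1, d_t), r_d * d_o)
        if p_t >= 2:
            add(i, (g_o, g_t, m_o, m_t, d_o, d_t + 1), k_d * p_t * (p_t - 1))
        if d_t >= 1:
            add(i, (g_o, g_t, m_o, m_t, d_o, d_t - 1), r_d * d_t)

    ns = null_space(Q.T)
    assert ns.shape[1] == 1, "generator should have a unique stationary law"
    pi = ns[:, 0]
    pi = np.abs(pi) / np.abs(pi).sum()
    return states, pi


def empirical_distribution(samples: np.ndarray, index: dict, tot_o: int,
                           tot_t: int) -> tuple[np.ndarray, float]:
    """Histogram simulator samples onto the CME state space.

    Sample columns follow the simulator layout; the gene activity is
    recovered from the active-copy counts.  Returns (probabilities over the
    enumerated states, fraction of samples outside the truncated space).
    """
    counts = np.zeros(len(index))
    outside = 0
    for row in samples:
        g_o, g_t = int(row[3]), int(row[5])
        m_o, m_t = int(row[6]), int(row[7])
        d_o, d_t = int(row[10]), int(row[11])
        key = (g_o, g_t, m_o, m_t, d_o, d_t)
        if key in index:
            counts[index[key]] += 1
        else:
            outside += 1
    total = counts.sum() + outside
    return counts / total, outside / total
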