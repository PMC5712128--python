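"""Deterministic (mean-field) approximation of the toggle switch.

Gene activities G_ori, G_ter ∈ [0, 1] and continuous mRNA / monomer / dimer
levels evolve under mass-action kinetics with implicit division: every
species except the gene activities is diluted at rate ln(2)/T.  Gene copy
numbers enter as their cycle averages (S_ori(T), and 2 S_ter(T) for the two
inserted ter-proximal copies by default) and the cell volume is held at its
pre-division value 2 V0(T), so the bimolecular rates r_g and k_d are
constant in time.  The eight equations (i ∈ {ori, ter}, j the opposing
gene):

    dG_i/dt = k_g (1 - G_i) - r_g D_j G_i
    dM_i/dt = S_i k_m(T) G_i - (r_m + ln2/T) M_i
    dP_i/dt = k_p(T) M_i - (ln2/T) P_i + 2 (r_d D_i - k_d P_i^2 / 2)
    dD_i/dt = k_d P_i^2 / 2 - (r_d + ln2/T) D_i

The approximation is coarse for the small molecule numbers of a bacterium
but identifies bistability: sweeping the doubling time T up and then down
while re-using the previous steady state exposes a hysteresis loop whenever
two stable branches coexist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .cell_cycle import CellCycleParams, LocusSpec, VolumeModel, mean_copies
from .model_params import RateConstants, transcription_rate, translation_rate

__all__ = [
    "DEFAULT_ORI_LOCUS",
    "DEFAULT_TER_LOCUS",
    "DeterministicState",
    "HysteresisResult",
    "SteadyStateError",
    "ode_rhs",
    "uncoupled_steady_state",
    "dominant_initial_state",
    "relax_to_steady_state",
    "total_protein",
    "protein_ratio",
    "hysteresis_scan",
]

#: Default toggle design: one copy at *ori*, two identical copies at *ter*
#: (balanced at T = 40 min, where the ori:ter dosage ratio is 2).
DEFAULT_ORI_LOCUS = LocusSpec(L=0.0, n_inserted=1)
DEFAULT_TER_LOCUS = LocusSpec(L=1.0, n_inserted=2)

# State vector layout.
_IDX = {"G_ori": 0, "G_ter": 1, "M_ori": 2, "M_ter": 3,
        "P_ori": 4, "P_ter": 5, "D_ori": 6, "D_ter": 7}


@dataclass(frozen=True)
class DeterministicState:
    """Continuous gene activities and molecule levels."""

    G_ori: float
    G_ter: float
    M_ori: float
    M_ter: float
    P_ori: float
    P_ter: float
    D_ori: float
    D_ter: float

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.G_ori <= 1 + 1e-9 and -1e-9 <= self.G_ter <= 1 + 1e-9):
            raise ValueError("gene activities must lie in [0, 1]")
        for name in ("M_ori", "M_ter", "P_ori", "P_ter", "D_ori", "D_ter"):
            if getattr(self, name) < -1e-9:
                raise ValueError(f"molecule level {name} must be non-negative")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in _IDX], dtype=float)

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "DeterministicState":
        y = np.asarray(y, dtype=float)
        return cls(**{k: float(np.clip(y[i], 0.0, 1.0)) if k.startswith("G")
                      else float(max(y[i], 0.0)) for k, i in _IDX.items()})

    def mirrored(self) -> "DeterministicState":
        """Swap the roles of the two genes (ori ↔ ter)."""
        return DeterministicState(
            G_ori=self.G_ter, G_ter=self.G_ori, M_ori=self.M_ter, M_ter=self.M_ori,
            P_ori=self.P_ter, P_ter=self.P_ori, D_ori=self.D_ter, D_ter=self.D_ori)


class SteadyStateError(RuntimeError):
    """Relaxation failed to reach the steady-state tolerance within t_max."""


def _coefficients(rc: RateConstants, cc: CellCycleParams,
                  ori: LocusSpec, ter: LocusSpec) -> tuple[float, ...]:
    vm = VolumeModel(cc)
    V = 2.0 * vm.V0                      # pre-division volume, constant here
    mu = cc.dilution_rate                # ln2 / T in 1/s
    k_m = transcription_rate(rc, cc)
    k_p = translation_rate(rc, cc)
    s_ori = mean_copies(ori, cc)         # includes inserted copy counts
    s_ter = mean_copies(ter, cc)
    return (rc.k_g, rc.r_g_scale / V, k_m, k_p, rc.k_d_scale / V,
            rc.r_d, rc.r_m, mu, s_ori, s_ter)


def ode_rhs(y: np.ndarray, rc: RateConstants, cc: CellCycleParams,
            ori: LocusSpec = DEFAULT_ORI_LOCUS,
            ter: LocusSpec = DEFAULT_TER_LOCUS) -> np.ndarray:
    """Time derivative (per second) of the 8-component state vector.

    Layout: [G_ori, G_ter, M_ori, M_ter, P_ori, P_ter, D_ori, D_ter].
    """
    k_g, r_g, k_m, k_p, k_d, r_d, r_m, mu, s_ori, s_ter = _coefficients(rc, cc, ori, ter)
    g_o, g_t, m_o, m_t, p_o, p_t, d_o, d_t = y
    dim_o = 0.5 * k_d * p_o * p_o
    dim_t = 0.5 * k_d * p_t * p_t
    return np.array([
        k_g * (1.0 - g_o) - r_g * d_t * g_o,
        k_g * (1.0 - g_t) - r_g * d_o * g_t,
        s_ori * k_m * g_o - (r_m + mu) * m_o,
        s_ter * k_m * g_t - (r_m + mu) * m_t,
        k_p * m_o - mu * p_o + 2.0 * (r_d * d_o - dim_o),
        k_p * m_t - mu * p_t + 2.0 * (r_d * d_t - dim_t),
        dim_o - (r_d + mu) * d_o,
        dim_t - (r_d + mu) * d_t,
    ])


def _ode_jac(y: np.ndarray, coef: tuple[float, ...]) -> np.ndarray:
    k_g, r_g, k_m, k_p, k_d, r_d, r_m, mu, s_ori, s_ter = coef
    g_o, g_t, m_o, m_t, p_o, p_t, d_o, d_t = y
    J = np.zeros((8, 8))
    J[0, 0] = -k_g - r_g * d_t
    J[0, 7] = -r_g * g_o
    J[1, 1] = -k_g - r_g * d_o
    J[1, 6] = -r_g * g_t
    J[2, 0] = s_ori * k_m
    J[2, 2] = -(r_m + mu)
    J[3, 1] = s_ter * k_m
    J[3, 3] = -(r_m + mu)
    J[4, 2] = k_p
    J[4, 4] = -mu - 2.0 * k_d * p_o
    J[4, 6] = 2.0 * r_d
    J[5, 3] = k_p
    J[5, 5] = -mu - 2.0 * k_d * p_t
    J[5, 7] = 2.0 * r_d
    J[6, 4] = k_d * p_o
    J[6, 6] = -(r_d + mu)
    J[7, 5] = k_d * p_t
    J[7, 7] = -(r_d + mu)
    return J


def uncoupled_steady_state(rc: RateConstants, cc: CellCycleParams,
                           locus: LocusSpec) -> tuple[float, float, float]:
    """Closed-form (M, P, D) steady state of one gene with r_g = 0.

    The linear mRNA / total-protein subsystem gives M* and the total
    protein P + 2D; the monomer–dimer balance ½ k_d P² = (r_d + μ) D then
    fixes the split via a quadratic.
    """
    vm = VolumeModel(cc)
    mu = cc.dilution_rate
    k_m = transcription_rate(rc, cc)
    k_p = translation_rate(rc, cc)
    k_d = rc.k_d_scale / (2.0 * vm.V0)
    m = mean_copies(locus, cc) * k_m / (rc.r_m + mu)
    tot = k_p * m / mu
    a = rc.r_d + mu
    if k_d == 0:
        return m, tot, 0.0
    p = (-a + math.sqrt(a * a + 4.0 * k_d * a * tot)) / (2.0 * k_d)
    return m, p, (tot - p) / 2.0


def dominant_initial_state(rc: RateConstants, cc: CellCycleParams,
                           dominant: str,
                           ori: LocusSpec = DEFAULT_ORI_LOCUS,
                           ter: LocusSpec = DEFAULT_TER_LOCUS) -> DeterministicState:
    """Extreme starting point with one gene fully expressed, the other silent."""
    if dominant not in ("ori", "ter"):
        raise ValueError("dominant must be 'ori' or 'ter'")
    locus = ori if dominant == "ori" else ter
    m, p, d = uncoupled_steady_state(rc, cc, locus)
    zeros = dict(M_ori=0.0, M_ter=0.0, P_ori=0.0, P_ter=0.0, D_ori=0.0, D_ter=0.0)
    zeros[f"M_{dominant}"] = m
    zeros[f"P_{dominant}"] = p
    zeros[f"D_{dominant}"] = d
    g = dict(G_ori=0.0, G_ter=0.0)
    g[f"G_{dominant}"] = 1.0
    return DeterministicState(**g, **zeros)


def relax_to_steady_state(s0: DeterministicState, rc: RateConstants,
                          cc: CellCycleParams,
                          ori: LocusSpec = DEFAULT_ORI_LOCUS,
                          ter: LocusSpec = DEFAULT_TER_LOCUS,
                          tol: float = 1e-9, t_max: float = 3e7,
                          raise_on_failure: bool = True,
                          ) -> tuple[DeterministicState, bool]:
    """Integrate until the scaled derivative norm drops below ``tol``.

    Convergence requires |dy_i/dt| <= tol * max(|y_i|, 1) for every
    component.  Integration uses the implicit BDF method (the gene-activity
    and dimer kinetics differ by orders of magnitude in rate) in chunks of
    ~30 dilution times, up to ``t_max`` seconds of model time.  Returns
    ``(state, converged)``; non-convergence raises unless
    ``raise_on_failure`` is False.
    """
    coef = _coefficients(rc, cc, ori, ter)
    rhs = lambda t, y: ode_rhs(y, rc, cc, ori, ter)
    jac = lambda t, y: _ode_jac(y, coef)
    y = s0.to_vector()
    chunk = 30.0 / cc.dilution_rate
    t_done = 0.0
    converged = False
    while t_done < t_max:
        sol = solve_ivp(rhs, (0.0, chunk), y, method="BDF", jac=jac,
                        rtol=1e-8, atol=1e-10)
        if not sol.success:
            break
        y = sol.y[:, -1]
        t_done += chunk
        f = rhs(0.0, y)
        if np.all(np.abs(f) <= tol * np.maximum(np.abs(y), 1.0)):
            converged = True
            break
    if not converged and raise_on_failure:
        raise SteadyStateError(f"no steady state within t_max={t_max} s")
    return DeterministicState.from_vector(y), converged


def total_protein(s: DeterministicState) -> tuple[float, float]:
    """Total protein content (monomers + 2·dimers) of each gene."""
    return s.P_ori + 2.0 * s.D_ori, s.P_ter + 2.0 * s.D_ter


def protein_ratio(s: DeterministicState) -> float:
    """(P_ori + 2 D_ori) / (P_ter + 2 D_ter)."""
    tot_o, tot_t = total_protein(s)
    return tot_o / tot_t


@dataclass(frozen=True)
class HysteresisResult:
    """Quasi-static sweep summary over the doubling time T."""

    T_grid: np.ndarray
    ratio_up: np.ndarray       # protein ratio along the increasing-T sweep
    ratio_down: np.ndarray     # along the decreasing-T sweep (same grid order)
    bistable: bool
    T_up_fold: float | None    # fold on the up-sweep (ori branch vanishes)
    T_down_fold: float | None  # fold on the down-sweep (ter branch vanishes)
    range_ratio: float         # T_up_fold / T_down_fold; 1.0 when monostable
    all_converged: bool


def _fold_T(T_grid: np.ndarray, log_ratio: np.ndarray, threshold: float) -> float | None:
    jumps = np.abs(np.diff(log_ratio))
    if jumps.max(initial=0.0) <= threshold:
        return None
    i = int(np.argmax(jumps))
    return float(0.5 * (T_grid[i] + T_grid[i + 1]))


def hysteresis_scan(rc: RateConstants, T_lo: float = 20.0, T_hi: float = 120.0,
                    step: float = 0.5,
                    ori: LocusSpec = DEFAULT_ORI_LOCUS,
                    ter: LocusSpec = DEFAULT_TER_LOCUS,
                    jump_threshold: float = 1.0,
                    cc_kwargs: dict | None = None) -> HysteresisResult:
    """Two quasi-static continuation sweeps in T; detect bistability.

    The up-sweep starts from the ori-dominant extreme at ``T_lo``, the
    down-sweep from the ter-dominant extreme at ``T_hi``; each subsequent T
    re-uses the previous steady state, so each sweep follows a stable branch
    until it folds.  A fold shows up as a jump of the log2 protein ratio
    exceeding ``jump_threshold`` between adjacent grid points; bistability is
    declared when the two sweeps disagree by more than the threshold
    anywhere.  ``range_ratio`` (fold on the up-sweep divided by fold on the
    down-sweep) measures the width of the bistable T interval.
    """
    if not (T_lo < T_hi) or step <= 0:
        raise ValueError("need T_lo < T_hi and step > 0")
    kw = cc_kwargs or {}
    T_grid = np.arange(T_lo, T_hi + step / 2, step)
    ratios = {}
    ok = True
    for direction, grid, dominant in (("up", T_grid, "ori"),
                                      ("down", T_grid[::-1], "ter")):
        cc0 = CellCycleParams(T=float(grid[0]), **kw)
        state = dominant_initial_state(rc, cc0, dominant, ori, ter)
        vals = np.empty(len(grid))
        for i, T in enumerate(grid):
            cc = CellCycleParams(T=float(T), **kw)
            state, conv = relax_to_steady_state(state, rc, cc, ori, ter,
                                                raise_on_failure=False)
            ok = ok and conv
            vals[i] = protein_ratio(state)
        ratios[direction] = vals if direction == "up" else vals[::-1]

    log_up = np.log2(ratios["up"])
    log_down = np.log2(ratios["down"])
    bistable = bool(np.any(np.abs(log_up - log_down) > jump_threshold))
    T_up = _fold_T(T_grid, log_up, jump_threshold)
    T_down = _fold_T(T_grid, log_down, jump_threshold)
    if bistable and T_up is not None and T_down is not None and T_down > 0:
        range_ratio = T_up / T_down
    else:
        range_ratio = 1.0
    return HysteresisResult(T_grid=T_grid, ratio_up=ratios["up"],
                            ratio_down=ratios["down"], bistable=bistable,
                            T_up_fold=T_up, T_down_fold=T_down,
                            range_ratio=range_ratio, all_converged=ok)
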