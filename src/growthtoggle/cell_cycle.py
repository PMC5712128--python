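"""Chromosome replication schedule, gene dosage and cell-volume model.

In fast-growing *E. coli* a replication round takes C ≈ 40 min and must finish
D ≈ 20 min before division, so for doubling times T < C + D replication rounds
overlap and loci near the origin of replication (*ori*) are present in more
copies than loci near the terminus (*ter*).  A locus at relative distance
``L`` from *ori* (with the *ori*–*ter* arc of length 1) is passed by a fork
``x = C (1 - L) + D_post`` minutes before the division it belongs to.  Within
a cell cycle of length T the locus therefore carries

    n_inserted * 2**floor(x / T)

copies from birth until age ``T - (x mod T)``, at which point every copy is
replicated simultaneously and the count doubles; when ``x`` is an exact
multiple of T the doubling coincides with division and the count is constant
over the cycle.

This module exposes instantaneous and cycle-averaged copy numbers, the
approximate dosage law ``S_L(T) = S_ter(T) * 2**((1 - L) C / T)``, dosage
ratios between loci, the balanced-locus design calculator, and the
exponentially growing scaled cell volume.

Units: doubling time T, replication time C and the post-replication period
D_post are in minutes throughout this module; volumes are dimensionless
(scaled so that a T = 40 min cell is born with volume 1/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

__all__ = [
    "CellCycleParams",
    "LocusSpec",
    "VolumeModel",
    "BalancedDesign",
    "NoAdmissibleDesignError",
    "DEFAULT_CANDIDATE_RATIOS",
    "copies_at_age",
    "replication_age",
    "copies_at_birth",
    "mean_copies",
    "mean_copies_approx",
    "genome_average_copies",
    "genome_average_copies_approx",
    "dosage_ratio",
    "balanced_locus",
    "best_balanced_design",
    "volume_at_age",
]

#: Inserted-copy ratios considered for the balanced-toggle designs
#: (1-4 copies of the ori-side gene against 2-5 copies of the ter-side gene).
DEFAULT_CANDIDATE_RATIOS: tuple[float, ...] = (
    1 / 4, 1 / 3, 2 / 5, 1 / 2, 3 / 5, 2 / 3, 3 / 4, 4 / 5,
)

# Tolerance for deciding that x = C(1-L) + D_post is an exact multiple of T,
# i.e. that the locus doubles exactly at division and the count is constant.
_MOD_EPS = 1e-9


@dataclass(frozen=True)
class CellCycleParams:
    """Cell-cycle clock: doubling time and replication geometry (minutes).

    Parameters
    ----------
    T:
        Doubling time in minutes.  The supported regime is 20–120 min.
    C:
        Genome replication (C period) duration, default 40 min.
    D_post:
        Termination-to-division (D period) duration, default 20 min.
    """

    T: float
    C: float = 40.0
    D_post: float = 20.0

    def __post_init__(self) -> None:
        if not (20.0 <= self.T <= 120.0):
            raise ValueError(f"doubling time T={self.T} min outside supported range [20, 120]")
        if self.C <= 0:
            raise ValueError("replication time C must be positive")
        if self.D_post < 0:
            raise ValueError("post-replication period D_post must be non-negative")

    @property
    def T_seconds(self) -> float:
        return self.T * 60.0

    @property
    def dilution_rate(self) -> float:
        """Effective dilution rate ln(2)/T in 1/s (implicit-division models)."""
        return math.log(2.0) / self.T_seconds


@dataclass(frozen=True)
class LocusSpec:
    """A gene insertion site: distance from *ori* and inserted copy count.

    ``L`` is measured along the shorter arc in units where the *ori*–*ter*
    distance equals 1, so ``L = 0`` is at *ori* and ``L = 1`` at *ter*.
    """

    L: float
    n_inserted: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.L <= 1.0):
            raise ValueError(f"locus distance L={self.L} outside [0, 1]")
        if self.n_inserted < 1 or int(self.n_inserted) != self.n_inserted:
            raise ValueError("n_inserted must be a positive integer")


@dataclass(frozen=True)
class VolumeModel:
    """Exponential cell growth, V(t) = V0(T) * 2**(t/T), doubling over a cycle."""

    cc: CellCycleParams
    V0: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if math.isnan(self.V0):
            object.__setattr__(self, "V0", birth_volume(self.cc.T))
        if self.V0 <= 0:
            raise ValueError("birth volume must be positive")


def birth_volume(T: float) -> float:
    """Scaled volume just after division, V0(T) = (1/6)(40/T)^2 + 1/3.

    Decreases with T: fast-growing cells are larger (V0(20) = 1,
    V0(40) = 1/2, V0(120) ≈ 0.352).
    """
    return (40.0 / T) ** 2 / 6.0 + 1.0 / 3.0


def volume_at_age(vm: VolumeModel, t: float) -> float:
    """Scaled cell volume at cell age ``t`` minutes, V0 * 2**(t/T)."""
    cc = vm.cc
    if not (0.0 <= t <= cc.T):
        raise ValueError(f"cell age t={t} outside [0, T={cc.T}]")
    return vm.V0 * 2.0 ** (t / cc.T)


def _schedule(locus: LocusSpec, cc: CellCycleParams) -> tuple[int, float, float]:
    """Return (copies at birth, doubling age in minutes, x) for a locus.

    The doubling age is ``T`` itself when the fork passage coincides with
    division (x an exact multiple of T): the count is then constant in [0, T).
    """
    x = cc.C * (1.0 - locus.L) + cc.D_post
    k = int(math.floor(x / cc.T + _MOD_EPS))
    frac = x - k * cc.T
    if frac < _MOD_EPS * max(1.0, cc.T):
        frac = 0.0
    n_birth = locus.n_inserted * (1 << k)
    rep_age = cc.T if frac == 0.0 else cc.T - frac
    return n_birth, rep_age, x


def replication_age(locus: LocusSpec, cc: CellCycleParams) -> float:
    """Cell age (minutes) at which all copies of the locus replicate.

    Equals ``T`` when replication coincides with division, in which case the
    copy count is constant throughout the cycle.
    """
    return _schedule(locus, cc)[1]


def copies_at_birth(locus: LocusSpec, cc: CellCycleParams) -> int:
    """Copy count carried from birth until the within-cycle doubling."""
    return _schedule(locus, cc)[0]


def copies_at_age(locus: LocusSpec, cc: CellCycleParams, t: float) -> int:
    """Instantaneous copy number of ``locus`` at cell age ``t`` (minutes).

    Piecewise constant over the cycle with at most one doubling, at age
    ``T - (x mod T)`` where ``x = C (1 - L) + D_post``.
    """
    if not (0.0 <= t < cc.T):
        raise ValueError(f"cell age t={t} outside [0, T={cc.T})")
    n_birth, rep_age, _ = _schedule(locus, cc)
    return 2 * n_birth if t >= rep_age else n_birth


def mean_copies(locus: LocusSpec, cc: CellCycleParams) -> float:
    """Cycle-averaged copy number (exact piecewise integration).

    For the default C = 40, D_post = 20 geometry this reproduces the
    Cooper–Helmstetter averages S_ori(T) (e.g. 8 at T = 20, 3 at T = 40)
    and S_ter(T) = 1 + 20/T.
    """
    n_birth, rep_age, _ = _schedule(locus, cc)
    # uniform cell-age average of the piecewise-constant count
    return n_birth * (1.0 + (cc.T - rep_age) / cc.T)


def mean_copies_approx(locus: LocusSpec, cc: CellCycleParams) -> float:
    """Smooth dosage approximation S_L(T) = S_ter(T) * 2**((1-L) C/T).

    Exact at L = 1 and within ~10% of :func:`mean_copies` elsewhere over the
    supported T range.
    """
    s_ter = 1.0 + cc.D_post / cc.T
    return locus.n_inserted * s_ter * 2.0 ** ((1.0 - locus.L) * cc.C / cc.T)


def genome_average_copies(cc: CellCycleParams) -> float:
    """DNA content per cell S(T): copy number averaged over all loci and the cycle.

    Three-branch piecewise form (T in minutes)::

        9T/80 + 175/T - 6.5   T < 30
        T/80  +  85/T - 0.5   30 <= T < 60
        1 + 40/T              T >= 60

    Valid for the default C = 40, D_post = 20 geometry.
    """
    T = cc.T
    if T < 30.0:
        return 9.0 * T / 80.0 + 175.0 / T - 6.5
    if T < 60.0:
        return T / 80.0 + 85.0 / T - 0.5
    return 1.0 + 40.0 / T


def genome_average_copies_approx(cc: CellCycleParams) -> float:
    """Smooth approximation S_appr(T) = (1/ln 2)(T/40 + 1/2)(2**(40/T) - 1)."""
    T = cc.T
    return (T / 40.0 + 0.5) * (2.0 ** (40.0 / T) - 1.0) / math.log(2.0)


def dosage_ratio(L1: float, L2: float, cc: CellCycleParams) -> float:
    """Average copy-number ratio of a locus at L1 to one at L2: 2**((C/T)(L2-L1)).

    For L1 = 0, L2 = 1 this is the *ori*:*ter* ratio 2**(C/T) — 2 at
    T = 40 min and 4 at T = 20 min.
    """
    for L in (L1, L2):
        if not (0.0 <= L <= 1.0):
            raise ValueError(f"locus distance {L} outside [0, 1]")
    return 2.0 ** ((cc.C / cc.T) * (L2 - L1))


def balanced_locus(R: float, cc: CellCycleParams) -> float:
    """Distance L2 at which a gene inserted at ratio R balances an *ori* gene.

    Inverts the dosage law: with the ori-side gene at L1 = 0 inserted in the
    smaller copy number (inserted-copy ratio ``R`` in (0, 1]), average
    expression is equal when ``L2 = -(T/C) log2 R``.  The returned value may
    exceed 1 (no admissible position on the chromosome); admissibility is the
    caller's decision.
    """
    if not (0.0 < R <= 1.0):
        raise ValueError(f"inserted-copy ratio R={R} outside (0, 1]")
    return -(cc.T / cc.C) * math.log2(R)


class NoAdmissibleDesignError(ValueError):
    """No candidate inserted-copy ratio yields a locus distance L2 <= 1."""


class BalancedDesign(NamedTuple):
    ratio: float
    L2: float


def best_balanced_design(
    T: float,
    candidate_ratios: Sequence[float] = DEFAULT_CANDIDATE_RATIOS,
    cc_kwargs: dict | None = None,
) -> BalancedDesign:
    """Pick the candidate ratio giving the greatest admissible L2 (<= 1).

    Sensitivity to the doubling time grows with the separation of the two
    gene loci, so among the candidate inserted-copy ratios the design with
    the largest ``L2 = -(T/C) log2 R`` not exceeding 1 is preferred.  Ties
    break toward the smaller ratio.
    """
    if not candidate_ratios:
        raise ValueError("candidate_ratios must be non-empty")
    cc = CellCycleParams(T=T, **(cc_kwargs or {}))
    best: BalancedDesign | None = None
    for R in sorted(candidate_ratios):
        L2 = balanced_locus(R, cc)
        if L2 > 1.0 + 1e-12:
            continue
        if best is None or L2 > best.L2 + 1e-12:
            best = BalancedDesign(ratio=R, L2=L2)
    if best is None:
        raise NoAdmissibleDesignError(
            f"no candidate ratio admits L2 <= 1 at T={T} min"
        )
    return best
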