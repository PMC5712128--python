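"""Kinetic parametrization of the toggle switch.

All rate constants are per second.  Bimolecular rates (repressor–promoter
binding ``r_g`` and dimer formation ``k_d``) scale inversely with the scaled
cell volume; transcription ``k_m`` scales inversely with the DNA content per
cell S(T) (total transcription is limited by RNA polymerase, not template);
translation ``k_p`` is proportional to the growth rate times the birth
volume (keeping protein concentration growth-rate independent).  Protein
monomers are not degraded — they are lost only by dilution at division.

Default values (the *scales* are the numerators of the volume/S-dependent
laws):

========================  =========================  =====================
quantity                  law                        default scale
========================  =========================  =====================
gene activation k_g       constant                   2e-3 /s
gene repression r_g       r_g_scale / V(t,T)         5, 20 or 35 × 1e-4
transcription k_m(T)      k_m_scale / S(T)           5e-3 /s
translation k_p(T)        2 V0(T) (40/T) k_p_scale   1e-2 /s
dimerization k_d          k_d_scale / V(t,T)         1e-3
dimer dissociation r_d    constant                   0.1 /s
mRNA degradation r_m      constant                   3e-3 /s
protein degradation       —                          0 (dilution only)
========================  =========================  =====================
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .cell_cycle import (
    CellCycleParams,
    VolumeModel,
    genome_average_copies,
    volume_at_age,
)

__all__ = [
    "RateConstants",
    "EffectiveRates",
    "RG_LABELS",
    "label_to_rg",
    "effective_rates",
    "transcription_rate",
    "translation_rate",
]

#: Published repression settings: the label used in the results equals the
#: numerator of r_g(t,T) = r_g_scale / V(t,T).
RG_LABELS: tuple[float, ...] = (5e-4, 20e-4, 35e-4)


@dataclass(frozen=True)
class RateConstants:
    """Volume- and T-independent kinetic constants (see module docstring)."""

    k_g: float = 2e-3
    r_g_scale: float = 20e-4
    k_m_scale: float = 5e-3
    k_p_scale: float = 1e-2
    k_d_scale: float = 1e-3
    r_d: float = 0.1
    r_m: float = 3e-3

    def __post_init__(self) -> None:
        for name in ("k_g", "r_g_scale", "k_m_scale", "k_p_scale", "k_d_scale", "r_d", "r_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be non-negative")

    def perturbed(self, name: str, factor: float) -> "RateConstants":
        """Return a copy with one constant multiplied by ``factor``."""
        return replace(self, **{name: getattr(self, name) * factor})


@dataclass(frozen=True)
class EffectiveRates:
    """Concrete per-second rates at a given cell age / doubling time."""

    k_g: float
    r_g: float
    k_m: float
    k_p: float
    k_d: float
    r_d: float
    r_m: float
    volume: float
    S: float


def label_to_rg(label: float) -> float:
    """Map a published repression setting (0, 0.0005, 0.002, 0.0035 or any
    non-negative number) to the numerator of ``r_g(t,T) = r_g_scale / V``.

    The published labels equal the numerators, so this is the identity on
    valid input; ``0`` means the two genes are uncoupled.
    """
    if label < 0:
        raise ValueError("repression setting must be non-negative")
    return float(label)


def transcription_rate(rc: RateConstants, cc: CellCycleParams) -> float:
    """k_m(T) = k_m_scale / S(T) per active gene copy, in 1/s."""
    return rc.k_m_scale / genome_average_copies(cc)


def translation_rate(rc: RateConstants, cc: CellCycleParams) -> float:
    """k_p(T) = 2 V0(T) (40/T) k_p_scale per mRNA, in 1/s."""
    vm = VolumeModel(cc)
    return 2.0 * vm.V0 * (40.0 / cc.T) * rc.k_p_scale


def effective_rates(rc: RateConstants, cc: CellCycleParams, t: float) -> EffectiveRates:
    """Evaluate all rates at cell age ``t`` (minutes).

    Bimolecular rates are divided by the current volume V(t, T); k_m by the
    genome-average copy number S(T).
    """
    vm = VolumeModel(cc)
    V = volume_at_age(vm, t)
    return EffectiveRates(
        k_g=rc.k_g,
        r_g=rc.r_g_scale / V,
        k_m=transcription_rate(rc, cc),
        k_p=translation_rate(rc, cc),
        k_d=rc.k_d_scale / V,
        r_d=rc.r_d,
        r_m=rc.r_m,
        volume=V,
        S=genome_average_copies(cc),
    )
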