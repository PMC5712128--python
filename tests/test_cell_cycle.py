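"""Gene-dosage model: copy-number schedule, cycle averages, design calculator."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from growthtoggle.cell_cycle import (
    CellCycleParams,
    LocusSpec,
    NoAdmissibleDesignError,
    VolumeModel,
    balanced_locus,
    best_balanced_design,
    copies_at_age,
    dosage_ratio,
    genome_average_copies,
    genome_average_copies_approx,
    mean_copies,
    mean_copies_approx,
    replication_age,
    volume_at_age,
)


def schedule_oracle(L: float, n_inserted: int, T: float, t: float,
                    C: float = 40.0, D: float = 20.0) -> int:
    """Independent copy count from the replication scheme itself.

    A replication round destined for the division at age k*T passes the
    locus at age k*T - (C*(1-L) + D); every passage doubles the copy
    count, so the count at age t is n * 2**(number of passages already
    behind us among future divisions).
    """
    x = C * (1.0 - L) + D
    k = 1
    passages = 0
    while k * T - x <= t + 1e-9:
        passages += 1
        k += 1
    return n_inserted * 2 ** passages


S_GRID = np.arange(20.0, 121.0, 1.0)


class TestCopiesAtAge:
    @pytest.mark.parametrize("L, n, T, t, expected", [
        (0.0, 1, 20.0, 5.0, 8),     # eight ori copies throughout at T=20
        (0.0, 1, 20.0, 19.9, 8),
        (1.0, 1, 20.0, 5.0, 2),     # two ter copies throughout at T=20
        (0.0, 1, 40.0, 10.0, 2),
        (0.0, 1, 40.0, 30.0, 4),
        (1.0, 1, 40.0, 30.0, 2),
        (0.0, 1, 120.0, 30.0, 1),
        (0.0, 1, 120.0, 90.0, 2),
    ])
    def test_printed_and_derived_examples(self, L, n, T, t, expected):
        cc = CellCycleParams(T=T)
        assert copies_at_age(LocusSpec(L, n), cc, t) == expected

    @given(st.floats(0.0, 1.0), st.integers(1, 4),
           st.floats(20.0, 120.0), st.floats(0.0, 0.999))
    def test_matches_replication_scheme_oracle(self, L, n, T, frac):
        t = frac * T
        cc = CellCycleParams(T=T)
        assert copies_at_age(LocusSpec(L, n), cc, t) == schedule_oracle(L, n, T, t)

    def test_single_doubling_and_division_consistency(self):
        # piecewise constant with one doubling per cycle (or none), and
        # halving the pre-division count recovers the birth count
        for T in (23.0, 40.0, 61.0, 97.0):
            cc = CellCycleParams(T=T)
            for L in (0.0, 0.3, 1.0):
                locus = LocusSpec(L, 1)
                ages = np.linspace(0.0, T, 500, endpoint=False)
                counts = np.array([copies_at_age(locus, cc, a) for a in ages])
                n_jumps = (np.diff(counts) != 0).sum()
                assert n_jumps in (0, 1)
                if n_jumps == 1:
                    assert counts[-1] == 2 * counts[0]
                assert counts[-1] // (2 if n_jumps else 1) == counts[0]

    def test_domain_errors(self):
        cc = CellCycleParams(T=40.0)
        with pytest.raises(ValueError):
            copies_at_age(LocusSpec(0.0, 1), cc, 40.0)
        with pytest.raises(ValueError):
            copies_at_age(LocusSpec(0.0, 1), cc, -1.0)
        with pytest.raises(ValueError):
            LocusSpec(1.5, 1)


class TestCycleAverages:
    @pytest.mark.parametrize("L, n, T, expected", [
        (0.0, 1, 20.0, 8.0),    # S_ori(20)
        (0.0, 1, 40.0, 3.0),    # S_ori(40) = 120/T
        (0.0, 1, 90.0, 1.0 + 60.0 / 90.0),
        (1.0, 1, 40.0, 1.5),    # S_ter = 1 + 20/T
        (1.0, 2, 40.0, 3.0),
    ])
    def test_known_averages(self, L, n, T, expected):
        assert mean_copies(LocusSpec(L, n), CellCycleParams(T=T)) == pytest.approx(expected)

    def test_time_average_of_instantaneous_equals_mean(self):
        # uniform cell-age average of copies_at_age reproduces the printed
        # cycle averages on a 1-min grid of doubling times
        for T in S_GRID:
            cc = CellCycleParams(T=float(T))
            for L, expect in ((0.0, None), (1.0, None)):
                locus = LocusSpec(L, 1)
                n0 = copies_at_age(locus, cc, 0.0)
                rep = replication_age(locus, cc)
                exact = n0 * (1.0 + (T - rep) / T)
                assert mean_copies(locus, cc) == pytest.approx(exact, abs=1e-9)
            s_ori = (240.0 / T - 4 if T < 30 else
                     120.0 / T if T < 60 else 1 + 60.0 / T)
            assert mean_copies(LocusSpec(0.0, 1), cc) == pytest.approx(s_ori, abs=1e-9)
            assert mean_copies(LocusSpec(1.0, 1), cc) == pytest.approx(1 + 20.0 / T, abs=1e-9)

    def test_numeric_time_average_intermediate_locus(self):
        cc = CellCycleParams(T=55.0)
        locus = LocusSpec(0.4, 3)
        ages = (np.arange(200000) + 0.5) * (55.0 / 200000)
        numeric = np.mean([copies_at_age(locus, cc, a) for a in ages])
        assert mean_copies(locus, cc) == pytest.approx(numeric, rel=1e-4)

    @pytest.mark.parametrize("L, T, expected", [
        (1.0, 33.0, 1 + 20.0 / 33.0),          # exact at ter
        (0.0, 40.0, 3.0),                       # equals the exact value here
        (0.0, 20.0, 8.0),
    ])
    def test_approximation_values(self, L, T, expected):
        assert mean_copies_approx(LocusSpec(L, 1), CellCycleParams(T=T)) == \
            pytest.approx(expected)

    def test_approximation_within_ten_percent(self):
        for T in S_GRID:
            cc = CellCycleParams(T=float(T))
            for L in (0.0, 1.0):
                locus = LocusSpec(L, 1)
                assert mean_copies_approx(locus, cc) == pytest.approx(
                    mean_copies(locus, cc), rel=0.10)


class TestGenomeAverage:
    def test_branch_values(self):
        assert genome_average_copies(CellCycleParams(T=120.0)) == pytest.approx(4.0 / 3.0)
        assert genome_average_copies(CellCycleParams(T=40.0)) == pytest.approx(2.125)
        assert genome_average_copies(CellCycleParams(T=25.0)) == pytest.approx(
            9 * 25 / 80 + 175 / 25 - 6.5)

    def test_approximation_close(self):
        cc = CellCycleParams(T=40.0)
        appr = genome_average_copies_approx(cc)
        assert appr == pytest.approx(1.5 / math.log(2), rel=1e-12)
        assert appr == pytest.approx(genome_average_copies(cc), rel=0.05)


class TestDosageRatioAndDesign:
    @pytest.mark.parametrize("L1, L2, T, expected", [
        (0.0, 1.0, 40.0, 2.0),
        (0.0, 1.0, 20.0, 4.0),
        (0.3, 0.3, 77.0, 1.0),
    ])
    def test_ratio_examples(self, L1, L2, T, expected):
        assert dosage_ratio(L1, L2, CellCycleParams(T=T)) == pytest.approx(expected)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(20.0, 120.0))
    def test_ratio_reciprocity(self, L1, L2, T):
        cc = CellCycleParams(T=T)
        assert dosage_ratio(L1, L2, cc) * dosage_ratio(L2, L1, cc) == pytest.approx(1.0)

    @pytest.mark.parametrize("R, T, expected", [
        (0.5, 40.0, 1.0),
        (0.8, 120.0, 3 * math.log2(1.25)),
        (1.0, 77.0, 0.0),
    ])
    def test_balanced_locus_values(self, R, T, expected):
        assert balanced_locus(R, CellCycleParams(T=T)) == pytest.approx(expected)

    @given(st.floats(0.01, 1.0), st.floats(20.0, 120.0))
    def test_balanced_locus_inverts_dosage_ratio(self, R, T):
        cc = CellCycleParams(T=T)
        L2 = balanced_locus(R, cc)
        if L2 <= 1.0:
            assert dosage_ratio(0.0, L2, cc) == pytest.approx(1.0 / R)

    def test_best_design_enumeration(self):
        assert best_balanced_design(20.0) == pytest.approx((0.25, 1.0))
        r, L2 = best_balanced_design(120.0)
        assert r == pytest.approx(0.8)
        assert L2 == pytest.approx(0.9658, abs=1e-3)

    def test_best_design_admissible_everywhere(self):
        # every supported doubling time admits a balanced design with the
        # competing genes separated by more than 0.7 ori-ter distances
        best = min(best_balanced_design(float(T)).L2
                   for T in np.linspace(20.0, 120.0, 2001))
        assert best > 0.7

    def test_no_admissible_design(self):
        with pytest.raises(NoAdmissibleDesignError):
            best_balanced_design(120.0, candidate_ratios=[0.25])


class TestVolume:
    @pytest.mark.parametrize("T, v0", [(40.0, 0.5), (20.0, 1.0)])
    def test_birth_volume(self, T, v0):
        assert VolumeModel(CellCycleParams(T=T)).V0 == pytest.approx(v0)

    @given(st.floats(20.0, 120.0), st.floats(0.0, 1.0))
    def test_doubling_law(self, T, frac):
        cc = CellCycleParams(T=T)
        vm = VolumeModel(cc)
        v = volume_at_age(vm, frac * T)
        assert vm.V0 <= v + 1e-12
        assert v == pytest.approx(vm.V0 * 2 ** frac)
        assert volume_at_age(vm, T) == pytest.approx(2 * vm.V0)
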