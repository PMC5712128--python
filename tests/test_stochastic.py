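"""Stochastic simulator: propensities, replication/division semantics,
bookkeeping audits and reproducibility."""

import numpy as np
import pytest

from growthtoggle.cell_cycle import CellCycleParams, copies_at_age, replication_age
from growthtoggle.model_params import RateConstants, effective_rates
from growthtoggle.stochastic import (
    SimulationConfig,
    StochasticCellState,
    advance,
    first_passage_time,
    initial_state,
    partition_at_division,
    propensities,
    replicate_locus,
    run_ensemble,
    simulate_frozen,
    simulate_lineage,
)

RC = RateConstants(r_g_scale=20e-4)
CC40 = CellCycleParams(T=40.0)


def make_state(gs_o=(1, 1), gs_t=(1, 1), **counts):
    return StochasticCellState(np.array(gs_o, np.int8), np.array(gs_t, np.int8), **counts)


class TestPropensities:
    def test_no_free_dimer_no_repression(self):
        er = effective_rates(RC, CC40, 0.0)
        s = make_state(D_ter=0, D_ori=5)
        props = propensities(s, er)
        assert props[1] == 0.0                        # repress_ori needs D_ter
        assert props[3] == pytest.approx(er.r_g * 5 * 2)

    def test_single_monomer_cannot_dimerize(self):
        er = effective_rates(RC, CC40, 0.0)
        s = make_state(P_ori=1, P_ter=3)
        props = propensities(s, er)
        assert props[10] == 0.0                       # p(p-1) with p = 1
        assert props[11] == pytest.approx(er.k_d * 3 * 2)

    def test_transcription_per_active_copy(self):
        er = effective_rates(RC, CC40, 0.0)
        s = make_state(gs_o=(1, 0), gs_t=(0, 0))
        props = propensities(s, er)
        assert props[4] == pytest.approx(5e-3 / 2.125)  # k_m(40), one active copy
        assert props[5] == 0.0

    def test_no_protein_degradation_channel(self):
        # silence gene switching and expression: nothing but dimerization
        # can change a monomer count (proteins decay only by dilution)
        rc = RateConstants(r_g_scale=0.0, k_m_scale=0.0)
        er = effective_rates(rc, CC40, 0.0)
        s = make_state(P_ori=100, P_ter=100)
        props = propensities(s, er)
        assert np.flatnonzero(props).tolist() == [10, 11]


class TestReplicationAndDivision:
    def test_replication_releases_repressors_and_activates(self):
        s = make_state(gs_o=(1, 0), gs_t=(1, 1), D_ter=3)
        new = replicate_locus(s, "ori")
        assert new.n_ori == 4 and new.active_ori == 4
        assert new.D_ter == 4                          # bound dimer released
        assert new.n_ter == 2                          # other locus untouched

    def test_partition_keeps_one_per_pair(self, rng):
        s = make_state(gs_o=(1, 0, 1, 1), gs_t=(1, 1, 0, 0), D_ori=10, D_ter=8)
        d = partition_at_division(s, rng)
        assert d.n_ori == 2 and d.n_ter == 2
        assert d.age == 0.0
        assert 0 <= d.D_ori <= 10 and 0 <= d.D_ter <= 8

    def test_partition_zero_molecules_stay_zero(self, rng):
        s = make_state()
        d = partition_at_division(s, rng)
        assert (d.M_ori, d.P_ori, d.D_ori) == (0, 0, 0)

    def test_binomial_partition_mean_half(self, rng):
        s = make_state(M_ori=40, M_ter=60, P_ori=100, P_ter=80, D_ori=100, D_ter=50)
        kept = np.array([[getattr(partition_at_division(s, rng), k)
                          for k in ("M_ori", "M_ter", "P_ori", "P_ter", "D_ori", "D_ter")]
                         for _ in range(10_000)], dtype=float)
        totals = np.array([40, 60, 100, 80, 100, 50], dtype=float)
        frac = kept / totals
        se = np.sqrt(0.25 / totals / 10_000)           # SE of the mean fraction
        assert np.all(np.abs(frac.mean(axis=0) - 0.5) < 3 * se)

    def test_partition_bound_dimers_follow_discarded_copies(self, rng):
        # with every copy repressed, the daughter keeps exactly half the
        # bound dimers (one per kept copy); none appear in the free pool
        s = make_state(gs_o=(0, 0, 0, 0), gs_t=(1, 1), D_ter=0)
        d = partition_at_division(s, rng, replicate_at_division=(False, True))
        assert d.n_ori == 2 and d.active_ori == 0
        assert d.D_ter == 0


class TestAdvance:
    def test_scheduled_replication_interrupts(self, rng):
        # at T=40 both loci replicate at age 20; start just below with one
        # repressed ori copy and no reactions possible
        rc0 = RateConstants(r_g_scale=0.0, k_g=0.0, k_m_scale=0.0,
                            k_d_scale=0.0, r_d=0.0)
        s = make_state(gs_o=(1, 0), gs_t=(1, 1), D_ter=2)
        s.age = 19.5
        new, event = advance(s, rc0, CC40, rng)
        assert event == "replication"
        assert new.age == pytest.approx(20.0)
        assert new.n_ori == 4 and new.active_ori == 4
        assert new.D_ter == 3
        assert new.n_ter == 4 and new.active_ter == 4

    def test_zero_propensity_jumps_to_division(self, rng):
        rc0 = RateConstants(r_g_scale=0.0, k_g=0.0, k_m_scale=0.0)
        s = make_state(gs_o=(1, 1, 1, 1), gs_t=(1, 1, 1, 1))
        s.age = 25.0
        new, event = advance(s, rc0, CC40, rng)
        assert event == "division"
        assert new.age == 0.0
        assert new.n_ori == 2 and new.n_ter == 2

    def test_reaction_updates_molecules(self, rng):
        rc = RateConstants(r_g_scale=0.0, k_g=0.0, k_m_scale=1.0)  # transcription dominates
        s = make_state()
        new, event = advance(s, rc, CC40, rng)
        assert event.startswith("transcribe")
        assert new.M_ori + new.M_ter == 1


class TestLineage:
    def test_identical_seeds_identical_trajectories(self):
        cfg = SimulationConfig(T=40.0, rc=RC, t_end_h=3.0, seed=42, record_dt_s=120.0)
        a = simulate_lineage(cfg)
        b = simulate_lineage(cfg)
        assert a.samples.equals(b.samples)
        assert np.array_equal(a.counters, b.counters)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            simulate_lineage(SimulationConfig(T=40.0, rc=RC, t_end_h=1.0))

    def test_copy_counts_follow_schedule_and_volume_bounded(self):
        cfg = SimulationConfig(T=35.0, rc=RC, t_end_h=6.0, seed=9, record_dt_s=61.0)
        traj = simulate_lineage(cfg)
        cc = cfg.cc
        v0 = 0.5 * traj.samples["V"].iloc[0] / 2 ** (traj.samples["age_s"].iloc[0] / cc.T_seconds) * 2
        for _, row in traj.samples.iterrows():
            age_min = row["age_s"] / 60.0
            assert row["V"] <= 2 * v0 + 1e-9
            for col, locus in (("N_ori", cfg.ori), ("N_ter", cfg.ter)):
                rep = replication_age(locus, cc)
                if age_min >= cc.T - 1e-6 or abs(age_min - rep) < 1e-6:
                    continue   # pre-event convention at scheduled instants
                assert row[col] == copies_at_age(locus, cc, age_min)

    def test_dimer_bookkeeping_balances(self):
        cfg = SimulationConfig(T=30.0, rc=RateConstants(r_g_scale=35e-4),
                               t_end_h=40.0, seed=5, record_dt_s=0.0)
        traj = simulate_lineage(cfg)
        c = traj.counters
        s0 = initial_state(cfg).to_counts()
        s1 = traj.final_state.to_counts()
        # free-pool ledger for each dimer species
        d_t = s0[9] + c[1] - c[3] - c[4] + c[6] + c[8] - c[11]
        d_o = s0[8] + c[0] - c[2] - c[5] + c[7] + c[9] - c[10]
        assert d_t == s1[9]
        assert d_o == s1[8]
        # free + bound conservation against creation/destruction/losses
        assert s1[9] + (s1[0] - s1[1]) == (s0[9] + (s0[0] - s0[1])
                                           + c[1] - c[3] - c[11] - c[13])
        assert s1[8] + (s1[2] - s1[3]) == (s0[8] + (s0[2] - s0[3])
                                           + c[0] - c[2] - c[10] - c[12])

    def test_symmetric_design_balanced_at_T40(self):
        cfg = SimulationConfig(T=40.0, rc=RateConstants(r_g_scale=0.0),
                               t_end_h=30.0, burn_in_h=5.0, seed=77, record_dt_s=600.0)
        es = run_ensemble(cfg, 60)
        assert es.R_protein == pytest.approx(1.0, abs=3 * es.ratio_se())

    def test_first_passage_none_when_uncoupled_short(self):
        cfg = SimulationConfig(T=40.0, rc=RateConstants(r_g_scale=35e-4),
                               t_end_h=0.05, seed=3, init="ori_dominant",
                               record_dt_s=0.0)
        assert first_passage_time(cfg, "ori_to_ter") is None


class TestFrozenMode:
    def test_mrna_birth_death_poisson(self):
        # one active copy, transcription/decay only: stationary Poisson(k/r)
        s0 = make_state(gs_o=(1,), gs_t=(1,))
        rates = {"k_m": 0.4, "r_m": 0.1}
        samples, state, sums, counters = simulate_frozen(
            rates, volume=1.0, state0=s0, t_end_s=2.0e5, seed=12,
            record_dt_s=5.0, burn_in_s=500.0)
        m = samples[:, 6]
        assert m.mean() == pytest.approx(4.0, rel=0.05)
        assert m.var() == pytest.approx(4.0, rel=0.15)

    def test_no_divisions_or_replications(self):
        s0 = make_state(M_ori=2, P_ori=10)
        samples, state, sums, counters = simulate_frozen(
            {"k_d_scale": 0.01, "r_d": 0.1}, volume=1.0, state0=s0,
            t_end_s=1e4, seed=1, record_dt_s=100.0)
        assert counters[14] == 0
        assert (samples[:, 2] == 2).all()   # copy counts frozen
        assert (samples[:, 12] == 1.0).all()
        # dimerization conserves total monomer equivalents
        assert state[6] + 2 * state[8] == 10
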