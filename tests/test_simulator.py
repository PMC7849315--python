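"""Stepping, events, mass ledger, and summaries of the multicellular model."""

import numpy as np
import pytest

from rootzone import ModelParameters, NitrogenRegime, initial_state, run, \
    step, summarize
from rootzone.model import CORTEX, EPIDERMIS
from rootzone.simulator import StabilityError, _ode_step, _pack, \
    maybe_divide, maybe_transition, steady_state_profile


@pytest.fixture(scope="module")
def short_run():
    # shared ammonium run reaching the division-active steady state; the
    # middle snapshot lets tests isolate steady-state division events
    return run(ModelParameters(), NitrogenRegime.constant(0), horizon=300.0,
               snapshot_every=150.0)


class TestStep:
    def test_step_matches_rhs_for_small_dt(self, params, ammonium):
        state = initial_state(params)
        state.epidermis.A[:] = 0.5
        state.cortex.A[:] = 0.2
        state.epidermis.Pm["apical"][:] = 5.0
        dt = 1e-6
        new = step(state, dt, ammonium, "B", params)
        from rootzone.simulator import _rhs
        k = _rhs(state, 0, np.where(
            np.arange(1, params.window + 1) < params.z, params.s1,
            params.s2), params)
        # (step - state)/dt approximates the rhs
        approx = (new.epidermis.A - state.epidermis.A) / dt
        assert np.allclose(approx, k[0], rtol=1e-3, atol=1e-4)

    def test_stability_bound_enforced_with_pool_name(self, params, ammonium):
        state = initial_state(params)
        state.epidermis.Pm["apical"][:] = 1e4   # makes auxin ultra-stiff
        state.epidermis.A[:] = 1.0
        with pytest.raises(StabilityError, match="A"):
            step(state, 0.01, ammonium, "B", params)

    def test_euler_and_rk4_agree_at_fine_steps(self, params, ammonium):
        s_rk = initial_state(params)
        s_eu = initial_state(params)
        src = np.where(np.arange(1, params.window + 1) < params.z,
                       params.s1, params.s2)
        for _ in range(2000):
            _ode_step(s_rk, 5e-3, 0, src, params, "rk4")
        for _ in range(10000):
            _ode_step(s_eu, 1e-3, 0, src, params, "euler")
        for fa, fb in ((s_rk.epidermis, s_eu.epidermis),
                       (s_rk.cortex, s_eu.cortex)):
            assert np.allclose(fa.A, fb.A, rtol=1e-3, atol=1e-8)
            assert np.allclose(fa.PINc, fb.PINc, rtol=1e-3)

    def test_one_step_preserves_non_negativity(self, params, ammonium, rng):
        state = initial_state(params)
        for fa in (state.epidermis, state.cortex):
            fa.A = rng.uniform(0, 5, fa.n)
            fa.PINc = rng.uniform(0, 400, fa.n)
            for f in fa.Pm:
                fa.Pm[f] = rng.uniform(0, 30, fa.n)
            fa.DIV = rng.uniform(0, 3, fa.n)
        new = step(state, 1e-3, ammonium, "B", params)
        for fa in (new.epidermis, new.cortex):
            assert np.all(fa.A >= 0) and np.all(fa.PINc >= 0)
            assert all(np.all(v >= 0) for v in fa.Pm.values())
            assert np.all(fa.DIV >= 0) and np.all(fa.L > 0)


class TestEvents:
    def test_transition_threshold_closed_and_irreversible(self, params):
        state = initial_state(params)
        state.epidermis.A[:] = 1.0
        state.epidermis.A[-1] = 10.0       # sets maxA
        thr_val = 10.0 * params.A_thr_ammonium
        state.epidermis.A[5] = thr_val      # exactly at threshold -> moves
        state.epidermis.A[6] = thr_val - 1e-9   # just below -> stays
        maybe_transition(state, 0, params)
        assert state.epidermis.elong[5]
        assert not state.epidermis.elong[6]
        # irreversible even if auxin later drops
        state.epidermis.A[5] = 0.0
        maybe_transition(state, 0, params)
        assert state.epidermis.elong[5]

    def test_regime_raises_required_auxin(self, params):
        # a relative level sufficient on ammonium may be insufficient on
        # nitrate (the elongation threshold is higher there)
        rel = (params.A_thr_ammonium + params.A_thr_nitrate) / 2
        for N, expect in ((0, True), (1, False)):
            state = initial_state(params)
            state.epidermis.A[:] = 0.01
            state.epidermis.A[-1] = 10.0
            state.epidermis.A[10] = rel * 10.0
            maybe_transition(state, N, params)
            assert bool(state.epidermis.elong[10]) is expect

    def test_division_requires_both_thresholds(self, params):
        state = initial_state(params)
        state.epidermis.DIV[3] = params.DIV_thr + 1
        state.epidermis.L[3] = params.min_div_length - 0.5
        assert maybe_divide(state, params) == 0
        state.epidermis.L[3] = params.min_div_length
        assert maybe_divide(state, params) == 1

    def test_division_conserves_amounts_and_shifts_indices(self, params):
        state = initial_state(params)
        fa = state.epidermis
        fa.A[:] = np.arange(1.0, fa.n + 1)
        fa.Pm["apical"][:] = 2.0
        fa.DIV[4] = params.DIV_thr
        fa.L[4] = 12.0
        total_A = fa.A.sum()
        total_pin = fa.total_membrane_pin().sum() + fa.PINc.sum()
        tagged = fa.A[10]
        maybe_divide(state, params)
        fa = state.epidermis
        assert fa.n == params.window            # window advection trims
        # daughters split everything 50/50 and reset DIV
        assert fa.A[4] == fa.A[5] == pytest.approx(5.0 / 2)
        assert fa.DIV[4] == fa.DIV[5] == 0.0
        assert fa.L[4] == fa.L[5] == pytest.approx(6.0)
        # shootward cells shifted by one
        assert fa.A[11] == tagged
        # conservation: only the advected last cell left the file
        dropped = state.ledger["advected"]
        assert fa.A.sum() + dropped == pytest.approx(total_A)
        assert state.division_log[(EPIDERMIS, 5)] == 1

    def test_division_log_orders_candidates_from_qc(self, params):
        state = initial_state(params)
        fa = state.epidermis
        for k in (2, 7):
            fa.DIV[k] = params.DIV_thr
            fa.L[k] = 12.0
        maybe_divide(state, params)
        # the second candidate's logged index accounts for the first split
        assert state.division_log == {(EPIDERMIS, 3): 1, (EPIDERMIS, 9): 1}


class TestRun:
    def test_zero_sources_decay_to_trivial_state(self):
        p = ModelParameters(s1=0.0, s2=0.0)
        traj = run(p, NitrogenRegime.constant(0), horizon=80.0)
        st = traj.final
        assert st.total_auxin() < 1e-6
        assert np.all(~st.epidermis.elong)
        assert st.epidermis.L.max() < 10.5      # growth stalled

    def test_deterministic_given_config(self, params):
        a = run(params, NitrogenRegime.constant(0), horizon=30.0)
        b = run(params, NitrogenRegime.constant(0), horizon=30.0)
        assert np.array_equal(a.final.epidermis.A, b.final.epidermis.A)
        assert np.array_equal(a.final.epidermis.L, b.final.epidermis.L)
        assert a.final.ledger == b.final.ledger

    def test_ledger_closes_through_events(self, short_run):
        # ~10^4 integration substeps with divisions and advection
        assert short_run.final.ledger_residual() < 1e-8

    def test_numba_and_numpy_paths_agree(self, params, ammonium):
        a = run(params, ammonium, horizon=1.0, use_numba=True)
        b = run(params, ammonium, horizon=1.0, use_numba=False)
        assert np.allclose(a.final.epidermis.A, b.final.epidermis.A,
                           rtol=1e-9, atol=1e-12)
        assert np.allclose(a.final.cortex.PINc, b.final.cortex.PINc,
                           rtol=1e-9)

    def test_regime_switch_rebalances_lateral_pin(self, params):
        reg = NitrogenRegime([(0.0, 0), (40.0, 1)])
        traj = run(params, reg, horizon=80.0, snapshot_every=40.0)
        before = traj.snapshots[1]      # t=40, still ammonium history
        after = traj.final
        assert before.cortex.Pm["outer"].sum() == pytest.approx(0.0, abs=1e-6)
        assert after.cortex.Pm["outer"].sum() > 1.0


class TestSummarize:
    def test_profile_and_onset_fields(self, short_run):
        s = summarize(short_run)
        assert set(s.onset_index) == {EPIDERMIS, CORTEX}
        assert s.onset_index[EPIDERMIS] >= 1
        assert len(s.profiles) == 2 * short_run.params.window
        assert s.synchrony_index == abs(s.onset_index[EPIDERMIS]
                                        - s.onset_index[CORTEX])

    def test_division_fractions_sum_to_one(self, short_run):
        s = summarize(short_run)
        assert s.division_fractions["fraction"].sum() == pytest.approx(1.0)

    def test_division_profile_unimodal_within_meristem(self, short_run):
        # steady-state division events (excluding the establishment phase)
        # peak inside the meristem and vanish beyond the elongation onset
        mid, final = short_run.snapshots[1], short_run.final
        delta = {k: v - mid.division_log.get(k, 0)
                 for k, v in final.division_log.items()
                 if v > mid.division_log.get(k, 0)}
        onset = summarize(final).onset_index[EPIDERMIS]
        epi = {i: c for (f, i), c in delta.items() if f == EPIDERMIS}
        total = sum(epi.values())
        assert total > 20
        beyond = sum(c for i, c in epi.items() if i > onset + 2)
        assert beyond / total < 0.1
        peak = max(epi, key=epi.get)
        assert 3 <= peak <= onset + 2

    def test_empty_trajectory_rejected(self, short_run):
        from rootzone.simulator import Trajectory
        empty = Trajectory([], False, short_run.params, short_run.regime, "B")
        with pytest.raises(ValueError):
            summarize(empty)

    def test_meristem_size_is_length_to_first_elongating_cell(self, params):
        state = initial_state(params)
        state.epidermis.elong[5] = True     # cells 1..5 meristematic
        state.epidermis.A[-1] = 1.0
        s = summarize(state)
        assert s.meristem_cells[EPIDERMIS] == 5
        assert s.meristem_size_um[EPIDERMIS] == pytest.approx(
            state.epidermis.L[:5].sum())


class TestInitializationRobustness:
    def test_two_naive_initializations_converge_together(self, params):
        t1 = run(params, NitrogenRegime.constant(0), horizon=250.0)
        # different naive state: longer cells, less cytoplasmic PIN2
        alt = initial_state(params, length=12.0,
                            pinc=0.5 * params.m_p / params.d_p)
        t2 = run(params, NitrogenRegime.constant(0), horizon=250.0, init=alt)
        a, b = summarize(t1), summarize(t2)
        assert abs(a.onset_index[EPIDERMIS] - b.onset_index[EPIDERMIS]) <= 1
        ta = a.profiles.query("file=='epidermis'")["A"].sum()
        tb = b.profiles.query("file=='epidermis'")["A"].sum()
        assert ta == pytest.approx(tb, rel=0.05)


class TestSteadyStateProfile:
    def test_matches_dynamic_integration_without_growth(self):
        # freeze growth/division so the dynamic run has the same attractor
        # as the static-file subsystem fixed point
        p = ModelParameters(k_l_meristem=0.0, k_l_elongation=0.0,
                            k_v0=0.0, DIV_thr=1e9)
        traj = run(p, NitrogenRegime.constant(1), horizon=900.0)
        prof = steady_state_profile(p, N=1)
        for tissue in (EPIDERMIS, CORTEX):
            dyn = traj.final.file(tissue)
            stat = prof[tissue]
            assert np.allclose(dyn.A, stat["A"], rtol=2e-2, atol=1e-4)
            assert np.allclose(dyn.Pm["apical"], stat["PINm_apical"],
                               rtol=2e-2)

    def test_literal_equations_have_no_membrane_steady_state(self):
        with pytest.raises(ValueError, match="literal"):
            steady_state_profile(ModelParameters(literal_equations=True))
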