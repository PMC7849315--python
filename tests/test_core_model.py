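"""Per-cell dynamical rules: frozen examples, limits, and properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootzone import Cell, ModelParameters, logistic
from rootzone.model import CORTEX, EPIDERMIS, EXCHANGE_FACE, SourceConfig, \
    auxin_rhs, auxin_source, division_factor_rhs, growth_rhs, \
    pin2_cytoplasm_rhs, pin2_membrane_rhs, pin2_trafficking_rate
from rootzone.simulator import steady_state_profile


class TestLogistic:
    def test_symmetry_at_zero(self):
        assert logistic(0.0) == 0.5

    def test_saturation(self):
        assert 1.0 - logistic(50.0) < 1e-20
        assert logistic(-50.0) < 1e-20
        assert np.isfinite(logistic(1000.0)) and np.isfinite(logistic(-1000.0))

    def test_trafficking_argument_evaluation(self):
        # tr_a*A + tr_i*i at A=0, i=10 with table coefficients
        p = ModelParameters()
        x = p.tr_a * 0.0 + p.tr_i * 10
        assert logistic(x) == pytest.approx(0.9525741268224334, abs=1e-12)

    @given(st.floats(-30, 30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_complementarity(self, x):
        assert logistic(-x) == pytest.approx(1 - logistic(x), abs=1e-12)

    @given(st.floats(-30, 29), st.floats(1e-3, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_increasing(self, x, dx):
        assert logistic(x + dx) > logistic(x)


class TestAuxinSource:
    def test_two_rate_variant_selects_by_z(self, params):
        assert auxin_source(5, EPIDERMIS, "B", params) == 8.36
        assert auxin_source(15, EPIDERMIS, "B", params) == 22.53
        # z = 10.6 is a continuous threshold on the 1-based index
        assert auxin_source(10, EPIDERMIS, "B", params) == 8.36
        assert auxin_source(11, EPIDERMIS, "B", params) == 22.53

    @pytest.mark.parametrize("variant", ["A", "B", "C"])
    def test_cortex_never_fed(self, params, variant):
        for i in (1, 7, 20):
            assert auxin_source(i, CORTEX, variant, params) == 0.0

    def test_uniform_variant_is_flat(self, params):
        src = SourceConfig("A", uniform_rate=5.0)
        rates = src.rates(40, params)
        assert np.all(rates == 5.0)

    def test_variant_d_requires_full_vector(self, params):
        src = SourceConfig("D", per_cell=np.ones(10))
        with pytest.raises(ValueError, match="window"):
            src.rates(40, params)

    def test_negative_spline_clamped(self, params, caplog):
        import rootzone.model as model_mod
        model_mod._CLAMP_WARNED.clear()
        src = SourceConfig("C", knots_x=[1, 7, 13, 19, 25],
                           knots_y=[10, -30, 10, 10, 10])
        with caplog.at_level("WARNING"):
            rates = src.rates(40, params)
        assert np.all(rates >= 0.0)
        assert "clamped" in caplog.text


def _integrate_scalar(rhs, y0, dt=0.05, t_end=2000.0):
    y = y0
    for _ in range(int(t_end / dt)):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * dt * k1)
        k3 = rhs(y + 0.5 * dt * k2)
        k4 = rhs(y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


class TestAuxinRhs:
    def test_isolated_cell_source_only(self, params, ammonium):
        cell = Cell(EPIDERMIS, 5)
        assert auxin_rhs(cell, [], ammonium, "B", params) == pytest.approx(8.36)

    def test_symmetric_neighbors_cancel(self, params, ammonium):
        cell = Cell(EPIDERMIS, 5, A=10.0)
        cell.PINm["apical"] = cell.PINm["basal"] = 2.0
        up = Cell(EPIDERMIS, 6, A=10.0)
        up.PINm["basal"] = 2.0
        dn = Cell(EPIDERMIS, 4, A=10.0)
        dn.PINm["apical"] = 2.0
        rate = auxin_rhs(cell, [(up, "apical", "basal"),
                                (dn, "basal", "apical")],
                         ammonium, "B", params)
        assert rate == pytest.approx(8.36 - params.d_a * 10.0, abs=1e-12)

    def test_isolated_steady_state_matches_closed_form(self, params, ammonium):
        cell = Cell(EPIDERMIS, 5)

        def rhs(a):
            cell.A = a
            return auxin_rhs(cell, [], ammonium, "B", params)

        a_star = _integrate_scalar(rhs, 0.0, dt=1.0, t_end=2000.0)
        assert a_star == pytest.approx(8.36 / 0.018, rel=1e-3)
        assert a_star == pytest.approx(464.444, rel=1e-3)

    def test_unknown_face_pairing_rejected(self, params, ammonium):
        cell = Cell(EPIDERMIS, 5)
        other = Cell(EPIDERMIS, 6)
        with pytest.raises(ValueError, match="face"):
            auxin_rhs(cell, [(other, "sideways", "basal")],
                      ammonium, "B", params)

    def test_outer_face_efflux_has_no_return(self, params, ammonium):
        # flux through the epidermal outer (soil-facing) face leaves the
        # system: rhs drops by exactly k_a*A*PINm_outer
        cell = Cell(EPIDERMIS, 5, A=3.0)
        base = auxin_rhs(cell, [], ammonium, "B", params)
        cell.PINm["outer"] = 4.0
        with_sink = auxin_rhs(cell, [], ammonium, "B", params)
        assert base - with_sink == pytest.approx(
            params.k_a * 3.0 * 4.0, abs=1e-12)


class TestPin2Cytoplasm:
    def test_synthesis_only_at_zero_pool(self, params):
        cell = Cell(EPIDERMIS, 5, PINc=0.0)
        assert pin2_cytoplasm_rhs(cell, params) == pytest.approx(30.49)

    @pytest.mark.parametrize("A,expected", [(0.0, 30.49 / 0.065),
                                            (100.0, 30.49 / (2 * 0.065))])
    def test_steady_state_closed_form(self, A, expected):
        # trafficking disabled: steady pool m_p / (d_p (1 + A/q_p))
        p = ModelParameters(tr_n=0.0, tr_wn=0.0)
        cell = Cell(EPIDERMIS, 5, A=A)

        def rhs(x):
            cell.PINc = x
            return pin2_cytoplasm_rhs(cell, p)

        star = _integrate_scalar(rhs, 0.0, dt=1.0, t_end=600.0)
        assert star == pytest.approx(expected, rel=1e-3)

    def test_literal_equations_drop_trafficking_debit(self, nitrate):
        p = ModelParameters(literal_equations=True)
        cell = Cell(EPIDERMIS, 10, PINc=100.0)
        literal = pin2_cytoplasm_rhs(cell, p, nitrate)
        conserving = pin2_cytoplasm_rhs(cell, p.replace(
            literal_equations=False), nitrate)
        total, _ = pin2_trafficking_rate(cell, 1, p)
        assert literal - conserving == pytest.approx(total)


class TestTrafficking:
    def test_ammonium_base_rate_and_no_lateral(self, params):
        cell = Cell(EPIDERMIS, 10, PINc=100.0)
        total, alloc = pin2_trafficking_rate(cell, 0, params)
        assert total == pytest.approx(100 * 0.13 * logistic(3.0))
        assert alloc[EXCHANGE_FACE[EPIDERMIS]] == 0.0
        assert alloc["apical"] == 1.0

    def test_nitrate_lateral_split(self, params):
        cell = Cell(CORTEX, 10, PINc=100.0)
        total, alloc = pin2_trafficking_rate(cell, 1, params)
        assert total == pytest.approx(100 * 0.246 * logistic(3.0))
        assert total == pytest.approx(23.43332, rel=1e-5)
        assert alloc[EXCHANGE_FACE[CORTEX]] == pytest.approx(0.60)
        assert alloc["apical"] == pytest.approx(0.40)

    def test_allocation_sums_to_one(self, params):
        for N in (0, 1):
            for file in (EPIDERMIS, CORTEX):
                _, alloc = pin2_trafficking_rate(Cell(file, 3, PINc=1.0),
                                                 N, params)
                assert sum(alloc.values()) == pytest.approx(1.0)


class TestMembrane:
    def test_pure_decay_without_delivery(self, params):
        cell = Cell(EPIDERMIS, 5, A=50.0, PINc=0.0)
        cell.PINm["apical"] = 10.0
        rate = pin2_membrane_rhs(cell, "apical", 0, params)
        assert rate == pytest.approx(-0.065 * (1 + 0.5) * 10.0)

    def test_steady_state_is_delivery_over_turnover(self, params):
        # constant delivery (PINc held fixed), A=0
        cell = Cell(CORTEX, 10, A=0.0, PINc=100.0)
        total, alloc = pin2_trafficking_rate(cell, 1, params)

        def rhs(x):
            cell.PINm["outer"] = x
            return pin2_membrane_rhs(cell, "outer", 1, params)

        star = _integrate_scalar(rhs, 0.0, dt=1.0, t_end=600.0)
        assert star == pytest.approx(alloc["outer"] * total / 0.065, rel=1e-3)

    def test_nitrate_switch_populates_lateral_face(self, params):
        cell = Cell(CORTEX, 10, A=0.0, PINc=100.0)
        rate_amm = pin2_membrane_rhs(cell, "outer", 0, params)
        rate_nit = pin2_membrane_rhs(cell, "outer", 1, params)
        assert rate_amm == 0.0
        assert rate_nit > 0.0


class TestDivisionFactor:
    def test_zero_state_is_stationary(self, params):
        assert division_factor_rhs(Cell(EPIDERMIS, 5, length=0.0), 1.0,
                                   params) == 0.0

    def test_linear_degradation_at_zero_auxin(self, params):
        cell = Cell(EPIDERMIS, 5, length=0.0, DIV=2.0)
        assert division_factor_rhs(cell, 1.0, params) == pytest.approx(
            -0.3 * 2.0)

    def test_reconstructed_synthesis_at_origin(self, params):
        cell = Cell(EPIDERMIS, 0, length=0.0, A=1.0)
        assert division_factor_rhs(cell, 1.0, params) == pytest.approx(
            1.5 * 20 / 2.0)

    def test_synthesis_decreases_with_index(self, params):
        vals = [division_factor_rhs(Cell(EPIDERMIS, i, length=0.0, A=1.0),
                                    1.0, params) for i in (1, 5, 10, 20)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_zero_maxA_rejected(self, params):
        with pytest.raises(ValueError, match="maxA"):
            division_factor_rhs(Cell(EPIDERMIS, 5), 0.0, params)


class TestGrowth:
    def test_no_growth_without_auxin(self, params):
        assert growth_rhs(Cell(EPIDERMIS, 5, A=0.0), params) == 0.0

    def test_no_growth_at_max_length(self, params):
        assert growth_rhs(Cell(EPIDERMIS, 5, A=5.0, length=200.0),
                          params) == 0.0

    def test_saturating_relative_growth_rate(self, params):
        cell = Cell(EPIDERMIS, 5, A=1e6, length=0.01)
        assert growth_rhs(cell, params) == pytest.approx(0.3 * 0.01, rel=1e-3)

    def test_overlong_cell_clamped_with_warning(self, params):
        cell = Cell(EPIDERMIS, 5, A=5.0, length=250.0)
        with pytest.warns(RuntimeWarning):
            assert growth_rhs(cell, params) == 0.0


class TestSteadyStateInvariants:
    def test_membrane_pin_monotone_in_trafficking_rates(self):
        def total_pin(**kw):
            prof = steady_state_profile(ModelParameters(**kw),
                                        N=kw.pop("N", 0))
            df = prof[EPIDERMIS]
            return (df.PINm_apical + df.PINm_basal + df.PINm_outer
                    + df.PINm_inner).to_numpy()

        lo = total_pin(tr_wn=0.08)
        hi = total_pin(tr_wn=0.20)
        assert np.all(hi >= lo)

    def test_lateral_face_share_equals_ln_times_N(self, params):
        prof = steady_state_profile(params, N=1)
        for tissue in (EPIDERMIS, CORTEX):
            df = prof[tissue]
            lateral = df[f"PINm_{EXCHANGE_FACE[tissue]}"]
            total = (df.PINm_apical + df.PINm_basal + df.PINm_outer
                     + df.PINm_inner)
            assert np.allclose(lateral / total, params.l_n, atol=1e-9)
        prof0 = steady_state_profile(params, N=0)
        for tissue in (EPIDERMIS, CORTEX):
            assert np.allclose(
                prof0[tissue][f"PINm_{EXCHANGE_FACE[tissue]}"], 0.0)

    def test_nitrate_raises_membrane_pin_at_every_position(self, params):
        # mirrors the higher PIN2 membrane signal observed on nitrate
        p0 = steady_state_profile(params, N=0)
        p1 = steady_state_profile(params, N=1)
        for tissue in (EPIDERMIS, CORTEX):
            t0 = (p0[tissue].PINm_apical + p0[tissue].PINm_basal
                  + p0[tissue].PINm_outer + p0[tissue].PINm_inner)
            t1 = (p1[tissue].PINm_apical + p1[tissue].PINm_basal
                  + p1[tissue].PINm_outer + p1[tissue].PINm_inner)
            assert np.all(t1.to_numpy()[:20] > t0.to_numpy()[:20])
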