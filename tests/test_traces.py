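"""Trace processing: P/N subtraction, steady-state extraction, IV building."""

import numpy as np
import pytest

from clcassay.synthdata import (
    GateModel,
    SessionSpec,
    coexpression_construct,
    simulate_cell,
    variant_library,
)
from clcassay.traces import (
    IVCurve,
    SweepSet,
    VoltageProtocol,
    build_iv,
    current_density,
    pn_subtract,
    steady_state,
)


def make_sweeps(current, protocol=None, corrected=False, **meta):
    protocol = protocol or VoltageProtocol()
    return SweepSet(protocol.time_s, current, protocol, dict(meta), corrected)


class TestVoltageProtocol:
    def test_default_ladder(self):
        p = VoltageProtocol()
        v = p.step_voltages_mv
        assert v[0] == 200 and v[-1] == -40 and v.size == 25
        assert np.all(np.diff(v) == -10)

    def test_rejects_misaligned_ladder(self):
        with pytest.raises(ValueError):
            VoltageProtocol(step_start_mv=200, step_end_mv=-45, step_delta_mv=-10)

    @pytest.mark.parametrize("pn", [0.0, 1.0, -0.2])
    def test_rejects_bad_pn_scale(self, pn):
        with pytest.raises(ValueError):
            VoltageProtocol(pn_scale=pn)

    def test_scaled_protocol_scales_all_voltages(self):
        p = VoltageProtocol().scaled(0.2)
        assert p.step_start_mv == 40.0
        assert np.allclose(p.step_voltages_mv, VoltageProtocol().step_voltages_mv * 0.2)


class TestSteadyState:
    def test_last_third_window_mean(self):
        # six-sample step segment [1..6]: window is samples {5, 6}
        p = VoltageProtocol(step_duration_ms=0.06, pre_ms=0.0, post_ms=0.0)
        assert p.n_step == 6
        cur = np.tile(np.array([1, 2, 3, 4, 5, 6], dtype=float)[:, None], (1, p.n_steps))
        ss = steady_state(make_sweeps(cur, p, corrected=True))
        assert np.allclose(ss, 5.5)

    def test_constant_segment_is_identity(self):
        p = VoltageProtocol()
        ss = steady_state(make_sweeps(np.full((p.n_samples, p.n_steps), 3.25), p, corrected=True))
        assert np.allclose(ss, 3.25)

    def test_settled_exponential_recovers_plateau(self):
        # tau far smaller than a third of the segment: plateau within 0.1%
        p = VoltageProtocol()
        t = p.time_s[:, None]
        plateau = 2.0
        cur = np.tile(plateau + 5.0 * np.exp(-t / 2e-4), (1, p.n_steps))
        ss = steady_state(make_sweeps(cur, p, corrected=True))
        assert np.allclose(ss, plateau, rtol=1e-3)

    def test_homogeneity_under_scaling(self):
        p = VoltageProtocol()
        rng = np.random.default_rng(0)
        cur = rng.normal(size=(p.n_samples, p.n_steps))
        base = steady_state(make_sweeps(cur, p, corrected=True))
        scaled = steady_state(make_sweeps(3.7 * cur, p, corrected=True))
        assert np.allclose(scaled, 3.7 * base)

    def test_refuses_uncorrected_without_flag(self):
        p = VoltageProtocol()
        raw = make_sweeps(np.zeros((p.n_samples, p.n_steps)), p)
        with pytest.raises(ValueError):
            steady_state(raw)
        steady_state(raw, allow_raw=True)

    def test_short_segment_rejected(self):
        p = VoltageProtocol(step_duration_ms=0.02)
        assert p.n_step == 2
        with pytest.raises(ValueError):
            steady_state(make_sweeps(np.zeros((p.n_samples, p.n_steps)), p, corrected=True))


class TestPnSubtract:
    def test_pure_leak_cancels_exactly(self):
        p = VoltageProtocol()
        volts = np.full((p.n_samples, p.n_steps), p.holding_mv)
        volts[p.step_slice] = p.step_voltages_mv
        g = 0.8e-3
        raw = make_sweeps(g * volts, p)
        pn = make_sweeps(g * volts * p.pn_scale, p)
        corr = pn_subtract(raw, pn)
        assert corr.corrected
        scale = np.maximum(np.abs(g * volts), 1e-12)
        assert np.max(np.abs(corr.current) / scale) < 1e-9

    def test_transport_survives_subtraction(self):
        p = VoltageProtocol()
        volts = np.full((p.n_samples, p.n_steps), p.holding_mv)
        volts[p.step_slice] = p.step_voltages_mv
        transport = np.zeros_like(volts)
        transport[p.step_slice] = np.linspace(-1, 5, p.n_steps)
        leak = 1.2e-3 * volts
        raw = make_sweeps(transport + leak, p)
        pn = make_sweeps(leak * p.pn_scale, p)
        corr = pn_subtract(raw, pn)
        assert np.allclose(corr.current, transport, atol=1e-12)

    def test_documented_formula_with_mismatched_scale(self):
        # pn recorded at a different scale than declared: the output obeys
        # raw - pn/pn_scale regardless (no hidden magic)
        p = VoltageProtocol()
        raw = make_sweeps(np.ones((p.n_samples, p.n_steps)), p)
        pn = make_sweeps(np.full((p.n_samples, p.n_steps), 0.1), p)
        corr = pn_subtract(raw, pn)
        assert np.allclose(corr.current, 1.0 - 0.1 / p.pn_scale)

    def test_shape_mismatch_rejected(self):
        p = VoltageProtocol()
        p2 = VoltageProtocol(step_end_mv=0)
        raw = make_sweeps(np.zeros((p.n_samples, p.n_steps)), p)
        pn = make_sweeps(np.zeros((p2.n_samples, p2.n_steps)), p2)
        with pytest.raises(ValueError):
            pn_subtract(raw, pn)

    def test_idempotent_on_corrected_zero_leak_data(self):
        p = VoltageProtocol()
        transport = np.random.default_rng(1).normal(size=(p.n_samples, p.n_steps))
        corr = make_sweeps(transport, p, corrected=True)
        zero_pn = make_sweeps(np.zeros_like(transport), p)
        again = pn_subtract(corr, zero_pn)
        assert np.array_equal(again.current, corr.current)


class TestBuildIv:
    def _cells(self, values, p=None):
        p = p or VoltageProtocol()
        out = []
        for i, v in enumerate(values):
            cur = np.tile(np.asarray(v, dtype=float), (p.n_samples, 1))
            out.append(make_sweeps(cur, p, corrected=True, cell_id=f"c{i}", construct="X"))
        return out

    def test_single_cell_stats(self):
        p = VoltageProtocol()
        vals = np.linspace(-1, 5, p.n_steps)
        iv = build_iv(self._cells([vals]))
        assert iv.n == 1
        assert np.allclose(iv.mean, vals)
        assert np.allclose(iv.sd, 0)

    def test_two_identical_cells(self):
        p = VoltageProtocol()
        vals = np.linspace(-1, 5, p.n_steps)
        iv = build_iv(self._cells([vals, vals]))
        assert iv.n == 2 and np.allclose(iv.sd, 0)

    def test_mean_invariant_to_cell_order(self):
        p = VoltageProtocol()
        rng = np.random.default_rng(2)
        vals = [rng.normal(size=p.n_steps) for _ in range(5)]
        a = build_iv(self._cells(vals))
        b = build_iv(self._cells(vals[::-1]))
        assert np.allclose(a.mean, b.mean)

    def test_mixed_construct_rejected(self):
        cells = self._cells([np.zeros(25), np.zeros(25)])
        cells[1].meta["construct"] = "Y"
        with pytest.raises(ValueError):
            build_iv(cells)
        build_iv(cells, allow_mixed=True)

    def test_simulator_round_trip_noise_off(self, gate, library):
        # with every corruption disabled the IV equals the model exactly
        wt = coexpression_construct(library["WT"])
        spec = SessionSpec(noise_sd=0.0, expression_cv=0.0, batch_cv=0.0, leak_g_sd=0.0)
        cells = []
        for ci in range(3):
            raw, pn = simulate_cell(
                spec, gate, wt, expression=1.0, batch_factor=1.0, leak_g=0.7,
                rng=None, meta={"cell_id": f"c{ci}"},
            )
            cells.append(pn_subtract(raw, pn))
        iv = build_iv(cells)
        model = wt.iv(gate, iv.voltages_mv)
        assert np.allclose(iv.mean, model, rtol=1e-12, atol=1e-12)


class TestCurrentDensity:
    def test_simple_division(self):
        iv = IVCurve([100.0], [[100.0]], units="pA", cell_ids=["a"])
        dens = current_density(iv, {"a": 10.0})
        assert dens.units == "pA/pF"
        assert np.allclose(dens.values, 10.0)

    def test_zero_capacitance_rejected(self):
        iv = IVCurve([100.0], [[100.0]], units="pA", cell_ids=["a"])
        with pytest.raises(ValueError):
            current_density(iv, {"a": 0.0})

    def test_missing_capacitance_rejected(self):
        iv = IVCurve([100.0], [[100.0], [200.0]], units="pA", cell_ids=["a", "b"])
        with pytest.raises(ValueError):
            current_density(iv, {"a": 10.0})

    def test_oocyte_units_rejected(self):
        iv = IVCurve([100.0], [[1.0]], units="uA", cell_ids=["a"])
        with pytest.raises(ValueError):
            current_density(iv, {"a": 10.0})

    def test_density_cancels_size_scaling(self):
        # when current scales with capacitance, density has lower CV
        rng = np.random.default_rng(3)
        caps = rng.lognormal(np.log(15), 0.2, size=30)
        base = 100.0
        values = (base * caps / 15.0)[:, None]
        iv = IVCurve([100.0], values, units="pA", cell_ids=[f"c{i}" for i in range(30)])
        dens = current_density(iv, dict(zip(iv.cell_ids, caps)))
        cv_raw = iv.values.std() / iv.values.mean()
        cv_dens = dens.values.std() / dens.values.mean()
        assert cv_dens < cv_raw
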