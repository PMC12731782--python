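"""Synthetic data generator: variant library, dimer mixing, model currents,
session and FLIM simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clcassay.flim_phasor import phasor_transform
from clcassay.synthdata import (
    DimerPopulation,
    FlimSpec,
    GateModel,
    SessionSpec,
    VariantParams,
    assemble_dimers,
    boltzmann,
    coexpression_construct,
    decay_profile,
    homodimer_construct,
    model_iv,
    simulate_cell,
    simulate_flim,
    simulate_study,
    variant_library,
)
from clcassay.traces import build_iv, pn_subtract, steady_state


class TestVariantLibrary:
    def test_wild_type_is_reference(self, library):
        wt = library["WT"]
        assert wt.dv_half == 0 and wt.amp_factor == 1.0 and wt.gof_inward_g == 0

    def test_r360s_is_dead_homodimer_with_gof(self, library):
        r = library["R360S"]
        assert r.amp_factor == 0.0 and r.gof_inward_g > 0 and r.dominant

    def test_shift_ordering_matches_reported_grading(self, library):
        assert library["K560E"].dv_half > library["G545S"].dv_half
        assert library["G545S"].dv_half >= library["V536M"].dv_half
        assert library["V536M"].dv_half > 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            VariantParams("x", amp_factor=-1)
        with pytest.raises(ValueError):
            VariantParams("x", gof_inward_g=-0.1)


class TestAssembleDimers:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (1.0, (0.25, 0.5, 0.25)),
            (2.0, (4 / 9, 4 / 9, 1 / 9)),
            (1e9, (1.0, 0.0, 0.0)),
        ],
    )
    def test_binomial_fractions(self, ratio, expected):
        pop = assemble_dimers(ratio)
        assert np.allclose((pop.frac_aa, pop.frac_ab, pop.frac_bb), expected, atol=1e-8)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            assemble_dimers(0.0)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(derandomize=True, max_examples=50)
    def test_fractions_sum_to_one_and_silencing_preserves_them(self, ratio):
        pop = assemble_dimers(ratio)
        sil = assemble_dimers(ratio, silent_b=True)
        assert abs(pop.frac_aa + pop.frac_ab + pop.frac_bb - 1.0) < 1e-12
        assert (pop.frac_aa, pop.frac_ab, pop.frac_bb) == (sil.frac_aa, sil.frac_ab, sil.frac_bb)
        assert not sil.transport_b and sil.transport_a


class TestModelIv:
    def test_dead_transporter_is_silent(self, gate):
        pop = assemble_dimers(1.0)
        dead = VariantParams("dead", amp_factor=0.0)
        i = model_iv(gate, DimerPopulation(0, 0, 1.0), dead, [-40, 0, 100, 200])
        assert np.allclose(i, 0)

    def test_wt_homodimer_matches_closed_form_ratio(self):
        gate = GateModel(v_half=120, slope_k=40)
        con = homodimer_construct(VariantParams("WT"))
        i = con.iv(gate, [200.0, 60.0])
        expected = (boltzmann(200, 120, 40) * 200) / (boltzmann(60, 120, 40) * 60)
        assert np.isclose(i[0] / i[1], expected, rtol=1e-12)

    def test_shifted_heterodimer_ratio_rises_with_voltage(self, gate, library):
        shifted = VariantParams("S", dv_half=40.0, dominant=True)
        het = coexpression_construct(shifted)
        ref = coexpression_construct(library["WT"])
        r60 = het.iv(gate, [60.0]) / ref.iv(gate, [60.0])
        r200 = het.iv(gate, [200.0]) / ref.iv(gate, [200.0])
        assert r60 < r200

    def test_linear_in_unit_current_and_fractions(self, library):
        # superposition: current is linear in i_unit and each population term
        v = np.array([-40.0, 50.0, 150.0])
        wt = library["WT"]
        g1 = GateModel(i_unit=1.0)
        g2 = GateModel(i_unit=2.5)
        pop = assemble_dimers(1.0)
        assert np.allclose(model_iv(g2, pop, wt, v), 2.5 * model_iv(g1, pop, wt, v))
        parts = [
            DimerPopulation(1, 0, 0), DimerPopulation(0, 1, 0), DimerPopulation(0, 0, 1)
        ]
        mix = sum(
            f * model_iv(g1, p, wt, v)
            for f, p in zip((pop.frac_aa, pop.frac_ab, pop.frac_bb), parts)
        )
        assert np.allclose(model_iv(g1, pop, wt, v), mix)

    def test_gof_term_only_at_acidic_ph_and_negative_voltages(self, gate, library):
        con = coexpression_construct(library["R360S"])
        v = np.array([-160.0, -40.0, 0.0, 100.0])
        i73 = con.iv(gate, v, "ph7.3")
        i53 = con.iv(gate, v, "ph5.3")
        delta = i53 - i73
        assert delta[0] < delta[1] < 0
        assert np.allclose(delta[2:], 0)

    def test_voltage_range_guard(self, gate, library):
        con = coexpression_construct(library["WT"])
        with pytest.raises(ValueError):
            con.iv(gate, [300.0])


class TestSimulateSession:
    def test_noise_free_cell_reproduces_model(self, gate, library):
        wt = coexpression_construct(library["WT"])
        spec = SessionSpec(noise_sd=0.0, expression_cv=0.0, batch_cv=0.0, leak_g_sd=0.0)
        raw, pn = simulate_cell(spec, gate, wt, expression=1.0, batch_factor=1.0,
                                leak_g=0.0, rng=None)
        ss = steady_state(raw, allow_raw=True)
        assert np.allclose(ss, wt.iv(gate, raw.voltages_mv), atol=1e-9)

    def test_ohmic_leak_obeys_ohms_law(self, gate):
        # transport-dead cell, 10 µS leak, +100 mV step -> 1 µA
        dead = homodimer_construct(VariantParams("dead", amp_factor=0.0))
        spec = SessionSpec(noise_sd=0.0, expression_cv=0.0, batch_cv=0.0, leak_g_sd=0.0)
        raw, _ = simulate_cell(spec, gate, dead, expression=1.0, batch_factor=1.0,
                               leak_g=10.0, rng=None)
        ss = steady_state(raw, allow_raw=True)
        i100 = ss[np.where(raw.voltages_mv == 100.0)[0][0]]
        assert np.isclose(i100, 1.0, rtol=1e-9)

    def test_session_files_byte_identical_across_runs(self, tmp_path, gate, library):
        import hashlib

        from clcassay.synthdata import simulate_session

        cons = [coexpression_construct(library["WT"])]
        spec = SessionSpec(seed=11, n_batches=1, cells_per_batch=2)
        simulate_session(spec, gate, cons, tmp_path / "a")
        simulate_session(spec, gate, cons, tmp_path / "b")
        for f1, f2 in zip(sorted((tmp_path / "a").iterdir()), sorted((tmp_path / "b").iterdir())):
            assert f1.name == f2.name
            assert hashlib.sha256(f1.read_bytes()).digest() == hashlib.sha256(f2.read_bytes()).digest()

    def test_corrected_currents_converge_to_batch_factor(self, gate, library):
        # law of large numbers: mean over cells of (corrected ss / model)
        # approaches the batch factor
        wt = coexpression_construct(library["WT"])
        spec = SessionSpec(seed=21, n_batches=1, cells_per_batch=100,
                           noise_sd=0.002, batch_cv=0.0)
        study = simulate_study(spec, gate, [wt])
        cells = study[wt.label][0]
        model = wt.iv(gate, cells[0][0].voltages_mv)
        j = 0  # +200 mV column: best signal-to-noise
        vals = np.asarray(
            [steady_state(pn_subtract(r, p))[j] / model[j] for r, p in cells]
        )
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        lognormal_mean = np.exp(spec.expression_cv**2 / 2)
        assert abs(vals.mean() - lognormal_mean) < 3 * se


class TestSimulateFlim:
    def test_regions_have_distinct_histograms(self):
        spec = FlimSpec(image_shape=(8, 8), tau_map={"a": 1.0, "b": 4.0},
                        photons_per_pixel=None)
        stack = simulate_flim(spec)
        pa = stack.counts[stack.region_masks["a"]][0]
        pb = stack.counts[stack.region_masks["b"]][0]
        assert not np.allclose(pa, pb)

    def test_zero_budget_gives_all_zero_stack(self):
        spec = FlimSpec(image_shape=(4, 4), photons_per_pixel=0.0, seed=1)
        stack = simulate_flim(spec)
        assert stack.counts.sum() == 0

    def test_determinism(self):
        spec = FlimSpec(image_shape=(6, 6), photons_per_pixel=200.0, seed=9)
        a = simulate_flim(spec)
        b = simulate_flim(spec)
        assert np.array_equal(a.counts, b.counts)

    def test_lifetime_longer_than_period_rejected(self):
        with pytest.raises(ValueError):
            FlimSpec(tau_map={"a": 13.0})  # period at 80 MHz is 12.5 ns

    def test_mean_arrival_time_converges_to_wrapped_decay_mean(self):
        # empirical mean arrival time -> analytic mean of the wrapped decay
        tau, rep = 2.0, 80.0
        period = 1e3 / rep
        spec = FlimSpec(image_shape=(16, 16), n_bins=512, tau_map={"a": tau},
                        photons_per_pixel=20000.0, seed=4)
        stack = simulate_flim(spec)
        centers = stack.bin_centers_ns
        prof = decay_profile(tau, 512, rep)
        analytic_mean = float((prof * centers).sum())
        counts = stack.counts.reshape(-1, 512).sum(axis=0)
        empirical = float((counts * centers).sum() / counts.sum())
        # ~5e6 photons: the empirical mean is within a small absolute band
        assert abs(empirical - analytic_mean) < 0.005
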