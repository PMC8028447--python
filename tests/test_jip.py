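import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import naive_jip_panel

from ojipcanopy import (
    DegenerateTransientError,
    Landmarks,
    Transient,
    UndefinedParameterError,
    classify_ji_phase,
    complementary_area,
    compute_jip_parameters,
    double_normalize,
    extract_landmarks,
    initial_slope_m0,
    jip_panel,
    relative_variable_fluorescence,
)
from ojipcanopy.jip import JIP_PARAMETER_NAMES
from ojipcanopy.simulate import OjipShapeParams, ojip_ground_truth, simulate_ojip

from conftest import random_landmark_tuples


class TestRelativeVariableFluorescence:
    @pytest.mark.parametrize(
        "f_t, expected", [(100.0, 0.0), (500.0, 1.0), (300.0, 0.5)]
    )
    def test_anchors_and_midpoint(self, f_t, expected):
        assert relative_variable_fluorescence(f_t, 100.0, 500.0) == pytest.approx(expected)

    def test_degenerate_when_fm_not_above_f0(self):
        with pytest.raises(DegenerateTransientError):
            relative_variable_fluorescence(100.0, 100.0, 100.0)


class TestInitialSlope:
    @pytest.mark.parametrize(
        "f300, expected", [(100.0, 0.0), (200.0, 1.0), (500.0, 4.0)]
    )
    def test_known_values(self, f300, expected):
        assert initial_slope_m0(100.0, f300, 500.0) == pytest.approx(expected)

    def test_warns_on_negative_onset(self):
        with pytest.warns(UserWarning):
            initial_slope_m0(100.0, 90.0, 500.0)


class TestLandmarkExtraction:
    def test_constant_transient_is_degenerate(self, grid_times):
        tr = Transient("c", "N1", "V1", "L1", grid_times, np.full(grid_times.size, 100.0))
        with pytest.raises(DegenerateTransientError):
            extract_landmarks(tr)

    def test_ramp_landmarks_match_closed_form(self, ramp_transient):
        lm = extract_landmarks(ramp_transient)
        assert lm.F0 == pytest.approx(100.0 + 4000.0 * 50e-6)
        assert lm.FJ == pytest.approx(108.0)
        assert lm.FI == pytest.approx(220.0)
        assert lm.FM == pytest.approx(4100.0)
        assert lm.t_fm == pytest.approx(1.0)

    def test_fm_tie_takes_earliest_time(self, grid_times):
        values = np.minimum(100.0 + 4000.0 * grid_times, 150.0)
        tr = Transient("p", "N1", "V1", "L1", grid_times, values)
        lm = extract_landmarks(tr)
        assert lm.FM == pytest.approx(150.0)
        # plateau starts at t = 50/4000 = 0.0125 s; earliest plateau node wins
        assert lm.t_fm <= 0.0135

    def test_simulated_landmarks_match_generator_truth(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            params = OjipShapeParams(
                f0=rng.uniform(300, 700),
                amplitude=rng.uniform(1000, 3000),
                w_oj=rng.uniform(0.6, 1.2),
                w_ji=rng.uniform(-0.5, 0.8),
                w_ip=rng.uniform(0.1, 0.8),
                noise_cv=0.0,
            )
            tr, truth = simulate_ojip(params)
            lm = extract_landmarks(tr)
            for got, want in [(lm.F0, truth.F0), (lm.F300, truth.F300),
                              (lm.FJ, truth.FJ), (lm.FI, truth.FI), (lm.FM, truth.FM)]:
                assert got == pytest.approx(want, rel=1e-6)


class TestComplementaryArea:
    def test_peak_at_first_sample_has_zero_area(self, grid_times):
        # peak at the very first sample: nothing to integrate above the curve
        values = np.full(grid_times.size, 400.0)
        values[0] = 500.0
        tr = Transient("s", "N1", "V1", "L1", grid_times, values)
        area, sm, n = complementary_area(tr, 500.0, grid_times[0])
        assert (area, sm, n) == (0.0, 0.0, 0.0)

    def test_linear_rise_gives_triangular_area(self):
        # F rises linearly from F0 to FM over [0, 300 ms]: Sm = 150 ms
        t = np.linspace(1e-5, 0.3, 30000)
        tr = Transient("lin", "N1", "V1", "L1", t, 100.0 + 300.0 * (t / 0.3))
        lm = extract_landmarks(tr)
        sm = lm.area / (lm.FM - lm.F0)
        assert sm == pytest.approx(150.0, rel=5e-3)

    def test_trapezoid_stable_under_grid_refinement(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            params = OjipShapeParams(
                f0=rng.uniform(300, 700), amplitude=rng.uniform(1000, 3000),
                w_oj=1.0, w_ji=rng.uniform(-0.4, 0.6), w_ip=rng.uniform(0.1, 0.6),
                noise_cv=0.0,
            )
            tr, _ = simulate_ojip(params)
            lm = extract_landmarks(tr)
            # same closed form on a 10x finer uniform grid
            fine_t = np.linspace(tr.times[0], lm.t_fm, 10 * tr.times.size)
            s = params.shape(fine_t)
            s_max = float(np.asarray(params.shape(tr.times)).max())
            fine_v = params.f0 + params.amplitude * s / s_max
            fine_area = np.trapezoid(lm.FM - fine_v, fine_t * 1e3)
            assert lm.area == pytest.approx(fine_area, rel=1e-2)


class TestDerivedPanel:
    def test_worked_example_full_panel(self, worked_landmarks):
        m0 = initial_slope_m0(100.0, 200.0, 500.0)
        p = compute_jip_parameters(worked_landmarks, m0, 10.0, "as_printed")
        expected = {
            "phi_Po": 0.8, "VJ": 0.5, "VI": 0.75, "M0": 1.0, "psi_Eo": 0.5,
            "phi_Eo": 0.4, "phi_Ro": 0.2, "ABS_RC": 2.5, "TR0_RC": 2.0,
            "ET0_RC": 1.0, "DI0_RC": 0.5, "PI_ABS": 1.6, "RE0_RC": 0.2,
            "ET0_CS": 160.0, "RE0_CS": 40.0, "ABS_CS": 500.0, "TR0_CS": 400.0,
            "DI0_CS": 100.0, "RC_CS": 200.0,
        }
        for name, value in expected.items():
            assert getattr(p, name) == pytest.approx(value), name

    def test_matches_naive_oracle_on_random_tuples(self, rng):
        f0s, f300s, fjs, fis, fms = random_landmark_tuples(rng, 300)
        for f0, f300, fj, fi, fm in zip(f0s, f300s, fjs, fis, fms):
            lm = Landmarks(F0=f0, F300=f300, FJ=fj, FI=fi, FM=fm, t_fm=0.5, area=0.0)
            m0 = initial_slope_m0(f0, f300, fm)
            for variant in ("as_printed", "strasser_standard"):
                got = compute_jip_parameters(lm, m0, 3.0, variant).as_dict()
                want = naive_jip_panel(f0, f300, fj, fi, fm, sm=3.0, variant=variant)
                for name in JIP_PARAMETER_NAMES:
                    assert got[name] == pytest.approx(want[name], rel=1e-10), name

    def test_algebraic_identities_hold_exactly(self, rng):
        f0s, f300s, fjs, fis, fms = random_landmark_tuples(rng, 200)
        for f0, f300, fj, fi, fm in zip(f0s, f300s, fjs, fis, fms):
            lm = Landmarks(F0=f0, F300=f300, FJ=fj, FI=fi, FM=fm, t_fm=0.5, area=0.0)
            m0 = initial_slope_m0(f0, f300, fm)
            for variant in ("as_printed", "strasser_standard"):
                p = compute_jip_parameters(lm, m0, 1.0, variant)
                assert p.DI0_RC == pytest.approx(p.ABS_RC - p.TR0_RC, rel=1e-12)
                assert p.DI0_CS == pytest.approx(p.ABS_CS - p.TR0_CS, rel=1e-12)
                assert p.phi_Eo == pytest.approx(p.phi_Po * p.psi_Eo, rel=1e-12)
                assert p.TR0_CS / p.ABS_CS == pytest.approx(p.phi_Po, rel=1e-12)

    def test_flat_ji_phase_variant_relation(self):
        # VI = VJ: printed RE0/RC keeps the phi_Ro factor, standard collapses
        lm = Landmarks(F0=100.0, F300=200.0, FJ=300.0, FI=300.0, FM=500.0, t_fm=0.5, area=0.0)
        m0 = initial_slope_m0(100.0, 200.0, 500.0)
        printed = compute_jip_parameters(lm, m0, 1.0, "as_printed")
        standard = compute_jip_parameters(lm, m0, 1.0, "strasser_standard")
        assert printed.RE0_RC / printed.ET0_RC == pytest.approx(printed.phi_Ro)
        assert standard.RE0_RC == pytest.approx(standard.ET0_RC)

    def test_variants_differ_only_in_three_fields(self, worked_landmarks):
        m0 = initial_slope_m0(100.0, 200.0, 500.0)
        a = compute_jip_parameters(worked_landmarks, m0, 10.0, "as_printed").as_dict()
        b = compute_jip_parameters(worked_landmarks, m0, 10.0, "strasser_standard").as_dict()
        differing = {k for k in a if a[k] != b[k]}
        assert differing == {"RE0_RC", "ET0_CS", "RE0_CS"}

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        fm_scale=st.floats(min_value=1.01, max_value=3.0),
        vj=st.floats(min_value=0.1, max_value=0.9),
    )
    def test_monotonicity_in_fm_and_vj(self, fm_scale, vj):
        f0, fv = 100.0, 400.0
        base = Landmarks(F0=f0, F300=f0 + 0.2 * fv, FJ=f0 + vj * fv, FI=f0 + 0.9 * fv,
                         FM=f0 + fv, t_fm=0.5, area=0.0)
        m0 = initial_slope_m0(base.F0, base.F300, base.FM)
        p = compute_jip_parameters(base, m0, 1.0)
        # raising FM (same landmarks otherwise) raises phi_Po
        fv2 = fv * fm_scale
        bigger = Landmarks(F0=f0, F300=base.F300, FJ=base.FJ, FI=base.FI,
                           FM=f0 + fv2, t_fm=0.5, area=0.0)
        p_big = compute_jip_parameters(bigger, initial_slope_m0(f0, base.F300, f0 + fv2), 1.0)
        assert p_big.phi_Po > p.phi_Po
        # raising VJ lowers psi_Eo, phi_Eo and PI_ABS
        if vj < 0.85:
            higher_vj = Landmarks(F0=f0, F300=base.F300, FJ=f0 + (vj + 0.05) * fv,
                                  FI=base.FI, FM=base.FM, t_fm=0.5, area=0.0)
            p_hi = compute_jip_parameters(higher_vj, m0, 1.0)
            assert p_hi.psi_Eo < p.psi_Eo
            assert p_hi.phi_Eo < p.phi_Eo
            assert p_hi.PI_ABS < p.PI_ABS

    def test_undefined_when_vj_degenerate(self):
        lm = Landmarks(F0=100.0, F300=100.0, FJ=100.0, FI=400.0, FM=500.0, t_fm=0.5, area=0.0)
        with pytest.raises(UndefinedParameterError):
            compute_jip_parameters(lm, 0.0, 1.0)


class TestDoubleNormalize:
    def test_anchors(self, ramp_transient):
        norm = double_normalize(ramp_transient)
        assert norm.max() == pytest.approx(1.0)
        f0_index = 4  # 50 us on the default grid
        assert norm[f0_index] == pytest.approx(0.0, abs=1e-12)

    def test_midpoint_value(self):
        t = np.linspace(1e-5, 0.5, 1000)
        values = np.interp(t, [1e-5, 0.25, 0.5], [100.0, 300.0, 500.0])
        tr = Transient("n", "N1", "V1", "L1", t, values)
        norm = double_normalize(tr)
        mid = np.argmin(np.abs(t - 0.25))
        f0 = np.interp(50e-6, t, values)
        expected = (values[mid] - f0) / (500.0 - f0)
        assert norm[mid] == pytest.approx(expected, rel=1e-12)
        assert norm[mid] == pytest.approx(0.5, abs=2e-3)


class TestJiPhase:
    @pytest.mark.parametrize(
        "fj, fi, expected",
        [(300.0, 400.0, "JI_rise"), (400.0, 300.0, "JI_fall"), (300.0, 301.0, "flat")],
    )
    def test_classification(self, fj, fi, expected):
        lm = Landmarks(F0=100.0, F300=200.0, FJ=fj, FI=fi, FM=500.0, t_fm=0.5, area=0.0)
        assert classify_ji_phase(lm, delta=0.01) == expected


class TestJipPanelPipeline:
    def test_jip_panel_consistent_with_parts(self, ramp_transient):
        lm, params = jip_panel(ramp_transient)
        assert params.Sm == pytest.approx(lm.area / (lm.FM - lm.F0))
        assert params.N == pytest.approx(params.Sm * params.M0 / params.VJ)
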