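import numpy as np
import pytest
from scipy.integrate import quad

from petref import acquisition as acq
from petref import input_function as ifn
from petref import phantom as ph


class TestModelEvaluation:
    def test_starts_at_zero_and_is_continuous_at_peak(self, planted_triexp):
        m = planted_triexp
        assert m(0.0) == 0.0
        eps = 1e-9
        assert abs(m(m.t_peak - eps) - m(m.t_peak + eps)) < 1e-5
        assert m(m.t_peak) == pytest.approx(m.peak_value)

    def test_negative_time_is_domain_error(self, planted_triexp):
        with pytest.raises(ValueError):
            planted_triexp(-0.1)
        with pytest.raises(ValueError):
            planted_triexp.integral(np.array([1.0, -1.0]))

    def test_rates_canonically_ordered(self):
        m = ifn.InputFunctionModel(t_peak=1.0, amplitudes=np.array([1.0, 2.0, 3.0]),
                                   rates=np.array([0.01, 1.0, 0.1]))
        assert (np.diff(m.rates) < 0).all()
        np.testing.assert_allclose(m.amplitudes, [2.0, 3.0, 1.0])

    def test_nonnegative_everywhere(self, planted_triexp):
        t = np.linspace(0, 120, 5000)
        assert (planted_triexp(t) >= 0).all()

    def test_integral_zero_at_origin_and_triangle_at_peak(self, planted_triexp):
        m = planted_triexp
        assert m.integral(0.0) == 0.0
        tri = 0.5 * m.peak_value * (m.t_peak - m.injection_start)
        assert m.integral(m.t_peak) == pytest.approx(tri)

    def test_integral_matches_adaptive_quadrature(self, planted_triexp):
        m = planted_triexp
        val, _ = quad(lambda t: float(m(t)), 0, 60, points=[m.t_peak], limit=200)
        assert abs(m.integral(60.0) / val - 1) < 1e-8

    def test_zero_rate_component_integrates_linearly(self):
        m = ifn.InputFunctionModel(t_peak=1.0, amplitudes=np.array([0.0, 0.0, 5.0]),
                                   rates=np.array([1.0, 0.5, 0.0]))
        # constant tail: integral grows linearly past the peak
        assert m.integral(11.0) - m.integral(1.0) == pytest.approx(50.0)


class TestModelProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        amps=st.lists(st.floats(0.0, 1000.0), min_size=3, max_size=3).filter(
            lambda a: sum(a) > 1.0),
        rates=st.lists(st.floats(0.0, 2.0), min_size=3, max_size=3),
        t_peak=st.floats(0.1, 2.0),
        t_end=st.floats(5.0, 90.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_closed_form_integral_matches_trapezoid(self, amps, rates, t_peak, t_end):
        m = ifn.InputFunctionModel(t_peak=t_peak, amplitudes=np.array(amps),
                                   rates=np.array(rates))
        t = np.linspace(0, t_end, 20001)
        numeric = np.trapezoid(m(t), t)
        assert m.integral(t_end) == pytest.approx(numeric, rel=1e-5, abs=1e-6)
        assert (m(t) >= 0).all()


class TestIdifExtraction:
    def test_uniform_image_gives_uniform_tac(self, schedule):
        data = np.full((4, 4, 4, schedule.n_frames), 7.5)
        img = acq.DynamicImage(data=data, schedule=schedule, voxel_size_mm=2.0)
        mask = np.ones((4, 4, 4), dtype=bool)
        tac = ifn.extract_idif(img, mask)
        np.testing.assert_allclose(tac.activity, 7.5)

    def test_single_voxel_mask_returns_that_series(self, schedule):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 5, (3, 3, 3, schedule.n_frames))
        img = acq.DynamicImage(data=data, schedule=schedule, voxel_size_mm=2.0)
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 2, 0] = True
        np.testing.assert_array_equal(ifn.extract_idif(img, mask).activity,
                                      data[1, 2, 0])

    def test_empty_mask_raises(self, schedule):
        img = acq.DynamicImage(data=np.zeros((2, 2, 2, schedule.n_frames)),
                               schedule=schedule, voxel_size_mm=2.0)
        with pytest.raises(ValueError, match="empty"):
            ifn.extract_idif(img, np.zeros((2, 2, 2), dtype=bool))


class TestCalibration:
    def _idif(self, model, schedule, factor):
        # sampling grid contains the blood sampling times, so interpolation
        # at those times is exact
        t = np.arange(0.5, 56.0, 0.5)
        return acq.TAC(times_min=t, activity=factor * model(t))

    def test_exact_ratio_recovered(self, input_model, schedule):
        idif = self._idif(input_model, schedule, 0.5)
        blood = acq.sample_blood(input_model)
        cal, s = ifn.calibrate_idif(idif, blood)
        assert s == pytest.approx(2.0)
        np.testing.assert_allclose(cal.activity, 2.0 * idif.activity)

    def test_identity(self, input_model, schedule):
        idif = self._idif(input_model, schedule, 1.0)
        _, s = ifn.calibrate_idif(idif, acq.sample_blood(input_model))
        assert s == pytest.approx(1.0)

    def test_all_zero_idif_is_degenerate(self, input_model, schedule):
        idif = acq.TAC(times_min=schedule.mid_times_min,
                       activity=np.zeros(schedule.n_frames))
        with pytest.raises(ValueError, match="degenerate"):
            ifn.calibrate_idif(idif, acq.sample_blood(input_model))


class TestTriexpFit:
    def _samples(self, model):
        """Concatenation-style samples that include the exact peak time."""
        t_idif = np.arange(0.1, 3.0, 0.2)  # includes 0.5 exactly
        idif = acq.TAC(times_min=t_idif, activity=model(t_idif))
        blood = acq.sample_blood(model, plasma_glucose=5.0)
        return idif, blood

    def test_planted_parameters_recovered_within_1pct(self, planted_triexp):
        idif, blood = self._samples(planted_triexp)
        fit = ifn.fit_input_function(idif, blood)
        np.testing.assert_allclose(fit.amplitudes, planted_triexp.amplitudes, rtol=0.01)
        np.testing.assert_allclose(fit.rates, planted_triexp.rates, rtol=0.01)

    def test_recovery_agrees_with_independent_grid_oracle(self, planted_triexp):
        """Cross-check with a brute-force curve_fit from a different grid."""
        from scipy.optimize import curve_fit
        idif, blood = self._samples(planted_triexp)
        fit = ifn.fit_input_function(idif, blood)
        t = np.concatenate([idif.times_min[idif.times_min < 3.0], blood.times_min])
        t = np.sort(t)
        v = planted_triexp(t)
        tail = t >= 0.5

        def f(tt, a1, a2, a3, l1, l2, l3):
            return (a1 * np.exp(-l1 * (tt - 0.5)) + a2 * np.exp(-l2 * (tt - 0.5))
                    + a3 * np.exp(-l3 * (tt - 0.5)))

        best = None
        for l0 in ([0.3, 0.03, 0.003], [1.0, 0.1, 0.01]):
            try:
                p, _ = curve_fit(f, t[tail], v[tail], p0=[600, 200, 100] + l0,
                                 bounds=(0, np.inf), maxfev=20000)
            except RuntimeError:
                continue
            r = float(np.sum((f(t[tail], *p) - v[tail]) ** 2))
            if best is None or r < best[0]:
                best = (r, p)
        oracle = best[1]
        order = np.argsort(-oracle[3:])
        np.testing.assert_allclose(fit.amplitudes, oracle[:3][order], rtol=0.02)
        np.testing.assert_allclose(fit.rates, oracle[3:][order], rtol=0.02)

    def test_single_exponential_is_fit_exactly(self):
        single = ifn.InputFunctionModel(t_peak=0.5, amplitudes=np.array([1000.0, 0, 0]),
                                        rates=np.array([0.1, 0, 0]))
        t_idif = np.arange(0.1, 3.0, 0.2)
        idif = acq.TAC(times_min=t_idif, activity=single(t_idif))
        blood = acq.sample_blood(single)
        fit = ifn.fit_input_function(idif, blood)
        t_check = np.linspace(0.5, 55, 40)
        np.testing.assert_allclose(fit(t_check), single(t_check), rtol=1e-6)

    def test_continuity_at_peak_enforced(self, planted_triexp):
        idif, blood = self._samples(planted_triexp)
        fit = ifn.fit_input_function(idif, blood)
        assert fit.amplitudes.sum() == pytest.approx(fit.peak_value)
        eps = 1e-9
        assert abs(fit(fit.t_peak - eps) - fit(fit.t_peak + eps)) < 1e-4

    def test_too_few_points_raises(self, planted_triexp):
        idif = acq.TAC(times_min=np.array([0.5]), activity=np.array([1000.0]))
        blood = acq.BloodSamples(times_min=np.array([3.0, 8.0]),
                                 activity=planted_triexp(np.array([3.0, 8.0])))
        with pytest.raises(ValueError, match="at least 7"):
            ifn.fit_input_function(idif, blood)

    def test_scale_equivariance(self, planted_triexp):
        """x c on blood and IDIF: s unchanged, amplitudes and integrals x c."""
        t = np.arange(0.1, 56.0, 0.4)
        idif = acq.TAC(times_min=t, activity=planted_triexp(t))
        blood = acq.sample_blood(planted_triexp, plasma_glucose=5.0)
        c = 3.7
        idif_c = acq.TAC(times_min=idif.times_min, activity=c * idif.activity)
        blood_c = acq.BloodSamples(times_min=blood.times_min,
                                   activity=c * blood.activity)
        _, s1 = ifn.calibrate_idif(idif, blood)
        _, s2 = ifn.calibrate_idif(idif_c, blood_c)
        assert s2 == pytest.approx(s1)
        f1 = ifn.fit_input_function(idif, blood)
        f2 = ifn.fit_input_function(idif_c, blood_c)
        np.testing.assert_allclose(f2.amplitudes, c * f1.amplitudes, rtol=1e-6)
        np.testing.assert_allclose(f2.rates, f1.rates, rtol=1e-6)
        assert f2.integral(60.0) == pytest.approx(c * f1.integral(60.0))


@pytest.fixture(scope="module")
def rendered(atlas, input_model, schedule):
    base = ph.baseline_kinetics(atlas.region_table)
    id_to_name = atlas.region_table.set_index("region_id")["name"]
    acts = {}
    for rid in np.unique(atlas.labels):
        if rid == 0:
            continue
        b = base.loc[id_to_name[int(rid)]]
        acts[int(rid)] = acq.simulate_tissue_tac(
            (b["K1"], b["k2"], b["k3"], b["vB"]), input_model, schedule).activity
    return acq.render_dynamic_image(atlas, acts, psf_fwhm_mm=6.0, schedule=schedule)


class TestPhantomIdifPipeline:
    def test_idif_peak_is_pve_underestimated(self, rendered, atlas, input_model, schedule):
        idif = ifn.extract_idif(rendered, atlas.labels == ph.CAROTID_ID)
        t = np.linspace(0, 60, 7201)
        cp_frames = acq.frame_average(t, input_model(t), schedule)
        assert idif.activity.max() < cp_frames.max()

    def test_calibrated_idif_matches_plasma_within_3pct(self, rendered, atlas, input_model):
        idif = ifn.extract_idif(rendered, atlas.labels == ph.CAROTID_ID)
        blood = acq.sample_blood(input_model, plasma_glucose=5.0)
        cal, s = ifn.calibrate_idif(idif, blood)
        at_samples = np.interp(blood.times_min, cal.times_min, cal.activity)
        np.testing.assert_allclose(at_samples, input_model(blood.times_min), rtol=0.03)
        assert s > 1.0  # calibration compensates partial-volume loss
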