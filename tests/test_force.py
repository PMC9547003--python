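"""Force spectroscopy: eWLC model, fitting, rupture/refold detection,
contour-length change and the area free-energy estimate."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from kymotrap.constants import KCAL_PER_PN_NM
from kymotrap.force import (
    EWLCModel,
    analyze_unfolding_curve,
    area_free_energy,
    detect_refold,
    detect_unfolding,
    ewlc_extension,
    ewlc_force,
    fit_ewlc,
    fit_gaussian,
    measure_delta_lc,
    segmented_unfolding_fit,
)
from kymotrap.simulate import RuptureSpec, make_force_extension
from kymotrap.structures import EWLCParams, ForceExtensionCurve, UnfoldingEvent


class TestEWLCClosedForm:
    def test_reference_value(self, dna_params):
        # independent evaluation: 4902·(1 − 0.5·sqrt(4.114/450) + 10/1200)
        assert ewlc_extension(10.0, dna_params) == pytest.approx(4708.50, abs=0.01)

    def test_domain_error_at_nonpositive_force(self, dna_params):
        for bad in (0.0, -1.0):
            with pytest.raises(ValueError):
                ewlc_extension(bad, dna_params)

    @given(f1=st.floats(0.1, 80.0), f2=st.floats(0.1, 80.0))
    def test_strictly_increasing_in_force(self, dna_params, f1, f2):
        if f1 == f2:
            return
        lo, hi = sorted((f1, f2))
        assert ewlc_extension(hi, dna_params) > ewlc_extension(lo, dna_params)

    def test_asymptote_is_contour_length(self, dna_params):
        stiff = EWLCParams(Lp=dna_params.Lp, Lc=dna_params.Lc, S=1e12)
        assert ewlc_extension(1e8, stiff) == pytest.approx(dna_params.Lc, rel=1e-4)

    @given(force=st.floats(0.5, 60.0))
    def test_inversion_round_trip(self, dna_params, force):
        x = ewlc_extension(force, dna_params)
        assert ewlc_force(x, dna_params) == pytest.approx(force, rel=1e-8)


class TestEWLCFitting:
    def test_noiseless_round_trip_recovers_generator(self, dna_params):
        stretch, _ = make_force_extension(dna_params, None, seed=0)
        fit = fit_ewlc(stretch)
        assert fit.Lp == pytest.approx(dna_params.Lp, rel=1e-6)
        assert fit.Lc == pytest.approx(dna_params.Lc, rel=1e-6)
        assert fit.S == pytest.approx(dna_params.S, rel=1e-6)

    def test_noisy_contour_length_within_three_se(self, dna_params, rng):
        hits = 0
        for _ in range(100):
            stretch, _ = make_force_extension(dna_params, None, noise_sd=0.2,
                                              rng=rng)
            fit = fit_ewlc(stretch)
            hits += abs(fit.Lc - dna_params.Lc) <= 3 * fit.Lc_se
        assert hits >= 95

    def test_empty_force_window_errors(self, dna_params):
        stretch, _ = make_force_extension(dna_params, None, seed=0)
        with pytest.raises(ValueError, match=">= 10 samples"):
            fit_ewlc(stretch, force_range=(60.0, 70.0))

    def test_fixed_parameters_are_held(self, dna_params):
        stretch, _ = make_force_extension(dna_params, None, seed=0)
        fit = fit_ewlc(stretch, fixed={"Lp": 50.0, "S": 1000.0})
        assert fit.Lp == 50.0 and fit.S == 1000.0
        assert fit.Lp_se == 0.0 and fit.S_se == 0.0

    def test_sklearn_estimator_protocol(self, dna_params):
        model = EWLCModel(lc=4800.0)
        params = model.get_params()
        assert params["lc"] == 4800.0
        cloned = clone(model)
        F = np.linspace(3, 18, 50)
        x = ewlc_extension(F, dna_params)
        cloned.fit(F, x)
        assert cloned.lc_ == pytest.approx(dna_params.Lc, rel=1e-6)
        np.testing.assert_allclose(cloned.predict(F), x, rtol=1e-6)


class TestDetectUnfolding:
    def test_noiseless_rupture_at_programmed_force(self, dna_params, rupture_spec):
        stretch, _ = make_force_extension(dna_params, rupture_spec, seed=0)
        grid_step = np.max(np.diff(np.sort(stretch.force)))
        event, _ = analyze_unfolding_curve(stretch)
        assert event is not None
        assert event.F_unfold == pytest.approx(23.0, abs=grid_step + 1e-9)

    def test_no_rupture_returns_none(self, dna_params):
        stretch, _ = make_force_extension(dna_params, None, seed=0)
        event, _ = analyze_unfolding_curve(stretch)
        assert event is None
        baseline = fit_ewlc(stretch)
        assert detect_unfolding(stretch, baseline) is None

    def test_monte_carlo_mean_within_two_sem(self, dna_params, rng):
        n = 36
        spec = RuptureSpec(23.0, 2.0, 14.0, 1.0, 9.5, 0.3)
        detected = []
        for _ in range(n):
            stretch, _ = make_force_extension(dna_params, spec, noise_sd=0.2,
                                              rng=rng)
            event, _ = analyze_unfolding_curve(stretch)
            if event is not None:
                detected.append(event.F_unfold)
        assert len(detected) >= 0.9 * n
        mean, sd = fit_gaussian(detected)
        sem = sd / np.sqrt(len(detected))
        assert abs(mean - 23.0) <= 2 * max(sem, 2.0 / np.sqrt(n))

    def test_false_positive_rate_below_one_percent(self, dna_params, rng):
        # rupture-free noisy curves must stay quiet
        false_pos = 0
        n = 1000
        for _ in range(n):
            stretch, _ = make_force_extension(dna_params, None, noise_sd=0.2,
                                              rng=rng)
            event, _ = analyze_unfolding_curve(stretch)
            false_pos += event is not None
        assert false_pos / n < 0.01


class TestDeltaLc:
    def test_noiseless_self_consistency(self, dna_params, rupture_spec):
        stretch, _ = make_force_extension(dna_params, rupture_spec, seed=0)
        event, baseline = analyze_unfolding_curve(stretch)
        assert event.delta_Lc == pytest.approx(9.5, abs=1e-3)
        # the classical two-stage recipe agrees in the noiseless case
        dlc, _ = measure_delta_lc(stretch, baseline, post_range=(23.5, 29.0),
                                  event=event)
        assert dlc == pytest.approx(9.5, abs=0.01)

    def test_no_rupture_violates_precondition(self, dna_params):
        stretch, _ = make_force_extension(dna_params, None, seed=0)
        baseline = fit_ewlc(stretch)
        with pytest.raises(ValueError, match="no unfolding event"):
            measure_delta_lc(stretch, baseline, event=None)

    def test_rupture_above_post_window_rejected(self, dna_params, rupture_spec):
        stretch, _ = make_force_extension(dna_params, rupture_spec, seed=0)
        event, baseline = analyze_unfolding_curve(stretch)
        with pytest.raises(ValueError, match="not below the post window"):
            measure_delta_lc(stretch, baseline, post_range=(10.0, 16.0),
                             event=event)

    def test_monte_carlo_mean_within_two_sem(self, dna_params, rng):
        n = 36
        spec = RuptureSpec(23.0, 2.0, 14.0, 1.0, 9.5, 1.8)
        values = []
        for _ in range(n):
            stretch, _ = make_force_extension(dna_params, spec, noise_sd=0.2,
                                              rng=rng)
            event, _ = analyze_unfolding_curve(stretch)
            if event is not None and event.delta_Lc is not None:
                values.append(event.delta_Lc)
        mean, sd = fit_gaussian(values)
        sem = sd / np.sqrt(len(values))
        assert abs(mean - 9.5) <= 2 * max(sem, 0.3)


class TestDetectRefold:
    def test_noiseless_refold_at_programmed_force(self, dna_params, rupture_spec):
        stretch, relax = make_force_extension(dna_params, rupture_spec, seed=0)
        event, _ = analyze_unfolding_curve(stretch, relax)
        grid_step = np.max(np.diff(np.sort(relax.force)))
        assert event.F_refold == pytest.approx(14.0, abs=grid_step + 1e-9)

    def test_relax_without_refold_returns_none(self, dna_params):
        # refold force below the force ramp minimum: never refolds
        spec = RuptureSpec(23.0, 0.0, 0.1, 0.0, 9.5, 0.0)
        stretch, relax = make_force_extension(dna_params, spec, f_min=0.5, seed=0)
        folded = EWLCParams(Lp=45.0, Lc=4902.0, S=1200.0)
        unfolded = EWLCParams(Lp=45.0, Lc=4911.5, S=1200.0)
        assert detect_refold(relax, unfolded, folded) is None

    def test_monte_carlo_mean_within_two_sem(self, dna_params, rng):
        n = 13
        spec = RuptureSpec(23.0, 1.0, 14.0, 1.0, 9.5, 0.3)
        values = []
        for _ in range(n):
            stretch, relax = make_force_extension(dna_params, spec, noise_sd=0.2,
                                                  rng=rng)
            event, _ = analyze_unfolding_curve(stretch, relax)
            if event is not None and event.F_refold is not None:
                values.append(event.F_refold)
        mean, sd = fit_gaussian(values)
        sem = sd / np.sqrt(len(values))
        assert abs(mean - 14.0) <= 2 * max(sem, 1.0 / np.sqrt(n) * np.sqrt(13))

    def test_hysteresis_ordering_preserved(self, dna_params, rng):
        spec = RuptureSpec(23.0, 2.0, 14.0, 2.0, 9.5, 0.3)
        checked = 0
        for _ in range(15):
            stretch, relax = make_force_extension(dna_params, spec, noise_sd=0.2,
                                                  rng=rng)
            event, _ = analyze_unfolding_curve(stretch, relax)
            if event is not None and event.F_refold is not None:
                assert event.F_refold < event.F_unfold
                checked += 1
        assert checked >= 10


class TestAreaFreeEnergy:
    def test_rectangular_toy_transition(self):
        # constant 23 pN across a 9.5 nm jump: 23·9.5 pN·nm → kcal/mol
        curve = ForceExtensionCurve(
            extension=[0.0, 9.5], force=[23.0, 23.0], time=[0.0, 1.0]
        )
        event = UnfoldingEvent(F_unfold=23.0, transition=(0, 1))
        expected = 23.0 * 9.5 * KCAL_PER_PN_NM
        assert area_free_energy(curve, event) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(31.4, abs=0.1)

    def test_zero_width_transition_warns_and_returns_zero(self):
        curve = ForceExtensionCurve(
            extension=[5.0, 5.0], force=[23.0, 23.0], time=[0.0, 1.0]
        )
        event = UnfoldingEvent(F_unfold=23.0, transition=(0, 1))
        with pytest.warns(UserWarning, match="degenerate"):
            assert area_free_energy(curve, event) == 0.0

    def test_matches_dense_trapezoid_oracle(self):
        # force varying linearly across the transition: closed-form area
        x = np.linspace(100.0, 109.5, 200)
        F = 20.0 + (x - 100.0) * 0.4
        curve = ForceExtensionCurve(extension=x, force=F, time=np.arange(200.0))
        event = UnfoldingEvent(F_unfold=20.0, transition=(0, 199))
        exact = (20.0 * 9.5 + 0.5 * 0.4 * 9.5**2) * KCAL_PER_PN_NM
        assert area_free_energy(curve, event) == pytest.approx(exact, rel=1e-3)


class TestSegmentedFit:
    def test_gain_separates_event_from_null(self, dna_params, rupture_spec, rng):
        stretch, _ = make_force_extension(dna_params, rupture_spec, noise_sd=0.2,
                                          rng=rng)
        seg = segmented_unfolding_fit(stretch)
        assert seg is not None and seg.gain > 100
        null, _ = make_force_extension(dna_params, None, noise_sd=0.2, rng=rng)
        assert segmented_unfolding_fit(null) is None

    def test_noiseless_null_has_no_event(self, dna_params):
        stretch, _ = make_force_extension(dna_params, None, seed=0)
        assert segmented_unfolding_fit(stretch) is None
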