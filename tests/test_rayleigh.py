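"""Rayleigh forward model, epsilon fitting, and reductase consistency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nitriso.isotopes import MASS_DEPENDENT_LAMBDA, cap_delta17o
from nitriso.rayleigh import (
    RayleighFit,
    classify_reductase,
    dual_isotope_proportionality,
    epsilon_in_literature_range,
    fit_epsilon,
    fit_rayleigh,
    rayleigh_forward,
)


class TestForward:
    def test_no_consumption_returns_initial(self):
        assert rayleigh_forward(6.1, -17.5, 1.0, "exact") == pytest.approx(6.1)
        assert rayleigh_forward(6.1, -17.5, 1.0, "approximate") == pytest.approx(6.1)

    def test_zero_epsilon_is_inert(self):
        assert rayleigh_forward(12.3, 0.0, 0.2, "exact") == pytest.approx(12.3)

    def test_half_consumed_reference_values(self):
        assert rayleigh_forward(0.0, -17.5, 0.5, "approximate") == pytest.approx(
            12.13, abs=5e-3
        )
        assert rayleigh_forward(0.0, -17.5, 0.5, "exact") == pytest.approx(
            12.204, abs=1e-3
        )

    def test_fully_consumed_pool_rejected(self):
        with pytest.raises(ValueError):
            rayleigh_forward(0.0, -17.5, 0.0)
        with pytest.raises(ValueError):
            rayleigh_forward(0.0, -17.5, -0.2)

    @given(f=st.floats(0.01, 0.99))
    @settings(max_examples=100, derandomize=True)
    def test_residual_enrichment_monotone_for_normal_kie(self, f):
        more_consumed = rayleigh_forward(2.0, -17.5, f, "exact")
        less_consumed = rayleigh_forward(2.0, -17.5, min(f + 0.01, 1.0), "exact")
        assert more_consumed > less_consumed

    @given(
        eps=st.floats(-30, -0.5),
        f=st.floats(0.3, 1.0),
        delta0=st.floats(-5, 25),
    )
    @settings(max_examples=200, derandomize=True)
    def test_exact_and_approximate_agree_to_second_order(self, eps, f, delta0):
        """The forms differ by the curvature term (eps*ln f)^2/2000 plus a
        delta0 cross-term; both are per-mil-scale small."""
        exact = rayleigh_forward(delta0, eps, f, "exact")
        approx = rayleigh_forward(delta0, eps, f, "approximate")
        x = abs(eps * np.log(f))
        bound = (0.7 * x**2 + 1.1 * abs(delta0) * x) / 1000.0 + 1e-9
        assert abs(exact - approx) <= bound

    @pytest.mark.parametrize("eps", [-30.0, -17.5, -4.5])
    @pytest.mark.parametrize("f", [0.4, 0.6, 0.8, 1.0])
    def test_forms_agree_within_015_for_moderate_enrichment(self, eps, f):
        exact = rayleigh_forward(0.0, eps, f, "exact")
        approx = rayleigh_forward(0.0, eps, f, "approximate")
        if abs(eps * np.log(f)) <= 17.0:  # the small-curvature regime
            assert abs(exact - approx) < 0.15

    def test_anomaly_invariant_under_mass_dependent_fractionation(self):
        """Jointly fractionating delta17O/delta18O with 17e = 0.52*18e
        leaves the anomaly unchanged in the matching reference frame."""
        d18o0, cap0 = 21.8, 6.9
        d17o0 = cap0 + MASS_DEPENDENT_LAMBDA * d18o0
        eps18 = -15.9
        eps17 = MASS_DEPENDENT_LAMBDA * eps18
        for f in np.linspace(0.1, 1.0, 10):
            # approximate form <-> linear anomaly frame
            d18 = rayleigh_forward(d18o0, eps18, f, "approximate")
            d17 = rayleigh_forward(d17o0, eps17, f, "approximate")
            assert cap_delta17o(d17, d18, "linear") == pytest.approx(cap0, abs=1e-9)
            # exact form <-> logarithmic anomaly frame
            d18 = rayleigh_forward(d18o0, eps18, f, "exact")
            d17 = rayleigh_forward(d17o0, eps17, f, "exact")
            assert cap_delta17o(d17, d18, "log") == pytest.approx(
                cap_delta17o(d17o0, d18o0, "log"), abs=1e-9
            )


class TestFitEpsilon:
    def test_noiseless_round_trip_is_exact(self):
        f = np.array([1.0, 0.8, 0.6, 0.4, 0.2])
        deltas = rayleigh_forward(2.0, -17.5, f, "approximate")
        eps, intercept, r2 = fit_epsilon(100.0 * f, deltas)
        assert eps == pytest.approx(-17.5, abs=1e-9)
        assert intercept == pytest.approx(2.0, abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_constant_deltas_give_zero_epsilon(self):
        eps, _, _ = fit_epsilon([100, 60, 30, 10], [5.0, 5.0, 5.0, 5.0])
        assert eps == pytest.approx(0.0, abs=1e-12)

    def test_seeded_noise_recovery_within_one_permil(self):
        from nitriso.synthetic import generate_rayleigh_series

        conc, deltas = generate_rayleigh_series(
            2.0, -17.5, np.linspace(0.05, 1.0, 20), noise_sd=0.1, seed=42
        )
        eps, _, _ = fit_epsilon(conc, deltas)
        assert eps == pytest.approx(-17.5, abs=1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_epsilon([100, 50], [1.0, 2.0])
        with pytest.raises(ValueError):
            fit_epsilon([50, 50, 50], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fit_epsilon([100, -5, 10], [1.0, 2.0, 3.0])

    def test_c0_choice_shifts_only_the_intercept(self):
        f = np.array([0.9, 0.5, 0.3, 0.1])
        deltas = rayleigh_forward(0.0, -10.0, f, "approximate")
        e_a, b_a, _ = fit_epsilon(100 * f, deltas, c0=100.0)
        e_b, b_b, _ = fit_epsilon(100 * f, deltas, c0=50.0)
        assert e_a == pytest.approx(e_b, abs=1e-9)
        assert b_a != pytest.approx(b_b, abs=1e-3)


class TestDualProportionality:
    def test_identical_series_have_unit_slope(self):
        d = [1.0, 5.0, 9.0, 14.0]
        slope, _, _ = dual_isotope_proportionality(d, d)
        assert slope == pytest.approx(1.0)

    def test_exact_linear_construction(self):
        d15 = np.array([0.0, 4.0, 9.0, 15.0, 22.0])
        slope, intercept, r2 = dual_isotope_proportionality(d15, 0.91 * d15 + 3)
        assert slope == pytest.approx(0.91, abs=1e-12)
        assert intercept == pytest.approx(3.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_noisy_nap_slope_recovered(self):
        rng = np.random.default_rng(7)
        d15 = np.linspace(0, 30, 50)
        d18 = 0.55 * d15 + 0.3 * rng.standard_normal(50)
        slope, _, _ = dual_isotope_proportionality(d15, d18)
        assert slope == pytest.approx(0.55, abs=0.05)

    def test_major_axis_option(self):
        d15 = np.array([0.0, 5.0, 10.0, 20.0])
        slope, intercept, _ = dual_isotope_proportionality(
            d15, 0.91 * d15 + 1, method="major_axis"
        )
        assert slope == pytest.approx(0.91, abs=1e-9)
        assert intercept == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            dual_isotope_proportionality([1, 2], [1, 2])


class TestReductaseInterpretation:
    @pytest.mark.parametrize(
        "slope,expected",
        [
            (1.0, "Nar-consistent"),
            (0.91, "Nar-consistent"),
            (0.55, "Nap-consistent"),
            (0.73, "ambiguous"),
            (0.2, "ambiguous"),
        ],
    )
    def test_classification(self, slope, expected):
        assert classify_reductase(slope) == expected

    def test_nonfinite_slope_rejected(self):
        with pytest.raises(ValueError):
            classify_reductase(float("nan"))

    @pytest.mark.parametrize(
        "eps,enzyme,expected",
        [
            (-17.5, "Nar", True),
            (-4.5, "Nar", False),
            (-39.8, "Nap", True),
            (-40.0, "Nap", False),
            (-6.6, "Nar", True),
        ],
    )
    def test_literature_ranges_inclusive(self, eps, enzyme, expected):
        assert epsilon_in_literature_range(eps, enzyme) is expected

    def test_unknown_enzyme_rejected(self):
        with pytest.raises(ValueError):
            epsilon_in_literature_range(-10.0, "Nir")


class TestRayleighFit:
    def test_joint_fit_consistency(self):
        f = np.linspace(0.1, 1.0, 8)
        d15 = rayleigh_forward(2.0, -17.5, f, "approximate")
        d18 = rayleigh_forward(5.0, -17.5 * 0.91, f, "approximate")
        fit = fit_rayleigh(120 * f, d15, d18)
        assert fit.epsilon15 == pytest.approx(-17.5, abs=1e-9)
        assert fit.proportionality == pytest.approx(0.91, abs=1e-9)
        assert fit.reductase_label == "Nar-consistent"
        assert fit.n == 8

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            RayleighFit(
                epsilon15=-10, epsilon18=-9.1, proportionality=0.5,
                intercept15=0, intercept18=0, r2_15=1, r2_18=1, r2_dual=1,
                n=5, reductase_label="ambiguous",
            )
        with pytest.raises(ValueError):
            RayleighFit(
                epsilon15=-10, epsilon18=-9.1, proportionality=0.91,
                intercept15=0, intercept18=0, r2_15=1, r2_18=1, r2_dual=1,
                n=2, reductase_label="ambiguous",
            )
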