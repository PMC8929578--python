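import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from ononis_cns.pampa import (
    PampaGeometry,
    PampaResult,
    PampaWell,
    StandardCompound,
    aggregate_pampa,
    analyze_well,
    calibrate_standards,
    classify_bbb,
    effective_permeability,
    log_pe,
    membrane_retention,
    retention_factor,
    skeleton_mean_MR,
)
from ononis_cns.synthetic import gen_standards, simulate_pampa_transport


def ode_forward(true_pe, true_mr, g, c_d0=1e-7):
    """Independent oracle: integrate the two-compartment transport ODE."""
    mobile0 = c_d0 * (1.0 - true_mr)

    def rhs(_t, y):
        cd, ca = y
        flux = true_pe * g.A * (cd - ca)
        return [-flux / g.V_D, flux / g.V_A]

    sol = solve_ivp(
        rhs, (0.0, g.t - g.tau_ss), [mobile0, 0.0], rtol=1e-10, atol=1e-18
    )
    return sol.y[0, -1], sol.y[1, -1]


class TestRetentionFactor:
    def test_unretained_marker(self):
        assert retention_factor(1.0, 1.0) == 0.0

    def test_hand_value(self):
        assert retention_factor(3.0, 1.0) == 2.0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            retention_factor(0.5, 1.0)
        with pytest.raises(ValueError):
            retention_factor(1.0, 0.0)


class TestMembraneRetention:
    def test_no_transport_no_retention(self, geometry):
        w = PampaWell(C_D0=1.0, C_Dt=1.0, C_At=0.0)
        assert membrane_retention(w, geometry) == 0.0

    def test_hand_evaluated_mass_balance(self):
        g = PampaGeometry(V_D=0.15, V_A=0.18)  # V_A/V_D = 1.2
        w = PampaWell(C_D0=1.0, C_Dt=0.5, C_At=0.25)
        assert membrane_retention(w, g) == pytest.approx(0.2)

    def test_everything_retained(self, geometry):
        w = PampaWell(C_D0=1.0, C_Dt=0.0, C_At=0.0)
        assert membrane_retention(w, geometry) == 1.0

    def test_small_negative_clamped_with_warning(self, geometry):
        w = PampaWell(C_D0=1.0, C_Dt=1.01, C_At=0.0)
        with pytest.warns(UserWarning, match="clamped"):
            assert membrane_retention(w, geometry) == 0.0

    def test_gross_mass_balance_violation_is_an_error(self, geometry):
        w = PampaWell(C_D0=1.0, C_Dt=1.2, C_At=0.1, compound_id="x")
        with pytest.raises(ValueError, match="mass balance"):
            membrane_retention(w, geometry)


class TestEffectivePermeability:
    def test_zero_acceptor_means_zero_permeability(self, geometry):
        w = PampaWell(C_D0=1e-7, C_Dt=1e-7, C_At=0.0)
        assert effective_permeability(w, geometry, 0.0) == 0.0

    def test_agrees_with_ode_oracle(self, geometry):
        """Closed-form inversion matches numerical integration of the
        donor/acceptor transport model."""
        true_pe, true_mr = 2.5e-6, 0.2
        cd, ca = ode_forward(true_pe, true_mr, geometry)
        w = PampaWell(C_D0=1e-7, C_Dt=cd, C_At=ca)
        mr = membrane_retention(w, geometry)
        pe = effective_permeability(w, geometry, mr)
        assert mr == pytest.approx(true_mr, rel=1e-6)
        # the printed 2.303 prefactor vs exact ln 10 bounds agreement at ~0.02%
        assert pe == pytest.approx(true_pe, rel=3e-4)

    def test_spec_well_direct_evaluation(self, geometry):
        # C_A/C_D0 = 0.1, MR = 0.2: direct formula evaluation
        w = PampaWell(C_D0=1e-7, C_Dt=0.6e-7, C_At=1e-8)
        arg = 1 - (0.33 / (0.8 * 0.15)) * 0.1
        expected = (
            -2.303 / (0.24 * (14400 - 240)) * (0.18 * 0.15 / 0.33) * math.log10(arg)
        )
        assert effective_permeability(w, geometry, 0.2) == pytest.approx(expected)

    def test_acceptor_above_equilibrium_names_the_well(self, geometry):
        w = PampaWell(C_D0=1.0, C_Dt=0.0, C_At=0.9, compound_id="bad_cpd")
        with pytest.raises(ValueError, match="bad_cpd"):
            effective_permeability(w, geometry, 0.0)

    @given(st.floats(1e-10, 4.4e-8), st.floats(1e-10, 4.4e-8))
    def test_strictly_increasing_in_acceptor_concentration(self, ca1, ca2):
        g = PampaGeometry()
        if ca1 == ca2:
            return
        lo, hi = sorted([ca1, ca2])
        pe_lo = effective_permeability(PampaWell(1e-7, 0.5e-7, lo), g, 0.0)
        pe_hi = effective_permeability(PampaWell(1e-7, 0.5e-7, hi), g, 0.0)
        assert pe_hi > pe_lo

    @pytest.mark.parametrize("true_pe", [1e-7, 1e-6, 1e-5, 1e-4])
    @pytest.mark.parametrize("true_mr", [0.0, 0.2, 0.5, 0.7])
    def test_round_trip_over_parameter_grid(self, geometry, true_pe, true_mr):
        w = simulate_pampa_transport(true_pe, true_mr, geometry, noise_sd=0.0)
        mr = membrane_retention(w, geometry)
        pe = effective_permeability(w, geometry, mr)
        assert mr == pytest.approx(true_mr, abs=1e-12)
        assert pe == pytest.approx(true_pe, rel=1e-9)


class TestLogPe:
    def test_basic_and_inverse(self):
        assert log_pe(1e-6) == -6.0
        assert log_pe(10 ** (-5.60)) == pytest.approx(-5.60)

    def test_printed_pe_value_round_trips_to_printed_log(self):
        # Pe = 2.5e-6 cm/s corresponds to log Pe = -5.60 at 2 d.p.
        assert round(log_pe(2.5e-6), 2) == -5.60

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_pe(0.0)


class TestClassification:
    def test_well_permeating_compound_under_all_schemes(self):
        for scheme in ("konczol", "di", "mensch"):
            assert classify_bbb(-4.45, scheme) == "BBB+"

    def test_borderline_compound_splits_the_schemes(self):
        # log Pe -5.60 (Pe = 2.5e-6 cm/s) sits inside the uncertain zone
        assert classify_bbb(-5.60, "konczol") == "BBB+"
        assert classify_bbb(-5.60, "mensch") == "BBB-"
        assert classify_bbb(-5.60, "di") == "uncertain"

    def test_poorly_permeating_compound(self):
        for scheme in ("konczol", "di", "mensch"):
            assert classify_bbb(-7.0, scheme) == "BBB-"

    def test_boundary_belongs_to_more_permeable_category(self):
        assert classify_bbb(-6.0, "konczol") == "BBB+"
        assert classify_bbb(math.log10(4e-6), "di") == "BBB+"
        assert classify_bbb(math.log10(2e-6), "di") == "uncertain"
        assert classify_bbb(math.log10(4e-6), "mensch") == "BBB+"

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            classify_bbb(-5.0, "nonsense")

    @given(st.floats(-8, -3), st.floats(-8, -3))
    def test_monotone_in_logPe(self, a, b):
        order = {"BBB-": 0, "uncertain": 1, "BBB+": 2}
        lo, hi = sorted([a, b])
        for scheme in ("konczol", "di", "mensch"):
            assert order[classify_bbb(lo, scheme)] <= order[classify_bbb(hi, scheme)]


class TestAggregation:
    def _result(self, logpe, mr=0.3, cid="c"):
        return PampaResult(Pe=10**logpe, logPe=logpe, MR=mr, compound_id=cid)

    def test_identical_wells_have_zero_sd(self):
        agg = aggregate_pampa({"c": [self._result(-5.0)] * 4})
        assert agg["c"].sd_logPe == 0.0
        assert agg["c"].n == 4

    def test_mean_of_two_wells(self):
        agg = aggregate_pampa({"c": [self._result(-5.0), self._result(-4.0)]})
        assert agg["c"].mean_logPe == pytest.approx(-4.5)

    def test_no_cross_compound_pooling(self):
        agg = aggregate_pampa(
            {"a": [self._result(-5.0, cid="a")], "b": [self._result(-4.0, cid="b")]}
        )
        assert agg["a"].mean_logPe == -5.0
        assert agg["b"].mean_logPe == -4.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            aggregate_pampa({"c": []})


class TestSkeletonMeanMR:
    def test_single_class_mean_in_percent(self):
        out = skeleton_mean_MR({"a": 0.2, "b": 0.2}, {"a": "isoflavone", "b": "isoflavone"})
        assert out == {"isoflavone": pytest.approx(20.0)}

    def test_isoflavanone_pair_averages_to_class_value(self):
        out = skeleton_mean_MR(
            {"sativanone": 0.30, "onogenin": 0.36},
            {"sativanone": "isoflavanone", "onogenin": "isoflavanone"},
        )
        assert out["isoflavanone"] == pytest.approx(33.0)

    def test_singleton_class_and_missing_class(self):
        out = skeleton_mean_MR({"m": 0.61}, {"m": "pterocarpan"})
        assert out["pterocarpan"] == pytest.approx(61.0)
        with pytest.raises(ValueError, match="skeleton class"):
            skeleton_mean_MR({"x": 0.5}, {})


class TestCalibration:
    def test_exact_line(self):
        standards = [
            StandardCompound("a", -1.0, -6.0),
            StandardCompound("b", 0.0, -5.0),
            StandardCompound("c", 1.0, -4.0),
        ]
        cal = calibrate_standards(standards)
        assert cal.slope == pytest.approx(1.0)
        assert cal.intercept == pytest.approx(-5.0)
        assert cal.r_squared == pytest.approx(1.0)

    def test_outlier_matches_normal_equation_oracle(self):
        standards = gen_standards(slope=0.8, intercept=-5.2, scatter_sd=0.0, seed=0)
        # perturb one standard into an outlier
        s0 = standards[0]
        standards[0] = StandardCompound(s0.name, s0.logBB_literature, s0.logPe + 0.8)
        cal = calibrate_standards(standards)
        x = np.array([s.logBB_literature for s in standards])
        y = np.array([s.logPe for s in standards])
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)  # closed-form OLS oracle
        ss_res = float(((y - X @ beta) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        assert cal.slope == pytest.approx(beta[0])
        assert cal.intercept == pytest.approx(beta[1])
        assert cal.r_squared == pytest.approx(1 - ss_res / ss_tot)
        assert cal.r_squared < 1.0

    def test_degenerate_predictor_rejected(self):
        standards = [StandardCompound(str(i), 0.5, -5.0 + i) for i in range(4)]
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_standards(standards)

    def test_too_few_standards_rejected(self):
        with pytest.raises(ValueError):
            calibrate_standards([StandardCompound("a", 0.0, -5.0)] * 2)


class TestAnalyzeWell:
    def test_full_well_analysis_with_scheme_verdicts(self, geometry):
        w = simulate_pampa_transport(1e-5, 0.3, geometry, compound_id="demo")
        res = analyze_well(w, geometry)
        assert res.MR == pytest.approx(0.3, abs=1e-12)
        assert res.logPe == pytest.approx(-5.0, abs=1e-9)
        assert res.classifications == {"konczol": "BBB+", "di": "BBB+", "mensch": "BBB+"}

    def test_ordering_of_skeleton_classes_on_panel_values(self, characterized):
        """Mean log Pe orders pterocarpans > isoflavanones > isoflavones."""
        by_class: dict[str, list[float]] = {}
        for rec in characterized.values():
            by_class.setdefault(rec.skeleton_class, []).append(rec.logPe)
        means = {k: np.mean(v) for k, v in by_class.items()}
        assert means["pterocarpan"] > means["isoflavanone"] > means["isoflavone"]
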