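"""Structural two-compartment infusion model and covariate machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import levipop as lp
from conftest import ode_concentrations


class TestTypicalClearance:
    def test_anchor_values_at_120_and_240(self):
        # the covariate equation predicts 4.5 and 9.2 L/h at the two
        # renal-function anchors (one-decimal rounding)
        assert round(lp.typical_clearance(120.0), 1) == 4.5
        assert round(lp.typical_clearance(240.0), 1) == 9.2

    def test_construction_identity_at_center(self):
        p = lp.published_params()
        assert lp.typical_clearance(120.0, p) == pytest.approx(p.theta_nr + 1.0)

    def test_direct_arithmetic_at_80(self):
        assert lp.typical_clearance(80.0) == pytest.approx(3.5 + (80 / 120) ** 2.5)

    def test_rejects_nonpositive_crcl(self):
        with pytest.raises(ValueError):
            lp.typical_clearance(0.0)
        with pytest.raises(ValueError):
            lp.typical_clearance(-10.0)


class TestMicroConstants:
    def test_against_eigenvalue_oracle(self):
        mc = lp.micro_constants(4.5, 20.7, 31.9, 33.5)
        k10, k12, k21 = 4.5 / 20.7, 31.9 / 20.7, 31.9 / 33.5
        A = np.array([[-(k10 + k12), k21], [k12, -k21]])
        eig = np.sort(np.linalg.eigvals(A))  # -alpha < -beta
        assert mc.alpha == pytest.approx(-eig[0], rel=1e-12)
        assert mc.beta == pytest.approx(-eig[1], rel=1e-12)

    @given(
        cl=st.floats(0.5, 20), v1=st.floats(5, 60),
        q=st.floats(1, 80), v2=st.floats(5, 100),
    )
    @settings(max_examples=60, deadline=None)
    def test_root_identities(self, cl, v1, q, v2):
        mc = lp.micro_constants(cl, v1, q, v2)
        assert mc.alpha >= mc.beta > 0
        assert mc.alpha + mc.beta == pytest.approx(mc.k10 + mc.k12 + mc.k21, rel=1e-9)
        assert mc.alpha * mc.beta == pytest.approx(mc.k10 * mc.k21, rel=1e-9)
        assert mc.coef_a + mc.coef_b == pytest.approx(1.0, abs=1e-12)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            lp.micro_constants(0.0, 20.7, 31.9, 33.5)


class TestConcProfile:
    def test_zero_dose_gives_zero_profile(self):
        reg = lp.DosingRegimen(dose=0.0, tau=12, infusion_duration=0.5, n_doses=3)
        t = np.linspace(0, 36, 20)
        assert np.all(lp.conc_profile(4.5, 20.7, 31.9, 33.5, reg, t) == 0)

    def test_dose_linearity_exact(self):
        t = np.linspace(0.1, 24, 40)
        reg1 = lp.DosingRegimen(1000, 12, 0.5, n_doses=2)
        reg3 = lp.DosingRegimen(3000, 12, 0.5, n_doses=2)
        c1 = lp.conc_profile(4.5, 20.7, 31.9, 33.5, reg1, t)
        c3 = lp.conc_profile(4.5, 20.7, 31.9, 33.5, reg3, t)
        np.testing.assert_allclose(c3, 3.0 * c1, rtol=1e-13)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_ode_oracle_on_random_parameters(self, seed):
        rng = np.random.default_rng(seed)
        cl = rng.uniform(1, 15)
        v1 = rng.uniform(8, 50)
        q = rng.uniform(5, 60)
        v2 = rng.uniform(10, 80)
        t = np.linspace(0.05, 12, 30)
        closed = lp.conc_profile(cl, v1, q, v2,
                                 lp.DosingRegimen(1000, 12, 0.5, n_doses=1), t)
        ode = ode_concentrations(cl, v1, q, v2, 1000, 0.5, t)
        np.testing.assert_allclose(closed, ode, rtol=1e-4)

    def test_superposition_reaches_steady_state(self):
        # concentration 12 h after the 50th dose matches the closed-form
        # steady-state value within 0.1%
        cl = lp.typical_clearance(120.0)
        t_obs = 49 * 12.0 + 12.0
        sup = lp.conc_profile(cl, 20.7, 31.9, 33.5,
                              lp.DosingRegimen(1000, 12, 0.5, n_doses=50), [t_obs])[0]
        ss = lp.conc_steady_state(cl, 20.7, 31.9, 33.5,
                                  lp.DosingRegimen(1000, 12, 0.5), 12.0)
        assert sup == pytest.approx(ss, rel=1e-3)


class TestConcSteadyState:
    def test_periodic_boundary(self):
        reg = lp.DosingRegimen(1000, 12, 0.5)
        c0 = lp.conc_steady_state(4.5, 20.7, 31.9, 33.5, reg, 0.0)
        ctau = lp.conc_steady_state(4.5, 20.7, 31.9, 33.5, reg, 12.0)
        assert c0 == pytest.approx(ctau, rel=1e-12)

    def test_washout_limit_for_long_interval(self):
        reg = lp.DosingRegimen(1000, 2000.0, 0.5)
        assert lp.conc_steady_state(4.5, 20.7, 31.9, 33.5, reg, 2000.0) < 1e-10

    def test_rejects_time_outside_interval(self):
        reg = lp.DosingRegimen(1000, 12, 0.5)
        with pytest.raises(ValueError):
            lp.conc_steady_state(4.5, 20.7, 31.9, 33.5, reg, 12.5)

    def test_trough_monotone_in_clearance_and_dose(self):
        reg = lp.DosingRegimen(1000, 12, 0.5)
        troughs = [lp.conc_steady_state(cl, 20.7, 31.9, 33.5, reg, 12.0)
                   for cl in (2.0, 4.0, 8.0, 16.0)]
        assert all(a > b for a, b in zip(troughs, troughs[1:]))
        by_dose = [lp.conc_steady_state(4.5, 20.7, 31.9, 33.5,
                                        lp.DosingRegimen(d, 12, 0.5), 12.0)
                   for d in (500, 1000, 1500, 2000)]
        assert all(a < b for a, b in zip(by_dose, by_dose[1:]))

    def test_terminal_slope_is_minus_beta(self):
        mc = lp.micro_constants(4.5, 20.7, 31.9, 33.5)
        t = np.linspace(30, 60, 50)
        c = lp.conc_profile(4.5, 20.7, 31.9, 33.5,
                            lp.DosingRegimen(1000, 12, 0.5, n_doses=1), t)
        slope = np.polyfit(t, np.log(c), 1)[0]
        assert -slope == pytest.approx(mc.beta, rel=1e-3)


class TestApplyCovariates:
    def _covs(self, **kw):
        defaults = dict(crcl=120.0, diagnosis="other")
        defaults.update(kw)
        return lp.SubjectCovariates(**defaults)

    def test_empty_model_is_identity(self):
        p = lp.published_params()
        out = lp.apply_covariates(p, lp.CovariateModel(), self._covs())
        assert out == {"cl": p.theta_nr, "v1": p.v1, "q": p.q, "v2": p.v2}

    def test_published_effect_reproduces_typical_clearance(self):
        p = lp.published_params()
        model = lp.published_covariate_model(p)
        for crcl in (54.0, 117.0, 239.0):
            out = lp.apply_covariates(p, model, self._covs(crcl=crcl))
            assert out["cl"] == pytest.approx(lp.typical_clearance(crcl, p))

    def test_centring_identity_at_median(self):
        out = lp.apply_covariates(
            lp.published_params(), lp.published_covariate_model(), self._covs(crcl=120.0)
        )
        assert out["cl"] == pytest.approx(3.5 + 1.0)

    def test_shift_leaves_reference_category_unchanged(self):
        eff = lp.CovariateEffect("v1", "diagnosis", "shift",
                                 coef=0.4, category="trauma")
        p = lp.published_params()
        out = lp.apply_covariates(p, lp.CovariateModel((eff,)),
                                  self._covs(diagnosis="other"))
        assert out["v1"] == p.v1
        out_t = lp.apply_covariates(p, lp.CovariateModel((eff,)),
                                    self._covs(diagnosis="trauma"))
        assert out_t["v1"] == pytest.approx(p.v1 * 1.4)

    def test_missing_covariate_raises_named_error(self):
        eff = lp.CovariateEffect("v1", "apache2", "linear", center=18.0, coef=0.01)
        with pytest.raises(ValueError, match="apache2"):
            lp.apply_covariates(lp.published_params(), lp.CovariateModel((eff,)),
                                self._covs(apache2=None))

    def test_theta_r_zero_gives_constant_renal_term(self):
        p = lp.PKParams(theta_r=1e-12)
        for crcl in (60.0, 120.0, 200.0):
            assert lp.typical_clearance(crcl, p) == pytest.approx(p.theta_nr + 1.0)
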