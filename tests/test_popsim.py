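"""Population simulation: log-normal IIV, residual error, study replication."""

import numpy as np
import pytest

import levipop as lp


def _covs(crcl=120.0):
    return lp.SubjectCovariates(crcl=crcl)


class TestSampleIndividual:
    def test_zero_iiv_returns_typical_values(self, published_bundle):
        omega0 = lp.OmegaSpec(terms={"cl": 0.0, "v1": 0.0})
        ind = lp.sample_individual(published_bundle.params,
                                   published_bundle.covariates, omega0,
                                   _covs(), np.random.default_rng(0))
        assert ind.cl == pytest.approx(lp.typical_clearance(120.0))
        assert ind.v1 == pytest.approx(20.7)

    def test_lognormal_median_and_log_sd(self, published_bundle):
        rng = np.random.default_rng(123)
        eta = lp.sample_etas(published_bundle.omega, 100_000, rng)
        cl = lp.typical_clearance(120.0) * np.exp(eta[:, 0])
        # log-normal median equals the typical value
        assert np.median(cl) == pytest.approx(4.5, rel=0.01)
        assert np.std(np.log(cl), ddof=1) == pytest.approx(0.327, rel=0.02)
        assert np.std(eta[:, 1], ddof=1) == pytest.approx(0.561, rel=0.02)
        assert abs(np.mean(eta[:, 0])) < 0.01

    def test_non_psd_omega_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            lp.OmegaSpec(terms={"cl": 0.3, "v1": 0.5},
                         correlations={("cl", "v1"): 1.5})


class TestSimulateObservations:
    def test_noise_off_returns_structural_predictions(self, typical_individual):
        times = np.array([0.5, 2.0, 6.0, 12.0])
        reg = lp.DosingRegimen(1000, 12, 0.5)
        prof = lp.simulate_observations(typical_individual, reg, times,
                                        lp.ResidualSpec(), include_residual=False)
        expected = lp.conc_profile(typical_individual.cl, 20.7, 31.9, 33.5, reg, times)
        np.testing.assert_allclose(prof.dv, expected)
        np.testing.assert_allclose(prof.pred, expected)

    def test_proportional_error_magnitude(self, typical_individual):
        rng = np.random.default_rng(7)
        reg = lp.DosingRegimen(1000, 12, 0.5)
        times = np.full(100_000, 2.0)
        prof = lp.simulate_observations(typical_individual, reg, times,
                                        lp.ResidualSpec(sigma_prop=0.223), rng)
        ratio = prof.dv / prof.pred - 1.0
        assert np.std(ratio, ddof=1) == pytest.approx(0.223, rel=0.02)

    def test_zero_prediction_stays_zero_under_multiplicative_error(self):
        ind = lp.IndividualParams("x", (0.0, 0.0), 4.5, 20.7, 31.9, 33.5, 120.0)
        reg = lp.DosingRegimen(1000, 12, 0.5, n_doses=1)
        prof = lp.simulate_observations(ind, reg, [0.0], lp.ResidualSpec(),
                                        np.random.default_rng(1))
        assert prof.dv[0] == 0.0


class TestSimulateStudy:
    def test_same_seed_reproduces_dataset(self, published_bundle):
        d1 = lp.simulate_study(lp.StudyDesign(), published_bundle, seed=11)
        d2 = lp.simulate_study(lp.StudyDesign(), published_bundle, seed=11)
        assert d1.records == d2.records
        assert d1.subjects == d2.subjects

    def test_observation_count_near_cohort_total(self, study_27):
        # 27 subjects x 6 samples minus four dropped samples = 158 before
        # LLOQ censoring; censoring removes at most a handful
        assert study_27.n_subjects == 27
        assert 140 <= study_27.n_observations <= 158
        per_subject = [sum(1 for r in study_27.records_for(s)
                           if r.kind == "observation")
                       for s in study_27.subject_ids]
        assert max(per_subject) <= 6

    def test_no_variability_collapses_to_identical_profiles(self):
        bundle = lp.ModelBundle(
            omega=lp.OmegaSpec(terms={"cl": 0.0, "v1": 0.0}),
            residual=lp.ResidualSpec(kind="additive", sigma_prop=0.0, sigma_add=0.0),
        )
        design = lp.StudyDesign(
            n_subjects=4, dose_allocation={500.0: 4},
            sampling_windows=(0.5, 2.0, 6.0, 12.0), n_five_sample_subjects=0,
            bloq_policy="lloq_half",
        )
        ds = lp.generate_study(design, bundle, seed=3)
        # force equal covariates post hoc is impossible; instead check that
        # predictions depend only on CrCl by comparing two same-CrCl subjects
        sid0 = ds.subject_ids[0]
        covs = ds.subjects[sid0]
        ind1 = lp.sample_individual(bundle.params, bundle.covariates,
                                    bundle.omega, covs,
                                    np.random.default_rng(0), "a")
        ind2 = lp.sample_individual(bundle.params, bundle.covariates,
                                    bundle.omega, covs,
                                    np.random.default_rng(99), "b")
        t = np.array([0.5, 2.0, 6.0, 12.0])
        reg = lp.DosingRegimen(500, 12, 0.5)
        p1 = lp.simulate_observations(ind1, reg, t, bundle.residual,
                                      include_residual=False).dv
        p2 = lp.simulate_observations(ind2, reg, t, bundle.residual,
                                      include_residual=False).dv
        np.testing.assert_allclose(p1, p2)

    def test_simulated_trough_median_matches_typical(self, published_bundle):
        rng = np.random.default_rng(2024)
        eta = lp.sample_etas(published_bundle.omega, 40_000, rng)
        cl = lp.typical_clearance(120.0) * np.exp(eta[:, 0])
        v1 = 20.7 * np.exp(eta[:, 1])
        from levipop.model import conc_ss

        troughs = conc_ss(cl, v1, 31.9, 33.5, 1000.0, 0.5, 12.0, 12.0)
        typical = lp.conc_steady_state(lp.typical_clearance(120.0), 20.7, 31.9,
                                       33.5, lp.DosingRegimen(1000, 12, 0.5), 12.0)
        # trough is monotone in the individual parameters, so the median
        # trough tracks the median (typical) parameters closely
        assert np.median(troughs) == pytest.approx(typical, rel=0.05)


class TestStreams:
    def test_purpose_streams_are_independent_of_toggles(self):
        s1 = lp.split_streams(99, ["eta", "eps"])
        s2 = lp.split_streams(99, ["eta", "eps"])
        a = s1["eta"].normal(size=5)
        s1["eps"].normal(size=1000)  # consuming eps must not move eta
        b = s2["eta"].normal(size=5)
        np.testing.assert_array_equal(a, b)
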