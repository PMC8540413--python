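"""FOCE-I objective, fit, stepwise covariate search, bootstrap mechanics."""

import numpy as np
import pytest

import levipop as lp
from levipop.estimate import foce_objective


class TestFoceObjectiveClosedForms:
    def test_no_iiv_additive_error_is_weighted_least_squares(self):
        # with k=0 random effects the objective must equal the plain
        # Gaussian -2LL (without the 2*pi constant) of independent residuals
        rng = np.random.default_rng(0)
        y = rng.normal(10.0, 1.0, size=12)
        f = np.full(12, 10.0)
        sigma = 1.3
        ofv = foce_objective(lambda e: f, y, np.repeat(np.arange(3), 4), 3,
                             np.array([]), lambda fv: np.full_like(fv, sigma**2))
        expected = np.sum((y - f) ** 2 / sigma**2 + np.log(sigma**2))
        assert ofv == pytest.approx(expected, rel=1e-12)

    def test_linear_mixed_model_matches_exact_likelihood(self):
        # one-parameter linear model with additive IIV and additive error is
        # linear in eta, so FOCE is exact; compare with the closed-form
        # marginal normal likelihood V = sigma^2 I + omega^2 J
        rng = np.random.default_rng(42)
        n_subj, n_obs = 3, 4
        theta, omega, sigma = 10.0, 2.0, 1.5
        obs_subj = np.repeat(np.arange(n_subj), n_obs)
        y = theta + np.repeat(rng.normal(0, omega, n_subj), n_obs) \
            + rng.normal(0, sigma, n_subj * n_obs)

        def predict(eta):
            return theta + eta[obs_subj, 0]

        ofv = foce_objective(predict, y, obs_subj, n_subj, np.array([omega]),
                             lambda f: np.full_like(f, sigma**2))
        expected = 0.0
        V = sigma**2 * np.eye(n_obs) + omega**2 * np.ones((n_obs, n_obs))
        sign, logdet = np.linalg.slogdet(V)
        for i in range(n_subj):
            r = y[obs_subj == i] - theta
            expected += logdet + r @ np.linalg.solve(V, r)
        assert ofv == pytest.approx(expected, rel=1e-6)

    def test_true_parameters_beat_doubled_clearance(self, published_bundle):
        ds = lp.generate_study(lp.StudyDesign.scaled(100), published_bundle,
                               seed=100)
        ofv_true = lp.ofv_foce(ds, published_bundle)
        wrong = lp.ModelBundle(
            params=lp.PKParams(theta_nr=7.0, theta_r=2.5, v1=20.7, q=31.9, v2=33.5),
            omega=published_bundle.omega, residual=published_bundle.residual,
        )
        # doubled base clearance (and hence roughly doubled CL) must be worse
        assert lp.ofv_foce(ds, wrong) > ofv_true


class TestOfvInvariances:
    def test_invariant_to_subject_relabelling_and_record_order(self, study_27,
                                                               published_bundle):
        base = lp.ofv_foce(study_27, published_bundle)
        # relabel subjects in reverse lexical order and rebuild
        mapping = {s: f"Z{idx:03d}" for idx, s in
                   enumerate(reversed(study_27.subject_ids))}
        records = [
            lp.EventRecord(subject_id=mapping[r.subject_id], time=r.time,
                           kind=r.kind, amount=r.amount,
                           infusion_duration=r.infusion_duration, ss=r.ss,
                           tau=r.tau, concentration=r.concentration,
                           bloq_flag=r.bloq_flag)
            for r in study_27.records
        ]
        order = sorted(range(len(records)),
                       key=lambda i: (records[i].subject_id, records[i].time,
                                      records[i].kind))
        ds2 = lp.PKDataset(records=[records[i] for i in order],
                           subjects={mapping[s]: c
                                     for s, c in study_27.subjects.items()})
        assert lp.ofv_foce(ds2, published_bundle) == pytest.approx(base, abs=1e-4)


@pytest.fixture(scope="module")
def small_study(published_bundle):
    """10-subject study for fast fit mechanics tests."""
    return lp.generate_study(lp.StudyDesign.scaled(10), published_bundle, seed=55)


@pytest.fixture(scope="module")
def small_fit(small_study, published_bundle):
    return lp.fit(small_study, published_bundle, compute_se=False)


class TestFit:
    def test_refit_from_converged_estimates_is_stable(self, small_study, small_fit):
        again = lp.fit(small_study, small_fit.bundle, compute_se=False)
        assert abs(again.ofv - small_fit.ofv) < 0.1

    def test_nested_model_never_beats_its_extension_at_optimum(self, small_study,
                                                               published_bundle):
        # the base model (no covariate) is a special case of the covariate
        # model, so the extended fit cannot have a larger OFV (monotone
        # likelihood), up to optimiser tolerance
        base = lp.ModelBundle(
            params=published_bundle.params, covariates=lp.CovariateModel(),
            omega=published_bundle.omega, residual=published_bundle.residual,
        )
        fit_base = lp.fit(small_study, base, compute_se=False)
        fit_full = lp.fit(small_study, published_bundle, compute_se=False)
        assert fit_full.ofv <= fit_base.ofv + 0.5

    def test_no_signal_data_shrinks_iiv_estimates(self):
        gen = lp.ModelBundle(
            omega=lp.OmegaSpec(terms={"cl": 0.0, "v1": 0.0}),
            residual=lp.ResidualSpec(sigma_prop=0.05),
        )
        ds = lp.generate_study(lp.StudyDesign.scaled(15), gen, seed=6)
        init = lp.ModelBundle(
            omega=lp.OmegaSpec(terms={"cl": 0.2, "v1": 0.2}),
            residual=lp.ResidualSpec(sigma_prop=0.1),
        )
        res = lp.fit(ds, init, compute_se=False)
        assert res.estimates["omega_cl"] < 0.08
        assert res.estimates["omega_v1"] < 0.12

    def test_shrinkage_definition(self, small_fit):
        ebe = small_fit.ebe["eta_cl"].to_numpy()
        om = small_fit.estimates["omega_cl"]
        expected = 100.0 * (1.0 - np.std(ebe, ddof=1) / om)
        assert small_fit.eta_shrinkage_pct["cl"] == pytest.approx(expected)


class TestScm:
    def test_empty_candidate_list_returns_base_model(self, small_study,
                                                     published_bundle):
        cfg = lp.SCMConfig(candidates=())
        final, log = lp.scm(small_study, published_bundle, cfg)
        assert tuple((e.parameter, e.covariate) for e in final.covariates) == \
               tuple((e.parameter, e.covariate) for e in published_bundle.covariates)
        assert log.empty

    def test_gate_order_constraint(self):
        with pytest.raises(ValueError):
            lp.SCMConfig(candidates=(), forward_delta=7.0, backward_delta=3.84)


class TestBootstrap:
    def test_single_replicate_percentiles_collapse(self, small_study, small_fit):
        bs = lp.bootstrap(small_study, small_fit.bundle, 1, seed=2)
        assert bs.n_replicates == 1
        for p in bs.summary.index:
            assert bs.summary.loc[p, "ci_lo"] == bs.summary.loc[p, "median"]
            assert bs.summary.loc[p, "ci_hi"] == bs.summary.loc[p, "median"]

    def test_identical_seed_identical_resamples(self, small_study, small_fit):
        a = lp.bootstrap(small_study, small_fit.bundle, 2, seed=3)
        b = lp.bootstrap(small_study, small_fit.bundle, 2, seed=3)
        assert a.replicates.equals(b.replicates)
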