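"""Residual diagnostics and the prediction-corrected VPC."""

import numpy as np
import pytest

import levipop as lp
from levipop.diagnostics import cwres, pcvpc


@pytest.fixture(scope="module")
def calibration_study(published_bundle):
    """~600 observations simulated under the published model."""
    return lp.generate_study(lp.StudyDesign.scaled(100), published_bundle,
                             seed=606)


class TestCwres:
    def test_calibrated_under_the_true_model(self, calibration_study,
                                             published_bundle):
        table = cwres(calibration_study, published_bundle)
        res = table["cwres"].to_numpy()
        assert abs(res.mean()) < 0.1
        assert 0.9 <= res.std(ddof=1) <= 1.1

    def test_detects_halved_clearance(self, calibration_study):
        wrong = lp.ModelBundle(
            params=lp.PKParams(theta_nr=1.2, theta_r=1.0, v1=20.7, q=31.9,
                               v2=33.5),
        )
        res = cwres(calibration_study, wrong)["cwres"].to_numpy()
        assert abs(res.mean()) > 0.5

    def test_reduces_to_standardized_residuals_without_iiv(self):
        # no random effects + additive error -> CWRES must equal the
        # classical (y - pred)/sigma
        bundle = lp.ModelBundle(
            omega=lp.OmegaSpec(terms={}),
            residual=lp.ResidualSpec(kind="additive", sigma_prop=0.0,
                                     sigma_add=1.5),
        )
        design = lp.StudyDesign(n_subjects=5, dose_allocation={1000.0: 5},
                                sampling_windows=(0.5, 2.0, 6.0, 12.0),
                                n_five_sample_subjects=0, bloq_policy="lloq_half")
        ds = lp.generate_study(design, bundle, seed=4)
        table = cwres(ds, bundle)
        expected = (table["dv_mg_L"] - table["pred"]) / 1.5
        np.testing.assert_allclose(table["cwres"], expected, rtol=1e-8)

    def test_unity_slope_of_observed_vs_individual_predictions(
            self, calibration_study, published_bundle):
        table = cwres(calibration_study, published_bundle)
        slope = np.polyfit(table["ipred"], table["dv_mg_L"], 1)[0]
        assert 0.95 <= slope <= 1.05


class TestPcvpc:
    def test_median_falls_inside_band_under_true_model(self, calibration_study,
                                                       published_bundle):
        res = pcvpc(calibration_study, published_bundle, n_replicates=400,
                    seed=17)
        t = res.table
        inside = ((t["obs_p50"] >= t["sim_p50_lo"])
                  & (t["obs_p50"] <= t["sim_p50_hi"]))
        assert inside.mean() >= 0.9

    def test_constant_predictions_make_correction_identity(self,
                                                           published_bundle):
        # trough-only design with one shared covariate value: every
        # population prediction is identical, so prediction correction
        # cannot change the observed percentiles
        covs = lp.SubjectCovariates(crcl=120.0)
        rng = np.random.default_rng(3)
        records, subjects = [], {}
        for i in range(30):
            sid = f"S{i}"
            subjects[sid] = covs
            ind = lp.sample_individual(published_bundle.params,
                                       published_bundle.covariates,
                                       published_bundle.omega, covs, rng,
                                       subject_id=sid)
            prof = lp.simulate_observations(ind, lp.DosingRegimen(1000, 12, 0.5),
                                            [12.0], published_bundle.residual,
                                            rng)
            records.append(lp.EventRecord(subject_id=sid, time=0.0, kind="dose",
                                          amount=1000.0, infusion_duration=0.5,
                                          ss=True, tau=12.0))
            records.append(lp.EventRecord(subject_id=sid, time=12.0,
                                          kind="observation",
                                          concentration=float(prof.dv[0])))
        ds = lp.PKDataset(records=records, subjects=subjects)
        res = pcvpc(ds, published_bundle, n_replicates=50, seed=8,
                    bin_edges=(11.0, 12.5))
        dv = np.array([r.concentration for r in ds.observations()])
        assert res.table["obs_p50"].iloc[0] == pytest.approx(np.median(dv))

    def test_single_replicate_bands_collapse(self, calibration_study,
                                             published_bundle):
        res = pcvpc(calibration_study, published_bundle, n_replicates=1, seed=2)
        for q in (10, 50, 90):
            np.testing.assert_allclose(res.table[f"sim_p{q}_lo"],
                                       res.table[f"sim_p{q}_hi"])

    def test_invariant_to_common_rescaling(self, published_bundle):
        # doubling every dose and concentration scales the pc values by the
        # same factor (model linearity), so percentile ratios are preserved
        ds = lp.generate_study(lp.StudyDesign.scaled(30), published_bundle,
                               seed=99)
        res1 = pcvpc(ds, published_bundle, n_replicates=100, seed=5)
        scaled_records = []
        for r in ds.records:
            if r.kind == "dose":
                scaled_records.append(lp.EventRecord(
                    subject_id=r.subject_id, time=r.time, kind="dose",
                    amount=2.0 * r.amount, infusion_duration=r.infusion_duration,
                    ss=r.ss, tau=r.tau))
            else:
                scaled_records.append(lp.EventRecord(
                    subject_id=r.subject_id, time=r.time, kind="observation",
                    concentration=2.0 * r.concentration, bloq_flag=r.bloq_flag))
        ds2 = lp.PKDataset(records=scaled_records, subjects=dict(ds.subjects))
        res2 = pcvpc(ds2, published_bundle, n_replicates=100, seed=5)
        np.testing.assert_allclose(res2.table["obs_p50"],
                                   2.0 * res1.table["obs_p50"], rtol=1e-9)
        np.testing.assert_allclose(res2.table["sim_p50_med"],
                                   2.0 * res1.table["sim_p50_med"], rtol=1e-9)

    def test_band_ordering_invariant(self, calibration_study, published_bundle):
        res = pcvpc(calibration_study, published_bundle, n_replicates=100,
                    seed=21)
        t = res.table
        for q in (10, 50, 90):
            assert (t[f"sim_p{q}_lo"] <= t[f"sim_p{q}_med"]).all()
            assert (t[f"sim_p{q}_med"] <= t[f"sim_p{q}_hi"]).all()
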