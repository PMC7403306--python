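"""Inverse fitting: residual conventions, initial guess, estimator
behaviour, and aggregation across samples."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from lcr import (
    AcquisitionProtocol,
    CavitationRheometer,
    FitParameters,
    FitResult,
    RadiusTimeDataset,
    aggregate_fits,
    circumferential_failure_strain,
    fit_dataset,
    generate_dataset,
    initial_guess,
    residuals,
)

TRUE = FitParameters(r_max=126e-6, eta=20e3, eps_f_rr=0.25, t0=0.0)
NOISELESS = AcquisitionProtocol(radius_noise_sigma=0.0, replicates_per_delay=1, seed=0)


@pytest.fixture(scope="module")
def clean_dataset():
    return generate_dataset(TRUE, protocol=NOISELESS)


@pytest.fixture(scope="module")
def clean_fit(clean_dataset):
    est = CavitationRheometer(fit_time_offset=False)
    est.fit(None, None, dataset=clean_dataset)
    return est


class TestDataset:
    def test_table_round_trip(self, clean_dataset, tmp_path):
        path = tmp_path / "ds.csv"
        clean_dataset.write_csv(path, header_comments=["synthetic fixture"])
        back = RadiusTimeDataset.read_csv(path)
        assert back.sample_id == clean_dataset.sample_id
        np.testing.assert_allclose(back.times, clean_dataset.times, rtol=1e-9)
        np.testing.assert_allclose(back.radii, clean_dataset.radii, rtol=1e-9)
        assert back.checksum() == clean_dataset.checksum()

    def test_split_samples(self, clean_dataset):
        t1 = clean_dataset.to_table()
        t2 = t1.copy()
        t2["sample_id"] = "other"
        datasets = RadiusTimeDataset.split_samples(pd.concat([t1, t2]))
        assert sorted(d.sample_id for d in datasets) == ["other", "synthetic"]

    def test_schema_validation(self):
        with pytest.raises(ValueError, match="missing columns"):
            RadiusTimeDataset.from_table(pd.DataFrame({"time_us": [1.0]}))
        with pytest.raises(ValueError, match="at least one point"):
            RadiusTimeDataset(
                "x",
                pd.DataFrame({"time_s": [], "radius_m": [], "replicate_id": []}),
            )


class TestResiduals:
    def test_self_consistency_zero(self, clean_dataset):
        r = residuals(TRUE, clean_dataset)
        np.testing.assert_allclose(r, 0.0, atol=1e-9)

    def test_shifted_radii_constant_residual(self, clean_dataset):
        shifted = RadiusTimeDataset(
            clean_dataset.sample_id,
            clean_dataset.points.assign(
                radius_m=clean_dataset.points["radius_m"] + 1e-6
            ),
        )
        r = residuals(TRUE, shifted)
        np.testing.assert_allclose(r, -1e-6, atol=1e-9)

    def test_modulus_perturbation_is_identifiable(self, clean_dataset):
        from dataclasses import replace

        r = residuals(replace(TRUE, eta=30e3), clean_dataset)
        assert np.linalg.norm(r) * 1e6 > 1.0  # well above solver noise

    def test_delay_mean_weighting_length(self):
        noisy = generate_dataset(TRUE, protocol=AcquisitionProtocol(seed=0))
        per_point = residuals(TRUE, noisy)
        per_delay = residuals(TRUE, noisy, weighting="delay-mean")
        assert len(per_point) == len(noisy.points)
        assert len(per_delay) == noisy.n_delays()


class TestInitialGuess:
    def test_r_max_from_data(self, clean_dataset):
        init = initial_guess(clean_dataset)
        assert init.r_max == pytest.approx(clean_dataset.radii.max())
        assert init.eps_f_rr == 0.25 and init.t0 == 0.0

    def test_water_like_data_gives_small_modulus(self):
        water = generate_dataset(
            FitParameters(r_max=120e-6, eta=0.0, eps_f_rr=None),
            protocol=NOISELESS,
            mode="elastic",
        )
        init = initial_guess(water)
        assert init.eta < 3e3

    def test_underdetermined_data_rejected(self, clean_dataset):
        small = RadiusTimeDataset(
            "x", clean_dataset.points.iloc[:3].reset_index(drop=True)
        )
        with pytest.raises(ValueError, match="under-determined"):
            initial_guess(small)


class TestEstimator:
    def test_recovers_generating_parameters(self, clean_fit):
        assert clean_fit.r_max_ == pytest.approx(TRUE.r_max, rel=1e-4)
        assert clean_fit.elastic_modulus_ == pytest.approx(TRUE.eta, rel=1e-3)
        assert clean_fit.radial_failure_strain_ == pytest.approx(
            TRUE.eps_f_rr, rel=1e-3
        )
        assert clean_fit.result_.converged

    def test_derived_strain_is_exact_composition(self, clean_fit):
        assert clean_fit.circumferential_failure_strain_ == pytest.approx(
            circumferential_failure_strain(clean_fit.radial_failure_strain_),
            rel=0, abs=0,
        )

    def test_predict_matches_data(self, clean_fit, clean_dataset):
        pred = clean_fit.predict(clean_dataset.times)
        np.testing.assert_allclose(pred, clean_dataset.radii, atol=5e-9)
        assert clean_fit.score(
            clean_dataset.times.reshape(-1, 1), clean_dataset.radii
        ) > 0.999

    def test_replicate_order_invariance(self, clean_dataset):
        shuffled = RadiusTimeDataset(
            clean_dataset.sample_id,
            clean_dataset.points.sample(frac=1.0, random_state=7).reset_index(
                drop=True
            ),
        )
        a = fit_dataset(clean_dataset, fit_time_offset=False)
        b = fit_dataset(shuffled, fit_time_offset=False)
        assert a.params.eta == pytest.approx(b.params.eta, rel=1e-6)
        assert a.params.r_max == pytest.approx(b.params.r_max, rel=1e-8)

    def test_no_failure_mode_freezes_strain(self, clean_dataset):
        res = fit_dataset(clean_dataset, mode="no_failure", fit_time_offset=False)
        assert res.params.eps_f_rr is None
        assert res.eps_f_tt is None
        assert "eps_f_rr" not in res.param_names

    def test_sklearn_protocol(self):
        est = CavitationRheometer(mode="no_failure", rtol=1e-6)
        params = est.get_params()
        assert params["mode"] == "no_failure"
        cloned = clone(est)
        assert cloned.get_params()["rtol"] == 1e-6
        with pytest.raises(AttributeError):
            est.predict([0.0])

    def test_bad_inputs_rejected(self):
        est = CavitationRheometer()
        with pytest.raises(ValueError):
            est.fit([1e-6, 2e-6], [1e-5])
        with pytest.raises(ValueError):
            est.fit([1e-6, np.nan], [1e-5, 1e-5])
        with pytest.raises(ValueError):
            CavitationRheometer(mode="bogus").fit([0, 1e-6, 2e-6, 3e-6],
                                                  [1e-5, 2e-5, 2e-5, 1e-5])


class TestAggregation:
    @staticmethod
    def _result(eta_kpa):
        params = FitParameters(r_max=120e-6, eta=eta_kpa * 1e3, eps_f_rr=0.25)
        return FitResult(
            params=params,
            eps_f_tt=circumferential_failure_strain(0.25),
            residual_norm=0.0,
            per_point_residuals=np.zeros(1),
            n_iter=1,
            status=1,
            message="",
            converged=True,
            covariance=None,
            param_names=("r_max", "eta", "eps_f_rr"),
            sample_id="s",
        )

    def test_single_result_sd_zero(self):
        summary = aggregate_fits([self._result(20.0)])
        assert summary.n_samples == 1
        assert summary.table.loc["eta_kpa", "mean"] == pytest.approx(20.0)
        assert summary.table.loc["eta_kpa", "sd"] == 0.0

    def test_identical_results_sd_zero(self):
        summary = aggregate_fits([self._result(25.0)] * 3)
        assert summary.table.loc["eta_kpa", "sd"] == pytest.approx(0.0)

    def test_hand_computed_mean_and_sd(self):
        summary = aggregate_fits([self._result(v) for v in (20.0, 25.0, 30.0)])
        assert summary.table.loc["eta_kpa", "mean"] == pytest.approx(25.0)
        assert summary.table.loc["eta_kpa", "sd"] == pytest.approx(5.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_fits([])
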