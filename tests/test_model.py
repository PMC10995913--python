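"""Warped Bayesian linear regression: evidence, fitting, transfer, z-scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import normdev as nd
from normdev.basis import BasisSpec, build_design_matrix
from normdev.exceptions import CalibrationError, DataError, FittingError
from normdev.model import gaussian_blr_evidence
from normdev.warp import WarpParams, inverse_warp, warp

from conftest import SUBSET


class TestEvidence:
    def test_matches_closed_form_marginal_gaussian(self):
        """With identity warp, the evidence must equal the density of
        t ~ N(0, X X'/alpha + I/beta) evaluated directly."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 3))
        t = rng.normal(size=5)
        for alpha, beta in [(1.0, 1.0), (0.3, 4.0), (10.0, 0.5)]:
            lml, _, _ = gaussian_blr_evidence(X, t, alpha, beta)
            cov = X @ X.T / alpha + np.eye(5) / beta
            oracle = sps.multivariate_normal(mean=np.zeros(5), cov=cov).logpdf(t)
            assert lml == pytest.approx(oracle, abs=1e-8)

    def test_duplication_leaves_posterior_mean_unchanged_vague_prior(self):
        """Replicating every observation doubles the posterior precision but
        leaves the mean fixed (exactly so in the vague-prior limit)."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        t = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(scale=0.1, size=20)
        alpha, beta = 1e-8, 25.0
        _, m1, _ = gaussian_blr_evidence(X, t, alpha, beta)
        _, m2, _ = gaussian_blr_evidence(np.vstack([X, X]), np.concatenate([t, t]), alpha, beta)
        np.testing.assert_allclose(m1, m2, atol=1e-8)


def _toy_reference(n=800, eps=0.0, delta=1.0, noise=0.05, seed=5):
    """Responses from a known linear age trend through the inverse warp."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(40, 90, n)
    sex = (np.arange(n) % 2).astype(float)
    site = np.repeat(["a", "b"], n // 2)
    p = WarpParams(eps=eps, delta=delta)
    latent = 0.02 * (age - 65) + 0.3 * sex + rng.normal(0, noise, n)
    y = inverse_warp(latent, p)
    return y, age, sex, site


class TestFitRegionModel:
    def test_recovers_linear_trajectory_and_identity_warp(self):
        y, age, sex, site = _toy_reference()
        m = nd.fit_region_model(y, age, sex, site, name="toy")
        assert abs(m.warp.eps) < 0.1
        # fitted mean curve vs truth on a grid, in native units
        grid = np.linspace(45, 85, 9)
        X = m.design(grid, np.zeros(9))
        pred_native = m.y_shift + m.y_scale * inverse_warp(X @ m.weights, m.warp)
        truth = 0.02 * (grid - 65)
        np.testing.assert_allclose(pred_native, truth, atol=0.02)

    def test_too_few_controls_rejected(self):
        y, age, sex, site = _toy_reference(n=30)
        with pytest.raises(FittingError, match="minimum"):
            nd.fit_region_model(y, age, sex, site)

    def test_nonfinite_response_names_participant(self):
        y, age, sex, site = _toy_reference(n=100)
        y[7] = np.nan
        ids = [f"p{i}" for i in range(100)]
        with pytest.raises(DataError, match="p7"):
            nd.fit_region_model(y, age, sex, site, name="r1", ids=ids)

    def test_site_with_single_control_rejected(self):
        y, age, sex, site = _toy_reference(n=100)
        site = site.astype(object).copy()
        site[0] = "lonely"
        with pytest.raises(FittingError, match="lonely"):
            nd.fit_region_model(y, age, sex, site)

    def test_reference_sites_precalibrated(self):
        y, age, sex, site = _toy_reference()
        m = nd.fit_region_model(y, age, sex, site)
        assert set(m.site_corrections) == {"a", "b"}


class TestRecalibration:
    def test_no_shift_gives_near_identity_correction(self, small_model, small_clinical):
        clin, _ = small_clinical
        ctl = clin[(clin["site"] == "clin1") & (clin["group"] == "Control")]
        model = nd.recalibrate_site(small_model, ctl)
        # clinical site offsets are drawn N(0, 0.3); scale should be ~1
        for r in SUBSET:
            assert model.models[r].site_corrections["clin1"].scale == pytest.approx(1.0, abs=0.25)

    def test_injected_offset_recovered(self):
        """Controls shifted by +0.8 residual SD yield m_s higher by 0.8."""
        cfg = nd.default_config(seed=33, n_reference=1200, n_sites=2, skew_eps=0.0,
                                group_specs={}, n_clinical_sites=1,
                                controls_per_clinical_site=200, site_effect_sd=0.0)
        ref, truth = nd.generate_reference_cohort(cfg)
        model = nd.fit_normative_model(ref, regions=SUBSET)
        clin, _ = nd.generate_clinical_cohort(cfg, truth)
        ctl = clin[clin["group"] == "Control"].copy()
        base = nd.recalibrate_site(model, ctl)
        shifted = ctl.copy()
        for r in SUBSET:  # identity warp: +0.8 warped-SD = +0.8 * scale in native units
            shifted[r] = ctl[r] + 0.8 * truth.region_params.loc[r, "scale"]
        rec = nd.recalibrate_site(model, shifted)
        recovered = []
        for r in SUBSET:
            m0 = base.models[r].site_corrections["clin1"].offset
            m1 = rec.models[r].site_corrections["clin1"].offset
            # convert warped-standardized offset back to warped-SD units
            recovered.append((m1 - m0) * rec.models[r].y_scale
                             / truth.region_params.loc[r, "scale"])
        assert np.mean(recovered) == pytest.approx(0.8, abs=0.1)

    def test_idempotent_and_does_not_mutate(self, small_model, small_clinical):
        clin, _ = small_clinical
        ctl = clin[(clin["site"] == "clin1") & (clin["group"] == "Control")]
        m1 = nd.recalibrate_site(small_model, ctl)
        m2 = nd.recalibrate_site(m1, ctl)
        for r in SUBSET:
            assert "clin1" not in small_model.models[r].site_corrections
            assert (m1.models[r].site_corrections["clin1"]
                    == m2.models[r].site_corrections["clin1"])

    def test_too_few_controls_rejected(self, small_model, small_clinical):
        clin, _ = small_clinical
        ctl = clin[(clin["site"] == "clin1") & (clin["group"] == "Control")].head(5)
        with pytest.raises(CalibrationError, match="minimum"):
            nd.recalibrate_site(small_model, ctl)

    def test_mixed_sites_rejected(self, small_model, small_clinical):
        clin, _ = small_clinical
        ctl = clin[clin["group"] == "Control"]
        with pytest.raises(CalibrationError, match="one site"):
            nd.recalibrate_site(small_model, ctl)


class TestPredictZscores:
    def test_uncalibrated_site_raises_with_instruction(self, small_model, small_clinical):
        clin, _ = small_clinical
        with pytest.raises(CalibrationError, match="recalibrate"):
            nd.predict_zscores(small_model, clin.head(10))

    def test_exact_zero_when_response_matches_predictor(self, calibrated_model, small_clinical):
        clin, _ = small_clinical
        row = clin[clin["group"] != "Control"].iloc[[0]].copy()
        site = row["site"].iloc[0]
        for r in SUBSET:
            m = calibrated_model.models[r]
            x = m.design(row["age"].to_numpy(), row["sex"].to_numpy())
            t_target = float((x @ m.weights)[0]) + m.site_corrections[site].offset
            y_std = inverse_warp(t_target, m.warp)
            row[r] = m.y_shift + m.y_scale * y_std
        z = nd.predict_zscores(calibrated_model, row)
        np.testing.assert_allclose(z.to_numpy(), 0.0, atol=1e-10)

    def test_heldout_controls_standard_normal(self, calibrated_model):
        """Data simulated from the fitted model itself must z-score to N(0,1)."""
        rng = np.random.default_rng(99)
        n = 2000
        r = SUBSET[0]
        m = calibrated_model.models[r]
        age = rng.uniform(55, 80, n)
        sex = (np.arange(n) % 2).astype(float)
        X = m.design(age, sex)
        corr = m.site_corrections["clin1"]
        sigma = np.sqrt(m.predictive_variance(X)) * corr.scale
        t = X @ m.weights + corr.offset + rng.standard_normal(n) * sigma
        y = m.y_shift + m.y_scale * inverse_warp(t, m.warp)
        cohort = pd.DataFrame({"participant_id": [f"h{i}" for i in range(n)],
                               "age": age, "sex": sex.astype(int), "site": "clin1",
                               "group": "Control"})
        for rr in SUBSET:
            cohort[rr] = 0.0  # other regions unused below
        cohort[r] = y
        z = nd.predict_zscores(calibrated_model, cohort)[r]
        assert abs(z.mean()) < 0.05
        assert z.var() == pytest.approx(1.0, abs=0.1)
        assert sps.kstest(z, "norm").pvalue > 0.01

    def test_injected_deficit_drops_z_by_predicted_amount(self, calibrated_model, small_clinical):
        """Subtracting 3 residual SD lowers z by 3/(s_s*sqrt(1 + beta*x'Sx)),
        with the predictive SD recomputed independently from the posterior."""
        clin, _ = small_clinical
        r = SUBSET[2]
        m = calibrated_model.models[r]
        row = clin[(clin["group"] != "Control") & (clin["site"] == "clin1")].iloc[[0]].copy()
        z0 = nd.predict_zscores(calibrated_model, row)[r].iloc[0]
        # shift is exact in warped space; map through the inverse warp
        t0 = warp((row[r].iloc[0] - m.y_shift) / m.y_scale, m.warp)
        t1 = t0 - 3.0 * np.sqrt(1.0 / m.beta)
        row[r] = m.y_shift + m.y_scale * inverse_warp(t1, m.warp)
        z1 = nd.predict_zscores(calibrated_model, row)[r].iloc[0]
        x = m.design(row["age"].to_numpy(), row["sex"].to_numpy())[0]
        S = np.asarray(m.post_cov)
        expected_drop = 3.0 / (m.site_corrections["clin1"].scale
                               * np.sqrt(1.0 + m.beta * x @ S @ x))
        assert z0 - z1 == pytest.approx(expected_drop, rel=1e-9)


class TestPersistence:
    def test_save_load_round_trip(self, calibrated_model, small_clinical, tmp_path):
        clin, _ = small_clinical
        path = tmp_path / "model.json"
        nd.save_model(calibrated_model, path)
        loaded = nd.load_model(path)
        assert loaded.calibrated_sites() == calibrated_model.calibrated_sites()
        patients = clin[clin["group"] != "Control"]
        z0 = nd.predict_zscores(calibrated_model, patients)
        z1 = nd.predict_zscores(loaded, patients)
        pd.testing.assert_frame_equal(z0, z1)
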