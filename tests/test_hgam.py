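import subprocess

import numpy as np
import pytest
from scipy import integrate, stats

from rutvox.hgam import (
    HGAMSpec,
    beta_loglik,
    diagnostics,
    fit_hgam,
    predict_smooths,
)
from rutvox.synth import BehaviourParams, synth_behaviour_series


def _flat(x):
    return 0.0 * np.asarray(x, dtype=float)


@pytest.fixture(scope="module")
def recovery_fit():
    params = BehaviourParams(seed=3, status_effect=1.2, n_individuals=4,
                             indiv_sd=0.3, days=(-7, 7))
    records = synth_behaviour_series(params, n_records=1200)
    return params, records, fit_hgam(records, HGAMSpec())


class TestBetaLikelihood:
    def test_matches_scipy_logpdf(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mu = rng.uniform(0.05, 0.95)
            theta = rng.uniform(0.5, 50)
            y = rng.uniform(0.01, 0.99, 50)
            ours = beta_loglik(y, np.full_like(y, mu), theta)
            ref = stats.beta.logpdf(y, mu * theta, (1 - mu) * theta)
            assert np.allclose(ours, ref, atol=1e-10)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            mu = rng.uniform(0.1, 0.9)
            theta = rng.uniform(1.0, 30)
            val, _err = integrate.quad(
                lambda y: np.exp(beta_loglik(np.array([y]), np.array([mu]), theta)[0]),
                0, 1,
            )
            assert abs(val - 1.0) < 1e-6


class TestFitValidation:
    def test_single_individual_rejected(self):
        rec = synth_behaviour_series(BehaviourParams(seed=0, n_individuals=1), n_records=200)
        with pytest.raises(ValueError, match="2 individuals"):
            fit_hgam(rec)

    def test_missing_status_level_rejected(self):
        rec = synth_behaviour_series(BehaviourParams(seed=0), n_records=400)
        rec["status"] = "dominant"
        with pytest.raises(ValueError, match="dominant and subdominant"):
            fit_hgam(rec)

    def test_unknown_status_records_are_excluded(self):
        rec = synth_behaviour_series(BehaviourParams(seed=1, n_individuals=4), n_records=900)
        rec.loc[rec.sample(100, random_state=0).index, "status"] = "unknown"
        fit = fit_hgam(rec, HGAMSpec())
        assert fit.y.size == (rec.status != "unknown").sum()


class TestFitQuality:
    def test_status_contrast_recovered(self, recovery_fit):
        params, _records, fit = recovery_fit
        assert fit.converged
        assert abs(fit.status_contrast - params.status_effect) < 0.3

    def test_fitted_means_inside_open_unit_interval(self, recovery_fit):
        _p, _r, fit = recovery_fit
        assert fit.mu_hat.min() > 0 and fit.mu_hat.max() < 1

    def test_deviance_explained_in_unit_interval(self, recovery_fit):
        _p, _r, fit = recovery_fit
        assert 0 <= fit.deviance_explained <= 1
        assert fit.theta > 0

    def test_edf_bounded_by_basis_size(self, recovery_fit):
        _p, _r, fit = recovery_fit
        for b in fit.blocks:
            assert fit.edf[b.name] <= (b.sl.stop - b.sl.start) + 1e-6

    def test_null_data_yield_negligible_deviance_explained(self):
        params = BehaviourParams(seed=5, status_effect=0.0, indiv_sd=0.0,
                                 diel_curve=_flat, season_curve=_flat)
        fit = fit_hgam(synth_behaviour_series(params, n_records=1500), HGAMSpec())
        assert fit.deviance_explained < 0.05


class TestPenaltyBehaviour:
    def _curve_range(self, lam):
        params = BehaviourParams(seed=7, n_individuals=3, days=(-7, 7))
        rec = synth_behaviour_series(params, n_records=900)
        spec = HGAMSpec(max_outer=0, lambda_init=lam)
        fit = fit_hgam(rec, spec)
        curves = predict_smooths(fit)["hour"]
        rng_ = curves.groupby("individual").estimate.agg(lambda s: s.max() - s.min())
        return float(rng_.mean()), fit.deviance

    def test_infinite_smoothing_flattens_hour_curve(self):
        range_stiff, dev_stiff = self._curve_range(1e7)
        range_loose, dev_loose = self._curve_range(1e-3)
        assert range_stiff < 0.05 * range_loose
        # relaxing the penalty can only improve the training deviance
        assert dev_loose <= dev_stiff + 1e-6


class TestPredictSmooths:
    def test_hour_curve_periodic(self, recovery_fit):
        _p, _r, fit = recovery_fit
        curves = predict_smooths(fit, hour_grid=np.array([0.0, 24.0]))["hour"]
        for _ind, grp in curves.groupby("individual"):
            est = grp.estimate.to_numpy()
            assert abs(est[0] - est[1]) < 1e-6

    def test_population_diel_curve_tracks_truth(self, recovery_fit):
        params, _r, fit = recovery_fit
        curves = predict_smooths(fit)["hour"]
        grid = np.sort(curves.x.unique())
        pop = curves.groupby("x").estimate.mean().to_numpy()
        truth = params.diel_curve(grid)
        truth = truth - truth.mean()
        assert np.corrcoef(pop, truth)[0, 1] >= 0.9

    def test_day_grid_outside_span_flagged(self, recovery_fit):
        _p, _r, fit = recovery_fit
        curves = predict_smooths(fit, day_grid=np.array([-30.0, 0.0]))["day"]
        assert curves.groupby("x").extrapolated.first()[-30.0]
        assert not curves.groupby("x").extrapolated.first()[0.0]

    def test_ci_width_shrinks_with_sample_size(self):
        widths = {}
        for n in (500, 5000):
            params = BehaviourParams(seed=9, n_individuals=4, days=(-14, 14))
            rec = synth_behaviour_series(params, n_records=n)
            fit = fit_hgam(rec, HGAMSpec())
            c = predict_smooths(fit)["hour"]
            widths[n] = float((c.hi - c.lo).mean())
        assert widths[5000] < widths[500]


class TestDiagnostics:
    def test_residual_count_and_acf_normalization(self, recovery_fit):
        _p, records, fit = recovery_fit
        d = diagnostics(fit, records)
        assert d["residuals"].size == fit.y.size
        assert np.isclose(d["acf"]["all"][0], 1.0)

    def test_well_specified_model_leaves_white_residuals(self):
        params = BehaviourParams(seed=13, n_individuals=4, days=(-10, 10))
        rec = synth_behaviour_series(params, n_records=1500)
        fit = fit_hgam(rec, HGAMSpec())
        d = diagnostics(fit, rec)
        n = fit.y.size
        assert abs(d["acf"]["all"][1]) < 3.0 / np.sqrt(n)


def test_agrees_with_mgcv_reference_fit(tmp_path):
    """Independent oracle: the same model structure fitted by mgcv's betar
    GAM should land on essentially the same status contrast and fit quality."""
    params = BehaviourParams(seed=3, status_effect=1.2, n_individuals=4,
                             indiv_sd=0.3, days=(-7, 7))
    records = synth_behaviour_series(params, n_records=1200)
    fit = fit_hgam(records, HGAMSpec())
    csv = tmp_path / "rec.csv"
    records.to_csv(csv, index=False)
    r_code = f"""
suppressMessages(library(mgcv))
d <- read.csv("{csv}")
d$status <- factor(d$status, levels=c("subdominant", "dominant"))
d$individual <- factor(d$individual)
m <- gam(proportion ~ status + s(hour, bs="cc", k=10) + s(day_rel_peak, k=10)
         + s(individual, bs="re"),
         family=betar(link="logit"), method="REML", data=d,
         knots=list(hour=c(0, 24)))
cat(coef(m)["statusdominant"], summary(m)$dev.expl, "\\n")
"""
    out = subprocess.run(["Rscript", "-e", r_code], capture_output=True, text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    ref_status, ref_devexpl = map(float, out.stdout.split())
    assert abs(fit.status_contrast - ref_status) < 0.2
    assert abs(fit.deviance_explained - ref_devexpl) < 0.1
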