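"""Laplace-approximate marginal likelihood, fitting and model comparison."""

import math

import numpy as np
import pytest
from scipy import stats

from cabopk import (
    OmegaMatrix,
    ResidualModel,
    compare_nested,
    fit_model,
    individual_joint_nll,
    laplace_ofv,
    load_preset,
    simulate_dataset,
)
from cabopk.estimation import (
    BASE_CONFIG,
    FM_CONFIG,
    ModelConfig,
    Parameterization,
    _SubjectModel,
    prepare_subjects,
)
from cabopk.synthetic_data import PKDataset
from conftest import make_study


@pytest.fixture(scope="module")
def tiny_ds(fm_theta):
    """Three subjects, rich-ish sampling, noiseless (for exact checks)."""
    spec = make_study("T", "HV", n=3, obs_times=(1, 2, 4, 8, 24, 72))
    return simulate_dataset([spec], fm_theta, OmegaMatrix.zero(),
                            ResidualModel(0.0), seed=2)


@pytest.fixture(scope="module")
def noisy_ds(fm_theta, fm_residual):
    spec = make_study("N", "HV", n=25,
                      obs_times=(0.5, 1, 2, 4, 8, 12, 24, 48, 96, 168, 336))
    om = OmegaMatrix.diagonal(0.0, 0.202, 0.0, 0.0)
    return simulate_dataset([spec], fm_theta, om, fm_residual, seed=6)


class TestIndividualJointNll:
    def test_standard_normal_densities_at_zero(self, fm_theta, tiny_ds):
        """One observation exactly at the model prediction, sigma2 = 1 and
        Omega = I: the joint -2 log density is 5 log(2 pi)."""
        subj = prepare_subjects(tiny_ds)[0]
        subj_one = type(subj)(
            sid=subj.sid, cov=subj.cov, dose_groups=subj.dose_groups,
            obs_times=subj.obs_times[:1], log_dv=subj.log_dv[:1],
        )
        val = individual_joint_nll(np.zeros(4), subj_one, fm_theta,
                                   OmegaMatrix(np.eye(4)), ResidualModel(1.0))
        assert val == pytest.approx(5.0 * math.log(2.0 * math.pi), abs=1e-6)

    def test_residual_contribution_is_quadratic(self, fm_theta, tiny_ds):
        subj = prepare_subjects(tiny_ds)[0]
        om, rm = OmegaMatrix(np.eye(4)), ResidualModel(1.0)
        base = individual_joint_nll(np.zeros(4), subj, fm_theta, om, rm)
        s1 = type(subj)(sid=subj.sid, cov=subj.cov, dose_groups=subj.dose_groups,
                        obs_times=subj.obs_times, log_dv=subj.log_dv + 0.1)
        s2 = type(subj)(sid=subj.sid, cov=subj.cov, dose_groups=subj.dose_groups,
                        obs_times=subj.obs_times, log_dv=subj.log_dv + 0.2)
        d1 = individual_joint_nll(np.zeros(4), s1, fm_theta, om, rm) - base
        d2 = individual_joint_nll(np.zeros(4), s2, fm_theta, om, rm) - base
        assert d2 == pytest.approx(4.0 * d1, rel=1e-9)

    def test_matches_brute_force_density_assembly(self, fm_theta, fm_omega_diag,
                                                  fm_residual, tiny_ds):
        """Term-by-term oracle: scipy normal log-densities summed directly."""
        subj = prepare_subjects(tiny_ds)[1]
        subj3 = type(subj)(sid=subj.sid, cov=subj.cov,
                           dose_groups=subj.dose_groups,
                           obs_times=subj.obs_times[:3],
                           log_dv=subj.log_dv[:3] + 0.05)
        eta = np.array([0.3, -0.2, 0.1, 0.25])
        model = _SubjectModel(subj3, fm_theta)
        logc = np.log(model.predict(eta))
        sigma = math.sqrt(fm_residual.sigma2)
        oracle = -2.0 * (
            stats.norm.logpdf(subj3.log_dv, loc=logc, scale=sigma).sum()
            + stats.multivariate_normal.logpdf(
                eta, mean=np.zeros(4),
                cov=fm_omega_diag.matrix + 1e-8 * np.eye(4))
        )
        val = individual_joint_nll(eta, subj3, fm_theta, fm_omega_diag,
                                   fm_residual)
        assert val == pytest.approx(oracle, rel=1e-10)


class TestLaplaceOfv:
    def test_zero_omega_collapses_to_fixed_effects_nll(self, fm_theta,
                                                       fm_residual, noisy_ds):
        """With no random effects the OFV is the eta = 0 -2 log likelihood."""
        ofv, etas = laplace_ofv(fm_theta, OmegaMatrix.zero(), fm_residual,
                                noisy_ds)
        subjects = prepare_subjects(noisy_ds)
        direct = sum(
            _SubjectModel(s, fm_theta).residual_nll(np.zeros(4),
                                                    fm_residual.sigma2)
            for s in subjects
        )
        assert ofv == pytest.approx(direct, rel=1e-12)
        assert all(np.all(v == 0) for v in etas.values())

    def test_invariant_to_subject_order(self, fm_theta, fm_residual, noisy_ds):
        om = OmegaMatrix.diagonal(0.0, 0.202, 0.0, 0.0)
        ofv1, _ = laplace_ofv(fm_theta, om, fm_residual, noisy_ds)
        df = noisy_ds.df.copy()
        df["ID"] = df["ID"].map(lambda i: 1000 - i)  # reverse the ordering
        df = df.sort_values(["ID", "TIME", "EVID"], kind="stable")
        ofv2, _ = laplace_ofv(fm_theta, om, fm_residual, PKDataset(df))
        assert ofv2 == pytest.approx(ofv1, abs=1e-8)

    def test_exact_for_linear_gaussian_model(self, fm_theta, noisy_ds,
                                             monkeypatch):
        """When log-prediction is linear in eta the marginal is Gaussian and
        the Laplace OFV equals the closed-form -2 log likelihood."""
        subjects = prepare_subjects(noisy_ds)[:5]
        slope, w2, s2 = 1.0, 0.09, 0.04

        def linear_predict(self, eta):
            return np.exp(np.full(len(self.subj.obs_times), 3.0)
                          + slope * eta[1])

        monkeypatch.setattr(_SubjectModel, "predict", linear_predict)
        om = OmegaMatrix.diagonal(0.0, w2, 0.0, 0.0)
        ofv, _ = laplace_ofv(fm_theta, om, ResidualModel(s2), subjects)
        exact = 0.0
        for s in subjects:
            n = len(s.log_dv)
            cov = s2 * np.eye(n) + slope**2 * w2 * np.ones((n, n))
            exact += -2.0 * stats.multivariate_normal.logpdf(
                s.log_dv, mean=np.full(n, 3.0), cov=cov)
        assert ofv == pytest.approx(exact, abs=1e-4)


class TestFitModel:
    def test_noiseless_identifiability(self, fm_theta):
        """Estimating only CL and Vc on noise-free rich data recovers the
        generating values within 1%."""
        # reference-covariate subjects so the structural references are
        # identified directly (no covariate variation to explain)
        spec = make_study("F", "HV", n=8, obs_times=(1, 2, 4, 8, 24, 72, 168),
                          male=1.0, age=(60.0, 0.0, 59.0, 61.0),
                          wt=(80.0, 0.0, 79.0, 81.0))
        ds = simulate_dataset([spec], fm_theta, OmegaMatrix.zero(),
                              ResidualModel(1e-6), seed=4)
        cfg = ModelConfig("cv", demographics=False, populations=False,
                          estimate=("cl", "vc"), random_effects=(), preset="FM")
        init = fm_theta.replace(cl_ref=2.478 * 1.3, vc_ref=187.0 * 0.8)
        fit = fit_model(cfg, ds, theta_init=init, rm_init=ResidualModel(1e-6),
                        maxfev=200)
        assert fit.theta.cl_ref == pytest.approx(2.478, rel=0.01)
        assert fit.theta.vc_ref == pytest.approx(187.0, rel=0.01)

    def test_parameterization_round_trip(self, fm_theta, fm_omega_diag,
                                         fm_residual):
        names = ("cl", "vc", "ka", "f1", "cl_pop_MTC", "omega_cl", "sigma2",
                 "cl_wt_exp", "capsule_f_fc")
        packer = Parameterization(names, fm_theta, fm_omega_diag, fm_residual)
        th, om, rm = packer.unpack(packer.pack())
        assert th.cl_ref == pytest.approx(fm_theta.cl_ref, rel=1e-12)
        assert th.f1_ref == pytest.approx(fm_theta.f1_ref, rel=1e-12)
        assert th.cl_pop_fc["MTC"] == pytest.approx(0.928, rel=1e-12)
        assert th.capsule_f_fc == pytest.approx(-0.144, rel=1e-12)
        assert om.variance("cl") == pytest.approx(0.202, rel=1e-12)
        assert rm.sigma2 == pytest.approx(0.118, rel=1e-12)

    def test_unknown_parameter_name_rejected(self, fm_theta, fm_omega_diag,
                                             fm_residual):
        with pytest.raises(ValueError, match="unknown parameter"):
            Parameterization(("cl", "bogus"), fm_theta, fm_omega_diag,
                             fm_residual)

    def test_config_structure_zeroing(self, fm_theta):
        th = BASE_CONFIG.apply_structure(fm_theta)
        assert th.cl_pop_fc == {} and th.cl_age_exp == 0.0
        # structural absorption covariates are retained
        assert th.capsule_f_fc == pytest.approx(-0.144)
        th2 = FM_CONFIG.apply_structure(fm_theta)
        assert th2 == fm_theta


class TestCompareNested:
    def _dummy_fit(self, cfg, ofv):
        from cabopk.estimation import FitResult

        return FitResult(theta=load_preset("FM"), omega=OmegaMatrix.zero(),
                         residual=ResidualModel(0.1), ofv=ofv, map_etas={},
                         converged=True, config=cfg,
                         param_names=cfg.estimate, x=np.zeros(len(cfg.estimate)))

    def test_identical_fits_give_null_comparison(self):
        cfg = ModelConfig("a", True, True, ("cl",))
        d, df, p = compare_nested(self._dummy_fit(cfg, 100.0),
                                  self._dummy_fit(cfg, 100.0))
        assert d == 0.0 and p == 1.0

    def test_chi_square_critical_value(self):
        red = ModelConfig("r", True, False, ("cl",))
        full = ModelConfig("f", True, True, ("cl", "cl_pop_MTC"))
        d, df, p = compare_nested(self._dummy_fit(red, 110.83),
                                  self._dummy_fit(full, 100.0))
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(10.83, 1), rel=1e-12)
        assert p == pytest.approx(0.001, rel=0.01)

    def test_non_nested_rejected(self):
        a = ModelConfig("a", True, True, ("cl", "vc"))
        b = ModelConfig("b", True, False, ("cl", "ka"))
        with pytest.raises(ValueError, match="not nested"):
            compare_nested(self._dummy_fit(b, 1.0), self._dummy_fit(a, 0.0))

    def test_full_model_ofv_not_worse_on_any_data(self, fm_theta, fm_residual):
        """Nesting guarantee: adding a parameter cannot raise the optimised
        OFV beyond optimizer tolerance."""
        spec = make_study("M", "MTC", n=20, dose=60.0, qd=True,
                          obs_times=(670.0, 672.0))
        om = OmegaMatrix.diagonal(0.0, 0.202, 0.0, 0.0)
        ds = simulate_dataset([spec], fm_theta, om, fm_residual, seed=9)
        red = ModelConfig("r", demographics=True, populations=False,
                          estimate=("cl",), random_effects=("cl",), preset="FM")
        full = ModelConfig("f", demographics=True, populations=True,
                           estimate=("cl", "cl_pop_MTC"),
                           random_effects=("cl",), preset="FM")
        f_r = fit_model(red, ds, theta_init=fm_theta, omega_init=om,
                        rm_init=fm_residual, maxfev=80)
        f_f = fit_model(full, ds, theta_init=fm_theta, omega_init=om,
                        rm_init=fm_residual, maxfev=120)
        assert f_f.ofv <= f_r.ofv + 0.1
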