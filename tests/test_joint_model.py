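"""Joint model: quadrature, likelihood, sampler, and posterior summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from phjoint.data_model import EventStatus, Sex, SubjectRecord
from phjoint.joint_model import (
    ConvergenceError,
    JointData,
    JointModelSpec,
    ParamState,
    compute_dic,
    cumulative_hazard,
    fit_joint,
    hazard_ratio_per_doubling,
    joint_log_likelihood,
    predict_subject_trajectory,
    random_effect_correlations,
    _dic_from_draws,
)
from phjoint.longitudinal_model import SplineSpec
from phjoint.scenarios import recovery_scenario_k2
from phjoint.synthetic_cohort import simulate_cohort


class TestCumulativeHazard:
    def test_constant_hazard_exact(self):
        lam = cumulative_hazard(lambda t: np.zeros_like(t), lambda t: np.full_like(t, 0.7),
                                1.0, 4.0)
        assert lam == pytest.approx(0.7 * 3.0, rel=1e-14)

    def test_loglinear_closed_form_at_15_nodes(self):
        a, b, lo, hi = -1.0, 0.4, 0.5, 6.0
        lam = cumulative_hazard(lambda t: a + b * t, lambda t: np.ones_like(t),
                                lo, hi, n_nodes=15)
        expect = np.exp(a) * (np.exp(b * hi) - np.exp(b * lo)) / b
        assert lam == pytest.approx(expect, abs=1e-8)

    def test_node_doubling_converged(self):
        f = lambda t: np.sin(t) * 0.3
        l15 = cumulative_hazard(f, lambda t: np.ones_like(t), 0.0, 3.0, 15)
        l30 = cumulative_hazard(f, lambda t: np.ones_like(t), 0.0, 3.0, 30)
        assert abs(l15 - l30) < 1e-10

    def test_entry_must_precede_exit(self):
        with pytest.raises(ValueError):
            cumulative_hazard(lambda t: t, lambda t: np.ones_like(t), 2.0, 2.0)


def _tiny_data(n=4, obs_per=0, delta=None, T=None, J_breaks=(0.0,), quad_nodes=7,
               seed=0):
    """Hand-built JointData: K=1, optional observations, simple survival."""
    rng = np.random.default_rng(seed)
    names = ["POX"]
    ids = [f"s{i}" for i in range(n)]
    w = np.column_stack([rng.uniform(5, 30, n), (np.arange(n) % 2).astype(float)])
    T = np.asarray(T if T is not None else rng.uniform(2, 8, n))
    delta = np.asarray(delta if delta is not None else [True] * (n // 2) + [False] * (n - n // 2))
    y, X, subj = [], [], []
    for i in range(n):
        t = rng.uniform(0, T[i], obs_per)
        y.extend(2.0 + 0.1 * t + rng.normal(0, 0.2, obs_per))
        X.extend(np.column_stack([np.ones(obs_per), np.full(obs_per, w[i, 0]),
                                  np.full(obs_per, w[i, 1]), t]))
        subj.extend([i] * obs_per)
    data = JointData(
        names, ids, w, [np.asarray(y)],
        [np.asarray(X).reshape(-1, 4)], [np.asarray(subj, int)],
        np.zeros(n), T, delta, np.asarray(J_breaks), quad_nodes,
    )
    data.set_time_designs([lambda t: np.asarray(t, float)[:, None]])
    return data


def _state(data, alpha=0.0, gamma=(0.0, 0.0), lam=0.1, beta=None, sigma=0.3, dvar=0.25):
    K, J = data.K, data.J
    return ParamState(
        beta=[np.asarray(beta if beta is not None else [2.0, 0.0, 0.0, 0.1])],
        sigma=np.full(K, sigma),
        D=np.eye(K) * dvar,
        gamma=np.asarray(gamma, float),
        alpha=np.full(K, alpha),
        lam=np.full(J, lam),
    )


class TestJointLogLikelihood:
    def test_constant_hazard_censored_survival_term_exact(self):
        # alpha = gamma = 0, constant hazard c, censored at T: term = -c*T
        data = _tiny_data(n=1, delta=[False], T=[5.0])
        st = _state(data, lam=0.23)
        b = np.zeros((1, 1))
        assert data.loglik_survival(st, b) == pytest.approx(-0.23 * 5.0, rel=1e-12)

    def test_zero_data_contribution_is_raneff_prior_only(self):
        # no observations, delta = 0, zero at-risk time
        data = _tiny_data(n=1, delta=[False], T=[1e-300])
        st = _state(data)
        b = np.array([[0.4]])
        total = joint_log_likelihood(st, b, data)
        from scipy.stats import norm

        expect = norm.logpdf(0.4, scale=np.sqrt(0.25))
        assert total == pytest.approx(expect, abs=1e-6)

    def test_alpha_zero_matches_standalone_ph_loglik(self):
        # with alpha = 0 the survival term is an ordinary parametric PH
        # log-likelihood in (gamma, lambda), computed independently here
        data = _tiny_data(n=6, delta=[True, True, False, True, False, False],
                          T=[2.0, 3.5, 4.0, 1.2, 6.0, 2.5])
        gamma = np.array([0.03, -0.4])
        st = _state(data, alpha=0.0, gamma=gamma, lam=0.15)
        b = np.zeros((6, 1))
        mine = data.loglik_survival(st, b)
        lp = data.w @ gamma
        expect = float(
            np.sum(np.asarray(data.delta) * (np.log(0.15) + lp))
            - 0.15 * np.sum(np.exp(lp) * data.T)
        )
        assert mine == pytest.approx(expect, rel=1e-10)

    def test_non_pd_D_returns_neg_inf_not_exception(self):
        data = _tiny_data()
        st = _state(data)
        st.D = np.array([[-1.0]])
        assert joint_log_likelihood(st, np.zeros((4, 1)), data) == -np.inf

    def test_longitudinal_term_is_gaussian_density(self):
        data = _tiny_data(n=3, obs_per=4)
        st = _state(data)
        b = np.array([[0.1], [-0.2], [0.0]])
        from scipy.stats import norm

        r = data.y[0] - data.X[0] @ st.beta[0] - b[data.subj[0], 0]
        expect = norm.logpdf(r, scale=0.3).sum()
        assert data.loglik_longitudinal(st, b) == pytest.approx(expect, rel=1e-10)


class TestSummaries:
    def test_hr_identity_cases(self):
        assert hazard_ratio_per_doubling(np.zeros(100)) == {"hr": 1.0, "lo": 1.0, "hi": 1.0}
        out = hazard_ratio_per_doubling(np.ones(50))
        assert out["hr"] == pytest.approx(2.0)

    def test_hr_posterior_median_convention(self):
        out = hazard_ratio_per_doubling(np.array([0.2, 0.6, 1.0]))
        assert out["hr"] == pytest.approx(2**0.6)
        assert out["hr"] == pytest.approx(1.5157, abs=1e-3)


@pytest.fixture(scope="module")
def small_fit():
    """Shared small-cohort multivariate fit (short, diagnostics not enforced)."""
    cfg = recovery_scenario_k2(n_subjects=90)
    subs, obs, truth = simulate_cohort(cfg, seed=31)
    spec = JointModelSpec(
        biomarkers={"POX": SplineSpec(2, (50.0,)), "UOX": SplineSpec(2, (50.0,))},
        chains=2, warmup=300, draws=300,
    )
    fit = fit_joint(subs, obs, spec, seed=2, enforce_convergence=False)
    return cfg, subs, obs, truth, fit


class TestFitJoint:
    def test_correlation_table_shape_and_range(self, small_fit):
        *_, fit = small_fit
        corr = random_effect_correlations(fit)
        assert list(corr["pair"]) == ["POX-UOX"]
        assert -1 <= corr["mean"].iloc[0] <= 1
        assert corr["lo"].iloc[0] <= corr["median"].iloc[0] <= corr["hi"].iloc[0]

    def test_correlations_require_two_biomarkers(self, small_fit):
        *_, fit = small_fit
        solo = type(fit)(**{**fit.__dict__, "names": ["POX"]})
        with pytest.raises(ValueError):
            random_effect_correlations(solo)

    def test_diagonal_D_draws_give_zero_corr(self, small_fit):
        *_, fit = small_fit
        fake = {**fit.draws, "D": np.repeat(np.eye(2)[None], 10, axis=0)}
        solo = type(fit)(**{**fit.__dict__, "draws": fake})
        corr = random_effect_correlations(solo)
        assert corr["mean"].iloc[0] == 0.0

    def test_fixed_corr_draws_recovered_exactly(self, small_fit):
        *_, fit = small_fit
        D = np.array([[1.0, 0.59 * np.sqrt(2.0)], [0.59 * np.sqrt(2.0), 2.0]])
        fake = {**fit.draws, "D": np.repeat(D[None], 7, axis=0)}
        solo = type(fit)(**{**fit.__dict__, "draws": fake})
        assert random_effect_correlations(solo)["mean"].iloc[0] == pytest.approx(0.59)

    def test_trajectory_monotone_transform_consistency(self, small_fit):
        _, subs, obs, _, fit = small_fit
        sid = subs[0].subject_id
        pred = predict_subject_trajectory(fit, sid, "POX", [0.5, 2.0, 5.0])
        assert pred["value_median"].to_numpy() == pytest.approx(
            np.exp(pred["log_median"].to_numpy())
        )

    def test_trajectory_tracks_well_measured_subject(self, small_fit):
        _, subs, obs, _, fit = small_fit
        counts = {}
        for o in obs:
            if o.biomarker == "POX":
                counts[o.subject_id] = counts.get(o.subject_id, 0) + 1
        sid = max(counts, key=counts.get)
        mine = [o for o in obs if o.subject_id == sid and o.biomarker == "POX"]
        t = np.array([o.time for o in mine])
        pred = predict_subject_trajectory(fit, sid, "POX", t)
        log_obs = np.log([o.value for o in mine])
        band = (pred["log_hi"] - pred["log_lo"]).to_numpy() / 2
        resid_sd = fit.draws["sigma"][:, 0].mean()
        # prediction of the latent mean should sit within measurement noise
        # plus posterior uncertainty of the observed values
        assert np.all(np.abs(pred["log_median"] - log_obs) < 2 * (band + resid_sd))

    def test_unknown_subject_or_biomarker_rejected(self, small_fit):
        *_, fit = small_fit
        with pytest.raises(KeyError):
            predict_subject_trajectory(fit, "nope", "POX", [1.0])
        with pytest.raises(KeyError):
            predict_subject_trajectory(fit, fit.subject_ids[0], "XXX", [1.0])

    def test_dic_reported_and_identity(self, small_fit):
        *_, fit = small_fit
        out = compute_dic(fit)
        assert out["dic"] == pytest.approx(fit.dic)
        assert out["dic"] == pytest.approx(out["dbar"] + out["pd"])
        assert out["pd"] > 0

    def test_one_draw_posterior_has_zero_pd(self, small_fit):
        *_, fit = small_fit
        one = {k: v[:1] for k, v in fit.draws.items()}
        dic = _dic_from_draws(one, fit._data)
        assert dic == pytest.approx(one["deviance"][0], abs=1e-6)

    def test_convergence_gate_raises_structured_error(self, small_fit):
        cfg, subs, obs, *_ = small_fit
        spec = JointModelSpec(
            biomarkers={"POX": SplineSpec(2, (50.0,)), "UOX": SplineSpec(2, (50.0,))},
            chains=2, warmup=30, draws=40, ess_min=10_000,
        )
        with pytest.raises(ConvergenceError) as exc:
            fit_joint(subs, obs, spec, seed=3)
        assert not exc.value.diagnostics.empty
        assert exc.value.fit.draws["alpha"].shape[0] == 80

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            JointModelSpec(biomarkers={})
        with pytest.raises(ValueError):
            JointModelSpec(biomarkers={"POX": SplineSpec(2, (50.0,))}, quad_nodes=3)
        with pytest.raises(ValueError):
            JointModelSpec(biomarkers={"POX": SplineSpec(2, (50.0,))}, chains=1)


class TestLabelSymmetry:
    def test_permuting_biomarkers_permutes_estimates(self):
        cfg = recovery_scenario_k2(n_subjects=80)
        subs, obs, _ = simulate_cohort(cfg, seed=77)
        sp = {"POX": SplineSpec(2, (50.0,)), "UOX": SplineSpec(2, (50.0,))}
        f1 = fit_joint(subs, obs, JointModelSpec(biomarkers=sp, chains=2,
                                                 warmup=250, draws=300),
                       seed=4, enforce_convergence=False)
        f2 = fit_joint(subs, obs,
                       JointModelSpec(biomarkers={k: sp[k] for k in ["UOX", "POX"]},
                                      chains=2, warmup=250, draws=300),
                       seed=4, enforce_convergence=False)
        a1 = dict(zip(f1.names, f1.draws["alpha"].mean(0)))
        a2 = dict(zip(f2.names, f2.draws["alpha"].mean(0)))
        sd1 = dict(zip(f1.names, f1.draws["alpha"].std(0)))
        for name in a1:
            tol = 3 * sd1[name] / np.sqrt(50)  # generous MC tolerance at low ESS
            assert abs(a1[name] - a2[name]) < max(5 * tol, 0.25)
        # DIC invariant to relabeling up to Monte-Carlo error
        assert abs(f1.dic - f2.dic) < 0.02 * abs(f1.dic)
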