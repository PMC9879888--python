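"""Multivariate Bayesian joint model of longitudinal biomarkers and survival.

Model.  For biomarker k (log scale) on subject i at time t:

    y_ik(t) = m_ik(t) + e,         e ~ N(0, sigma_k^2)
    m_ik(t) = x_ik(t)' beta_k + b_ik

with fixed effects (intercept, age at diagnosis, sex, natural cubic spline
in years since diagnosis) and a subject-level random intercept vector
b_i ~ N_K(0, D) correlated across biomarkers.  The kidney-failure hazard is

    h_i(t) = h0(t) * exp(gamma' w_i + sum_k alpha_k m_ik(t))

with w_i = (age at diagnosis, male), a piecewise-constant baseline hazard
h0 on quantile-based intervals, and current-value association: the survival
predictor is the subject-specific *predicted* biomarker value at t, smooth
in time, not the last observed value.  Subjects contribute survival
likelihood only over their at-risk window (entry, T] (delayed entry); the
cumulative hazard over that window is computed by Gauss-Legendre quadrature
within each baseline interval, where the integrand is smooth.

Estimation is by Markov chain Monte Carlo with block updates: random
intercepts by vectorized per-subject Metropolis steps; fixed effects
beta_k by independence proposals from their Gaussian longitudinal
conditional (Metropolis-corrected for the survival factor); residual SDs by
adaptive random-walk on the log scale; D by a conjugate inverse-Wishart
Gibbs draw; baseline-hazard levels by conjugate gamma Gibbs draws; and
(gamma, alpha) jointly by an adaptive random-walk Metropolis step.
Association coefficients are reported per doubling of the biomarker as
2^alpha.  Model fit is summarized by the conditional-deviance DIC.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import EventStatus, LongitudinalObservation, Sex, SubjectRecord
from .longitudinal_model import (
    ResolvedKnots,
    SplineSpec,
    build_design,
    estimate_random_intercept,
    fit_lmm_arrays,
    ns_basis,
    resolve_knots,
)

# ---------------------------------------------------------------------------
# Spec / fit containers
# ---------------------------------------------------------------------------

@dataclass
class JointModelSpec:
    """Configuration of the multivariate joint model.

    ``biomarkers`` maps biomarker name to its time-spline spec (insertion
    order fixes the index k).  ``alpha_fixed`` pins named association
    coefficients (e.g. to 0 for factorization checks); pinned coefficients
    are not sampled.
    """

    biomarkers: dict[str, SplineSpec]
    n_hazard_intervals: int = 7
    quad_nodes: int = 7            # Gauss-Legendre nodes per baseline interval
    chains: int = 2
    warmup: int = 1000
    draws: int = 2500
    coef_prior_sd: float = 10.0    # normal prior SD for beta, gamma, alpha
    sd_prior_scale: float = 5.0    # half-normal prior scale for sigma_k
    hazard_prior_shape: float = 0.01
    hazard_prior_rate: float = 0.01
    iw_prior_df_add: int = 2       # D ~ inverse-Wishart(K + add, I)
    rhat_bound: float = 1.05
    ess_min: float = 400.0
    alpha_fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.biomarkers) < 1:
            raise ValueError("need at least one biomarker submodel")
        if self.quad_nodes < 7:
            raise ValueError("quadrature nodes per interval must be >= 7")
        if self.chains < 2:
            raise ValueError("need at least 2 chains for split-chain diagnostics")

    @property
    def names(self) -> list[str]:
        return list(self.biomarkers)


class ConvergenceError(RuntimeError):
    """Raised when MCMC diagnostics exceed the configured bounds.

    Carries the diagnostics table and the (partial) fit so the draws are
    not lost.
    """

    def __init__(self, message: str, diagnostics: pd.DataFrame, fit: "JointModelFit"):
        super().__init__(message)
        self.diagnostics = diagnostics
        self.fit = fit


@dataclass
class ParamState:
    """One point in parameter space (random effects held separately)."""

    beta: list[np.ndarray]
    sigma: np.ndarray        # (K,)
    D: np.ndarray            # (K, K)
    gamma: np.ndarray        # (2,) age, male
    alpha: np.ndarray        # (K,)
    lam: np.ndarray          # (J,) baseline hazard levels

    def copy(self) -> "ParamState":
        return ParamState(
            [b.copy() for b in self.beta], self.sigma.copy(), self.D.copy(),
            self.gamma.copy(), self.alpha.copy(), self.lam.copy(),
        )


@dataclass
class JointModelFit:
    """Posterior draws and diagnostics from :func:`fit_joint`.

    ``draws[name]`` has the chain dimension flattened out; ``chain_draws``
    keeps it for diagnostics.  Random-intercept draws are in ``draws["b"]``
    with shape (S, n, K).
    """

    spec: JointModelSpec
    names: list[str]
    subject_ids: list[str]
    knots: dict[str, ResolvedKnots]
    beta_names: dict[str, list[str]]
    draws: dict[str, np.ndarray]
    chain_draws: dict[str, np.ndarray]
    diagnostics: pd.DataFrame
    dic: float
    data_signature: str
    _data: "JointData"

    def coefficient_draws(self, name: str) -> np.ndarray:
        """Draws of a named log-hazard coefficient (association or covariate)."""
        if name in self.names:
            return self.draws["alpha"][:, self.names.index(name)]
        if name in ("age_at_dx", "sex_male"):
            return self.draws["gamma"][:, ("age_at_dx", "sex_male").index(name)]
        raise KeyError(f"unknown coefficient {name!r}")


# ---------------------------------------------------------------------------
# Quadrature
# ---------------------------------------------------------------------------

def cumulative_hazard(
    linear_predictor: Callable[[np.ndarray], np.ndarray],
    h0: Callable[[np.ndarray], np.ndarray],
    entry: float,
    exit: float,
    n_nodes: int = 15,
) -> float:
    """Gauss-Legendre approximation of int_entry^exit h0(t) exp(lp(t)) dt."""
    if not entry < exit:
        raise ValueError("entry must be strictly before exit")
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    mid, half = 0.5 * (entry + exit), 0.5 * (exit - entry)
    t = mid + half * x
    return float(half * np.dot(w, np.asarray(h0(t)) * np.exp(linear_predictor(t))))


# ---------------------------------------------------------------------------
# Prepared data
# ---------------------------------------------------------------------------

class JointData:
    """Cohort arrays, spline designs and quadrature grid for one model spec."""

    def __init__(
        self,
        names: list[str],
        subject_ids: list[str],
        w: np.ndarray,
        y: list[np.ndarray],
        X: list[np.ndarray],
        subj: list[np.ndarray],
        entry: np.ndarray,
        T: np.ndarray,
        delta: np.ndarray,
        breaks: np.ndarray,
        quad_nodes: int,
        knots: dict[str, ResolvedKnots] | None = None,
        beta_names: dict[str, list[str]] | None = None,
    ):
        self.names = names
        self.subject_ids = subject_ids
        self.n = len(subject_ids)
        self.K = len(names)
        self.w = w
        self.y, self.X, self.subj = y, X, subj
        self.entry, self.T, self.delta = entry, T, delta
        self.breaks = breaks
        self.J = len(breaks)
        self.knots = knots or {}
        self.beta_names = beta_names or {}
        self.ncount = np.column_stack(
            [np.bincount(subj[k], minlength=self.n) for k in range(self.K)]
        ).astype(float)
        self.ev_interval = np.clip(
            np.searchsorted(breaks, T, side="right") - 1, 0, self.J - 1
        )
        self._build_quadrature(quad_nodes)
        # Xev / Xq (designs at event times and quadrature nodes) are filled
        # by set_time_designs once the spline bases are known
        self.Xev: list[np.ndarray] = []
        self.Xq: list[np.ndarray] = []

    # -- construction helpers -------------------------------------------------

    _time_design: list[Callable[[np.ndarray], np.ndarray]] | None = None

    def set_time_designs(self, fns: list[Callable[[np.ndarray], np.ndarray]]) -> None:
        """fns[k](times) -> spline part of the design; covariate part from w."""
        self._time_design = fns
        self.Xev = [self._design_at(np.arange(self.n), self.T, k) for k in range(self.K)]
        self.Xq = [
            self._design_at(self.q_subj, self.q_t, k) for k in range(self.K)
        ]

    def _design_at(self, subj_idx: np.ndarray, times: np.ndarray, k: int) -> np.ndarray:
        if self._time_design is None:
            raise RuntimeError("time designs not set")
        B = self._time_design[k](np.asarray(times, float))
        wi = self.w[subj_idx]
        return np.column_stack([np.ones(len(times)), wi[:, 0], wi[:, 1], B])

    def _build_quadrature(self, nodes: int) -> None:
        gx, gw = np.polynomial.legendre.leggauss(nodes)
        q_t, q_w, q_subj, q_int = [], [], [], []
        edges = np.r_[self.breaks, np.inf]
        for i in range(self.n):
            lo_i, hi_i = self.entry[i], self.T[i]
            for j in range(self.J):
                lo = max(lo_i, edges[j])
                hi = min(hi_i, edges[j + 1])
                if hi <= lo:
                    continue
                mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
                q_t.append(mid + half * gx)
                q_w.append(half * gw)
                q_subj.append(np.full(nodes, i))
                q_int.append(np.full(nodes, j))
        self.q_t = np.concatenate(q_t) if q_t else np.empty(0)
        self.q_w = np.concatenate(q_w) if q_w else np.empty(0)
        self.q_subj = (np.concatenate(q_subj) if q_subj else np.empty(0)).astype(int)
        self.q_interval = (np.concatenate(q_int) if q_int else np.empty(0)).astype(int)

    @classmethod
    def from_cohort(
        cls,
        subjects: Sequence[SubjectRecord],
        observations: Sequence[LongitudinalObservation],
        spec: JointModelSpec,
    ) -> "JointData":
        names = spec.names
        subject_ids = [s.subject_id for s in subjects]
        sidx = {sid: i for i, sid in enumerate(subject_ids)}
        w = np.array(
            [[s.age_at_dx, 1.0 if s.sex == Sex.male else 0.0] for s in subjects]
        )
        entry = np.array([s.entry_time for s in subjects])
        T = np.array([s.event_time for s in subjects])
        delta = np.array([s.event == EventStatus.kidney_failure for s in subjects])

        y, X, subj, knots, beta_names, fns = [], [], [], {}, {}, []
        for name, sspec in spec.biomarkers.items():
            obs = [o for o in observations if o.biomarker == name and o.subject_id in sidx]
            if obs:
                yk, Xk, groups, colnames, kn = build_design(
                    subjects, observations, name, sspec
                )
                sk = np.array([sidx[g] for g in groups])
            else:
                kn = resolve_knots(np.linspace(0, max(T)), sspec)
                yk = np.empty(0)
                Xk = np.empty((0, 3 + kn.df))
                sk = np.empty(0, int)
                colnames = ["intercept", "age_at_dx", "sex_male"] + [
                    f"ns_time_{j+1}" for j in range(kn.df)
                ]
            y.append(yk)
            X.append(Xk)
            subj.append(sk)
            knots[name] = kn
            beta_names[name] = colnames
            def _basis(t, kn=kn):
                # event times / quadrature nodes may exceed the last
                # observation time; the natural spline extends linearly there
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    return ns_basis(t, kn)

            fns.append(_basis)

        ev_times = np.sort(T[delta])
        J = spec.n_hazard_intervals
        if ev_times.size >= 2:
            qs = np.quantile(ev_times, np.linspace(0, 1, J + 1)[1:-1])
            breaks = np.unique(np.r_[0.0, qs])
        else:
            breaks = np.array([0.0])
        data = cls(
            names, subject_ids, w, y, X, subj, entry, T, delta, breaks,
            spec.quad_nodes, knots, beta_names,
        )
        data._time_design = fns
        data.set_time_designs(fns)
        return data

    def signature(self) -> str:
        h = hashlib.sha256()
        for arr in (self.w, self.entry, self.T, self.delta.astype(np.int8), *self.y):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:16]

    # -- likelihood pieces ----------------------------------------------------

    def loglik_longitudinal(self, state: ParamState, b: np.ndarray) -> float:
        ll = 0.0
        for k in range(self.K):
            if self.y[k].size == 0:
                continue
            r = self.y[k] - self.X[k] @ state.beta[k] - b[self.subj[k], k]
            s2 = state.sigma[k] ** 2
            ll += -0.5 * (self.y[k].size * np.log(2 * np.pi * s2) + r @ r / s2)
        return float(ll)

    def _node_logpred(self, state: ParamState, b: np.ndarray) -> np.ndarray:
        lp = self.w[self.q_subj] @ state.gamma
        for k in range(self.K):
            lp = lp + state.alpha[k] * (self.Xq[k] @ state.beta[k] + b[self.q_subj, k])
        return lp

    def loglik_survival(self, state: ParamState, b: np.ndarray) -> float:
        if self.q_t.size == 0 and not self.delta.any():
            return 0.0
        Lam = float(
            np.dot(self.q_w, state.lam[self.q_interval] * np.exp(self._node_logpred(state, b)))
        )
        lp_ev = self.w @ state.gamma
        for k in range(self.K):
            lp_ev = lp_ev + state.alpha[k] * (self.Xev[k] @ state.beta[k] + b[:, k])
        ev = float(np.sum(np.log(state.lam[self.ev_interval][self.delta])) +
                   lp_ev[self.delta].sum())
        return ev - Lam

    def loglik_raneff(self, state: ParamState, b: np.ndarray) -> float:
        sign, logdet = np.linalg.slogdet(state.D)
        if sign <= 0:
            return -np.inf
        Dinv = np.linalg.inv(state.D)
        quad = np.einsum("ij,jk,ik->", b, Dinv, b)
        return float(-0.5 * (self.n * (self.K * np.log(2 * np.pi) + logdet) + quad))


def joint_log_likelihood(state: ParamState, b: np.ndarray, data: JointData) -> float:
    """Complete-data joint log density: longitudinal Gaussian terms, the
    survival term log h(T)^delta - Lambda(entry, T), and the N(0, D) density
    of the random intercepts.  A non-positive-definite D yields -inf (the
    draw is rejectable) rather than an exception."""
    eig = np.linalg.eigvalsh((state.D + state.D.T) / 2)
    if eig.min() <= 0:
        return -np.inf
    return (
        data.loglik_longitudinal(state, b)
        + data.loglik_survival(state, b)
        + data.loglik_raneff(state, b)
    )


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

class _Chain:
    def __init__(self, data: JointData, spec: JointModelSpec, init: ParamState,
                 b_init: np.ndarray, rng: np.random.Generator):
        self.d, self.spec, self.rng = data, spec, rng
        self.state = init.copy()
        self.b = b_init.copy()
        K = data.K
        self.alpha_free = np.array(
            [name not in spec.alpha_fixed for name in data.names]
        )
        for k, name in enumerate(data.names):
            if name in spec.alpha_fixed:
                self.state.alpha[k] = spec.alpha_fixed[name]
        # adaptation state
        self.log_s_b = np.log(0.5)
        self.log_s_sigma = np.full(K, np.log(0.3))
        d_phi = 2 + int(self.alpha_free.sum())
        self.phi_scale = 1.0
        free = np.flatnonzero(self.alpha_free)
        self.phi_mean = np.r_[self.state.gamma, self.state.alpha[free]]
        self.phi_cov = np.eye(d_phi) * 0.01
        self.phi_count = 0
        self.log_s_swap = np.full(K, np.log(0.2))
        self.it = 0
        self._refresh_beta_caches()
        self._refresh_node_caches()

    # caches ------------------------------------------------------------
    def _refresh_beta_caches(self) -> None:
        d, st = self.d, self.state
        self.resid = [d.y[k] - d.X[k] @ st.beta[k] for k in range(d.K)]
        self.ssum = np.column_stack(
            [
                np.bincount(d.subj[k], weights=self.resid[k], minlength=d.n)
                if d.y[k].size
                else np.zeros(d.n)
                for k in range(d.K)
            ]
        )
        self.Mq = np.column_stack([d.Xq[k] @ st.beta[k] for k in range(d.K)])
        self.Mev = np.column_stack([d.Xev[k] @ st.beta[k] for k in range(d.K)])

    def _refresh_node_caches(self) -> None:
        """Per-node hazard pieces excluding the subject's b contribution."""
        d, st = self.d, self.state
        lp_fixed = d.w[d.q_subj] @ st.gamma + self.Mq @ st.alpha
        self.node_base = d.q_w * st.lam[d.q_interval] * np.exp(lp_fixed)

    # survival loglik as function of phi = (gamma, alpha_free) ----------
    def _surv_loglik_phi(self, gamma: np.ndarray, alpha: np.ndarray) -> float:
        d = self.d
        lpq = d.w[d.q_subj] @ gamma + (self.Mq + self.b[d.q_subj]) @ alpha
        Lam = float(np.dot(d.q_w * self.state.lam[d.q_interval], np.exp(lpq)))
        lp_ev = d.w @ gamma + (self.Mev + self.b) @ alpha
        ev = float(lp_ev[d.delta].sum())
        return ev - Lam

    # block updates -----------------------------------------------------
    def update_b(self) -> None:
        """Independence Metropolis on each subject's random-intercept vector.

        The proposal is the exact Gaussian conditional given the longitudinal
        data and the N(0, D) prior, so those factors cancel in the acceptance
        ratio and only the survival factor remains.  Because b is constant in
        time, Lambda_i(b_i) = base_i * exp(alpha . b_i) with base_i the
        b-free quadrature sum, so the ratio is a couple of exps per subject.
        Acceptance is typically near 1 and the field decorrelates in one
        sweep, which is what makes the alternation with the (gamma, alpha)
        block mix.
        """
        d, st, rng = self.d, self.state, self.rng
        Dinv = np.linalg.inv(st.D)
        prec = Dinv[None, :, :] + (
            d.ncount[:, :, None] / (st.sigma**2)[None, :, None] * np.eye(d.K)[None, :, :]
        )
        V = np.linalg.inv(prec)
        mean = np.einsum("nij,nj->ni", V, self.ssum / st.sigma**2)
        Lv = np.linalg.cholesky(V)
        prop = mean + np.einsum("nij,nj->ni", Lv, rng.standard_normal((d.n, d.K)))
        base = np.bincount(d.q_subj, weights=self.node_base, minlength=d.n) \
            if d.q_t.size else np.zeros(d.n)
        ab_old = self.b @ st.alpha
        ab_new = prop @ st.alpha
        logr = d.delta * (ab_new - ab_old) - base * (np.exp(ab_new) - np.exp(ab_old))
        acc = np.log(rng.random(d.n)) < logr
        self.b[acc] = prop[acc]

    def update_beta(self) -> None:
        d, st, rng = self.d, self.state, self.rng
        for k in range(d.K):
            if d.y[k].size == 0:
                continue
            s2 = st.sigma[k] ** 2
            Xk, yk = d.X[k], d.y[k]
            prec = Xk.T @ Xk / s2 + np.eye(Xk.shape[1]) / self.spec.coef_prior_sd**2
            rhs = Xk.T @ (yk - self.b[d.subj[k], k]) / s2
            cl = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, rhs)
            prop = mean + np.linalg.solve(cl.T, rng.standard_normal(len(rhs)))
            if st.alpha[k] == 0.0:
                st.beta[k] = prop  # exact Gibbs: survival factor does not involve beta_k
                continue
            # Metropolis correction by the survival factor
            dq = d.Xq[k] @ (prop - st.beta[k])
            dev = d.Xev[k] @ (prop - st.beta[k])
            new_base_term = self.node_base * np.expm1(st.alpha[k] * dq)
            dLam = float(np.dot(np.exp(self.b[d.q_subj] @ st.alpha), new_base_term)) \
                if d.q_t.size else 0.0
            dEv = float(st.alpha[k] * dev[d.delta].sum())
            logr = dEv - dLam
            if np.log(rng.random()) < logr:
                st.beta[k] = prop
                self.resid[k] = yk - Xk @ prop
                self.ssum[:, k] = np.bincount(d.subj[k], weights=self.resid[k], minlength=d.n)
                self.Mq[:, k] = d.Xq[k] @ prop
                self.Mev[:, k] = d.Xev[k] @ prop
                self._refresh_node_caches()

    def update_sigma(self) -> None:
        d, st, rng = self.d, self.state, self.rng
        for k in range(d.K):
            Nk = d.y[k].size
            if Nk == 0:
                continue
            r = self.resid[k] - self.b[d.subj[k], k]
            rss = float(r @ r)
            cur = np.log(st.sigma[k])

            def target(ls: float) -> float:
                sig = np.exp(ls)
                return (-Nk * ls - rss / (2 * sig**2)
                        - sig**2 / (2 * self.spec.sd_prior_scale**2) + ls)

            prop = cur + np.exp(self.log_s_sigma[k]) * rng.standard_normal()
            acc = np.log(rng.random()) < target(prop) - target(cur)
            if acc:
                st.sigma[k] = np.exp(prop)
            if self.it < self.spec.warmup:
                self.log_s_sigma[k] += (float(acc) - 0.44) / (1 + self.it) ** 0.55

    def update_D(self) -> None:
        d, st = self.d, self.state
        nu = d.K + self.spec.iw_prior_df_add + d.n
        S = np.eye(d.K) + self.b.T @ self.b
        st.D = stats.invwishart.rvs(df=nu, scale=S, random_state=self.rng)
        st.D = np.atleast_2d(st.D)

    def update_lambda(self) -> None:
        d, st, rng = self.d, self.state, self.rng
        if d.q_t.size == 0:
            return
        expo = self.node_base / st.lam[d.q_interval] * np.exp(self.b[d.q_subj] @ st.alpha)
        C = np.bincount(d.q_interval, weights=expo, minlength=d.J)
        dj = np.bincount(d.ev_interval[d.delta], minlength=d.J)
        st.lam = rng.gamma(self.spec.hazard_prior_shape + dj,
                           1.0 / (self.spec.hazard_prior_rate + C))
        st.lam = np.clip(st.lam, 1e-12, None)
        self._refresh_node_caches()

    def _surv_loglik_full(self, gamma, alpha, lam) -> float:
        d = self.d
        lpq = d.w[d.q_subj] @ gamma + (self.Mq + self.b[d.q_subj]) @ alpha
        Lam = float(np.dot(d.q_w * lam[d.q_interval], np.exp(lpq)))
        lp_ev = d.w @ gamma + (self.Mev + self.b) @ alpha
        ev = float(np.sum(np.log(lam[d.ev_interval][d.delta])) + lp_ev[d.delta].sum())
        return ev - Lam

    def update_trend_swap(self) -> None:
        """Joint (alpha_k, baseline-hazard) ridge move.

        When a biomarker's population curve trends in time, a change in
        alpha_k can be nearly absorbed by re-tilting the piecewise-constant
        baseline, creating a posterior ridge that axis-aligned updates walk
        slowly.  This move proposes alpha_k -> alpha_k + eps together with
        log lam_j -> log lam_j - eps * mbar_k(j), where mbar_k(j) is the
        current exposure-weighted mean of the biomarker's predicted value in
        baseline interval j, and accepts with the exact posterior ratio
        (multiplicative lambda Jacobian included).
        """
        d, st, rng = self.d, self.state, self.rng
        if d.q_t.size == 0:
            return
        # mbar uses hazard-independent weights (plain quadrature time weights)
        # so the move is symmetric in (alpha_k, lam)
        denom = np.bincount(d.q_interval, weights=d.q_w, minlength=d.J)
        for k in np.flatnonzero(self.alpha_free):
            mk = self.Mq[:, k] + self.b[d.q_subj, k]
            mbar = np.bincount(d.q_interval, weights=d.q_w * mk, minlength=d.J) / \
                np.where(denom > 0, denom, 1.0)
            eps = np.exp(self.log_s_swap[k]) * rng.standard_normal()
            a_new = st.alpha.copy()
            a_new[k] += eps
            lam_new = st.lam * np.exp(-eps * mbar)
            a0, b0 = self.spec.hazard_prior_shape, self.spec.hazard_prior_rate
            logr = (
                self._surv_loglik_full(st.gamma, a_new, lam_new)
                - self._surv_loglik_full(st.gamma, st.alpha, st.lam)
                - 0.5 * (a_new[k] ** 2 - st.alpha[k] ** 2) / self.spec.coef_prior_sd**2
                + a0 * float(np.sum(np.log(lam_new / st.lam)))
                - b0 * float(np.sum(lam_new - st.lam))
            )
            acc = np.log(rng.random()) < logr
            if acc:
                st.alpha = a_new
                st.lam = lam_new
                self._refresh_node_caches()
            if self.it < self.spec.warmup:
                self.log_s_swap[k] += (float(acc) - 0.25) / (1 + self.it) ** 0.55

    def update_phi(self, n_substeps: int = 5) -> None:
        """Adaptive random-walk Metropolis on phi = (gamma, free alpha).

        Proposal covariance is the running empirical posterior covariance
        (Haario-style) times an acceptance-adapted global scale; both are
        frozen at the end of warmup.
        """
        d, st, rng = self.d, self.state, self.rng
        free = np.flatnonzero(self.alpha_free)
        dphi = 2 + len(free)
        cov = self.phi_cov + 1e-8 * np.eye(dphi)
        try:
            Lp = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            Lp = np.eye(dphi) * 0.05
        cur_ll = self._surv_loglik_phi(st.gamma, st.alpha)
        any_acc = False
        for _ in range(n_substeps):
            phi = np.r_[st.gamma, st.alpha[free]]
            prop = phi + self.phi_scale * (Lp @ rng.standard_normal(dphi))
            g_new, a_new = prop[:2], st.alpha.copy()
            a_new[free] = prop[2:]
            pr = -0.5 * (prop @ prop - phi @ phi) / self.spec.coef_prior_sd**2
            new_ll = self._surv_loglik_phi(g_new, a_new)
            acc = np.log(rng.random()) < new_ll - cur_ll + pr
            if acc:
                st.gamma, st.alpha, cur_ll = g_new, a_new, new_ll
                any_acc = True
            if self.it < self.spec.warmup:
                self.phi_scale *= np.exp((float(acc) - 0.25) / (1 + self.it) ** 0.55)
                self.phi_count += 1
                w = 1.0 / self.phi_count
                curr = np.r_[st.gamma, st.alpha[free]]
                delta = curr - self.phi_mean
                self.phi_mean += w * delta
                self.phi_cov = (1 - w) * (self.phi_cov + w * np.outer(delta, delta))
        if any_acc:
            self._refresh_node_caches()

    def iterate(self) -> None:
        self.update_b()
        self.update_beta()
        self.update_b()
        self.update_sigma()
        self.update_D()
        self.update_lambda()
        self.update_phi(n_substeps=8)
        self.update_trend_swap()
        self.update_trend_swap()
        self.it += 1


def _initial_state(
    data: JointData,
    spec: JointModelSpec,
    gamma0: np.ndarray | None = None,
    alpha0: np.ndarray | None = None,
) -> tuple[ParamState, np.ndarray]:
    K, n = data.K, data.n
    betas, sigmas, b0 = [], [], np.zeros((n, K))
    dvar = np.full(K, 0.1)
    for k in range(K):
        if data.y[k].size:
            f = fit_lmm_arrays(data.y[k], data.X[k], data.subj[k])
            betas.append(f.beta)
            sigmas.append(max(f.sigma, 1e-3))
            dvar[k] = max(f.d, 1e-3)
            for i in range(n):
                rows = data.subj[k] == i
                b0[i, k], _ = estimate_random_intercept(
                    f, data.y[k][rows], data.X[k][rows]
                )
        else:
            betas.append(np.zeros(data.X[k].shape[1]))
            sigmas.append(0.5)
    Dcov = np.cov(b0.T) if n > K else np.diag(dvar)
    Dcov = np.atleast_2d(Dcov) + 1e-3 * np.eye(K)
    # crude baseline level: events per person-year of at-risk time
    at_risk = float(np.sum(data.T - data.entry))
    lam0 = max(data.delta.sum(), 1) / max(at_risk, 1e-6)
    state = ParamState(
        beta=betas,
        sigma=np.array(sigmas),
        D=Dcov,
        gamma=np.zeros(2) if gamma0 is None else np.asarray(gamma0, float),
        alpha=np.zeros(K) if alpha0 is None else np.asarray(alpha0, float),
        lam=np.full(data.J, lam0),
    )
    return state, b0


def fit_joint(
    subjects: Sequence[SubjectRecord],
    observations: Sequence[LongitudinalObservation],
    spec: JointModelSpec,
    seed: int,
    enforce_convergence: bool = True,
) -> JointModelFit:
    """Fit the multivariate joint model by MCMC.

    Initialization comes from the per-biomarker mixed-model fits (and their
    empirical Bayes random intercepts); chains use independent seed streams
    derived from ``seed``.  Split-chain R-hat and effective sample size are
    computed for every reported parameter; if ``enforce_convergence`` and
    any R-hat exceeds ``spec.rhat_bound`` or any ESS falls below
    ``spec.ess_min``, a :class:`ConvergenceError` is raised carrying the
    diagnostics and the partial fit.
    """
    data = JointData.from_cohort(subjects, observations, spec)
    gamma0, alpha0 = _cox_init(subjects, observations, spec)
    return _fit_prepared(data, spec, seed, enforce_convergence, gamma0, alpha0)


def _cox_init(subjects, observations, spec: JointModelSpec):
    """Starting values for (gamma, alpha) from an LOCF Cox fit; zeros if the
    comparator cannot be fit (e.g. no subject has all biomarkers)."""
    try:
        from .locf_cox import build_counting_process, fit_cox_td

        table, _ = build_counting_process(subjects, observations, spec.names)
        covs = [f"log_{bm}" for bm in spec.names] + ["age_at_dx", "sex_male"]
        f = fit_cox_td(table, covs)
        alpha0 = np.clip(f.beta[: len(spec.names)], -3, 3)
        gamma0 = np.clip(f.beta[len(spec.names):], -3, 3)
        for k, name in enumerate(spec.names):
            if name in spec.alpha_fixed:
                alpha0[k] = spec.alpha_fixed[name]
        return gamma0, alpha0
    except Exception:
        return None, None


def _fit_prepared(
    data: JointData,
    spec: JointModelSpec,
    seed: int,
    enforce_convergence: bool = True,
    gamma0: np.ndarray | None = None,
    alpha0: np.ndarray | None = None,
) -> JointModelFit:
    init, b0 = _initial_state(data, spec, gamma0, alpha0)
    chain_seeds = np.random.SeedSequence(seed).spawn(spec.chains)
    K, J = data.K, data.J

    store: dict[str, list[np.ndarray]] = {
        "alpha": [], "gamma": [], "sigma": [], "lam": [], "D": [], "b": [], "deviance": [],
    }
    for name in data.names:
        store[f"beta_{name}"] = []

    for cs in chain_seeds:
        rng = np.random.default_rng(cs)
        chain = _Chain(data, spec, init, b0, rng)
        keep = {k: [] for k in store}
        for it in range(spec.warmup + spec.draws):
            chain.iterate()
            if it >= spec.warmup:
                st = chain.state
                keep["alpha"].append(st.alpha.copy())
                keep["gamma"].append(st.gamma.copy())
                keep["sigma"].append(st.sigma.copy())
                keep["lam"].append(st.lam.copy())
                keep["D"].append(st.D.copy())
                keep["b"].append(chain.b.copy())
                dev = -2.0 * (
                    data.loglik_longitudinal(st, chain.b)
                    + data.loglik_survival(st, chain.b)
                )
                keep["deviance"].append(dev)
                for k, name in enumerate(data.names):
                    keep[f"beta_{name}"].append(st.beta[k].copy())
        for k in store:
            store[k].append(np.asarray(keep[k]))

    chain_draws = {k: np.stack(v) for k, v in store.items()}  # (C, S, ...)
    draws = {k: v.reshape(-1, *v.shape[2:]) for k, v in chain_draws.items()}

    diagnostics = _diagnostics(chain_draws, data.names, spec)
    dic = _dic_from_draws(draws, data)

    fit = JointModelFit(
        spec=spec,
        names=data.names,
        subject_ids=data.subject_ids,
        knots=data.knots,
        beta_names=data.beta_names,
        draws=draws,
        chain_draws=chain_draws,
        diagnostics=diagnostics,
        dic=dic,
        data_signature=data.signature(),
        _data=data,
    )
    bad = diagnostics[
        (diagnostics["rhat"] > spec.rhat_bound) | (diagnostics["ess"] < spec.ess_min)
    ]
    if enforce_convergence and not bad.empty:
        raise ConvergenceError(
            f"MCMC diagnostics exceeded bounds for: {', '.join(bad['parameter'])}",
            diagnostics, fit,
        )
    return fit


def _diagnostics(chain_draws: dict[str, np.ndarray], names: list[str],
                 spec: JointModelSpec) -> pd.DataFrame:
    import arviz as az

    rows = []
    scalars: dict[str, np.ndarray] = {}
    for k, name in enumerate(names):
        if name not in spec.alpha_fixed:
            scalars[f"alpha[{name}]"] = chain_draws["alpha"][:, :, k]
        scalars[f"sigma[{name}]"] = chain_draws["sigma"][:, :, k]
    scalars["gamma[age_at_dx]"] = chain_draws["gamma"][:, :, 0]
    scalars["gamma[sex_male]"] = chain_draws["gamma"][:, :, 1]
    Dd = chain_draws["D"]
    for a in range(len(names)):
        for bb in range(a, len(names)):
            if a == bb:
                scalars[f"D[{names[a]},{names[a]}]"] = Dd[:, :, a, a]
            else:
                scalars[f"corr[{names[a]},{names[bb]}]"] = Dd[:, :, a, bb] / np.sqrt(
                    Dd[:, :, a, a] * Dd[:, :, bb, bb]
                )
    for pname, arr in scalars.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = float(az.rhat(az.convert_to_dataset(arr))["x"].values)
            ess = float(az.ess(az.convert_to_dataset(arr))["x"].values)
        rows.append({"parameter": pname, "rhat": rhat, "ess": ess})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

def _state_from_draw(draws: dict[str, np.ndarray], data: JointData, s) -> ParamState:
    return ParamState(
        beta=[draws[f"beta_{name}"][s] for name in data.names],
        sigma=draws["sigma"][s],
        D=draws["D"][s],
        gamma=draws["gamma"][s],
        alpha=draws["alpha"][s],
        lam=draws["lam"][s],
    )


def _dic_from_draws(draws: dict[str, np.ndarray], data: JointData) -> float:
    dev = draws["deviance"]
    dbar = float(dev.mean())
    mean_state = ParamState(
        beta=[draws[f"beta_{name}"].mean(axis=0) for name in data.names],
        sigma=draws["sigma"].mean(axis=0),
        D=draws["D"].mean(axis=0),
        gamma=draws["gamma"].mean(axis=0),
        alpha=draws["alpha"].mean(axis=0),
        lam=draws["lam"].mean(axis=0),
    )
    b_mean = draws["b"].mean(axis=0)
    d_at_mean = -2.0 * (
        data.loglik_longitudinal(mean_state, b_mean)
        + data.loglik_survival(mean_state, b_mean)
    )
    return dbar + (dbar - d_at_mean)


def compute_dic(fit: JointModelFit) -> dict:
    """Conditional-deviance DIC: D_bar + pD with pD = D_bar - D(posterior mean).

    The deviance conditions on the random intercepts (longitudinal +
    survival likelihood given b), the usual choice for shared-random-effect
    joint models; random effects are plugged in at their posterior means for
    D(posterior mean).  A degenerate one-draw posterior gives pD = 0.
    """
    dev = fit.draws["deviance"]
    dic = _dic_from_draws(fit.draws, fit._data)
    dbar = float(dev.mean())
    return {"dic": dic, "dbar": dbar, "pd": dic - dbar}


def hazard_ratio_per_doubling(
    fit_or_draws, name: str | None = None, level: float = 0.95
) -> dict:
    """Per-doubling hazard ratio 2^beta applied draw-wise.

    Accepts a :class:`JointModelFit` plus a coefficient name, or a raw array
    of natural-log-scale coefficient draws.  Point estimate is the posterior
    median of 2^beta (equivalently 2^median) with equal-tailed interval.
    """
    if isinstance(fit_or_draws, JointModelFit):
        if name is None:
            raise ValueError("name required with a fit object")
        beta = fit_or_draws.coefficient_draws(name)
    else:
        beta = np.asarray(fit_or_draws, float)
    hr = 2.0**beta
    lo, hi = np.quantile(hr, [(1 - level) / 2, 1 - (1 - level) / 2])
    return {"hr": float(np.median(hr)), "lo": float(lo), "hi": float(hi)}


def random_effect_correlations(fit: JointModelFit, level: float = 0.95) -> pd.DataFrame:
    """Draw-wise correlations of the random intercepts across biomarkers.

    A positive correlation means subjects with persistently higher values of
    one biomarker also tend to have persistently higher values of the other
    (after fixed effects are taken into account).
    """
    if len(fit.names) < 2:
        raise ValueError("correlations need at least 2 biomarkers")
    D = fit.draws["D"]
    sd = np.sqrt(np.einsum("skk->sk", D))
    rows = []
    for a in range(len(fit.names)):
        for b in range(a + 1, len(fit.names)):
            r = D[:, a, b] / (sd[:, a] * sd[:, b])
            lo, hi = np.quantile(r, [(1 - level) / 2, 1 - (1 - level) / 2])
            rows.append(
                {
                    "pair": f"{fit.names[a]}-{fit.names[b]}",
                    "mean": float(r.mean()),
                    "median": float(np.median(r)),
                    "lo": float(lo),
                    "hi": float(hi),
                }
            )
    return pd.DataFrame(rows)


def predict_subject_trajectory(
    fit: JointModelFit,
    subject_id: str,
    biomarker: str,
    times: Sequence[float],
    level: float = 0.95,
) -> pd.DataFrame:
    """Posterior subject-specific predicted biomarker values m_ik(t).

    Returns per-time summaries on the log scale and the original scale; the
    original-scale median is the exponentiated log-scale median (quantile
    equivariance under the monotone transform).
    """
    if subject_id not in fit.subject_ids:
        raise KeyError(f"unknown subject {subject_id!r}")
    if biomarker not in fit.names:
        raise KeyError(f"unknown biomarker {biomarker!r}")
    i = fit.subject_ids.index(subject_id)
    k = fit.names.index(biomarker)
    data = fit._data
    t = np.asarray(times, float)
    Xt = data._design_at(np.full(t.size, i), t, k)
    m = fit.draws[f"beta_{biomarker}"] @ Xt.T + fit.draws["b"][:, i, k][:, None]
    qlo, qhi = (1 - level) / 2, 1 - (1 - level) / 2
    log_med = np.median(m, axis=0)
    return pd.DataFrame(
        {
            "time": t,
            "log_mean": m.mean(axis=0),
            "log_median": log_med,
            "log_lo": np.quantile(m, qlo, axis=0),
            "log_hi": np.quantile(m, qhi, axis=0),
            "value_median": np.exp(log_med),
            "value_lo": np.exp(np.quantile(m, qlo, axis=0)),
            "value_hi": np.exp(np.quantile(m, qhi, axis=0)),
        }
    )
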