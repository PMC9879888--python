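"""Natural cubic spline bases and log-scale random-intercept mixed models.

One linear mixed submodel per biomarker: the natural log of the biomarker is
regressed on age at diagnosis, sex, and a natural cubic spline in years since
diagnosis, with a subject-level random intercept absorbing within-subject
correlation.  These fits are useful standalone and serve as the
initialization (and an independent check) for the joint model.

The spline follows the usual natural-cubic construction: a cubic B-spline
basis on the boundary + internal knots, with the second derivative
constrained to zero at and beyond the boundary knots, so extrapolation
outside the boundary is linear.  With ``k`` internal knots the basis has
``k + 1`` columns (the model supplies its own intercept), matching the
"degrees of freedom" convention of R's ``splines::ns``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, optimize

from .data_model import LongitudinalObservation, Sex, SubjectRecord


@dataclass(frozen=True)
class SplineSpec:
    """Declarative spec for a natural cubic spline in time.

    ``df`` degrees of freedom require ``df - 1`` internal knots, placed at
    ``internal_percentiles`` of the pooled observation times (linear
    interpolation / type-7 quantiles).  Boundary knots default to the data
    min/max but may be fixed.
    """

    df: int
    internal_percentiles: tuple[float, ...]
    boundary_knots: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.df != len(self.internal_percentiles) + 1:
            raise ValueError(
                f"natural cubic spline with df={self.df} needs exactly {self.df - 1} "
                f"internal knots, got {len(self.internal_percentiles)} percentiles"
            )
        if list(self.internal_percentiles) != sorted(self.internal_percentiles):
            raise ValueError("internal percentiles must be increasing")


#: df=2, one internal knot at the median of the time distribution — the
#: functional form used for eGFR and POX.
NS_DF2 = SplineSpec(df=2, internal_percentiles=(50.0,))
#: df=5, internal knots at the 20/40/60/80th percentiles — used for UOX.
NS_DF5 = SplineSpec(df=5, internal_percentiles=(20.0, 40.0, 60.0, 80.0))


@dataclass(frozen=True)
class ResolvedKnots:
    internal: tuple[float, ...]
    boundary: tuple[float, float]

    def __post_init__(self) -> None:
        seq = [self.boundary[0], *self.internal, self.boundary[1]]
        if any(a >= b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"knots must be strictly increasing, got {seq}")

    @property
    def df(self) -> int:
        return len(self.internal) + 1


def resolve_knots(times: Sequence[float], spec: SplineSpec) -> ResolvedKnots:
    """Turn percentile placements into concrete knot locations.

    Internal knots are linear-interpolation (type-7) quantiles of the pooled
    observation times; boundary knots are the data min/max unless fixed in
    the spec.
    """
    t = np.asarray(times, dtype=float)
    distinct = np.unique(t)
    if distinct.size < spec.df + 1:
        raise ValueError(
            f"need at least {spec.df + 1} distinct times to place a df={spec.df} "
            f"natural spline, got {distinct.size}"
        )
    internal = tuple(np.percentile(t, list(spec.internal_percentiles)))
    boundary = spec.boundary_knots or (float(t.min()), float(t.max()))
    return ResolvedKnots(internal=internal, boundary=tuple(boundary))


def _bspline_design(x: np.ndarray, aug_knots: np.ndarray, nu: int = 0) -> np.ndarray:
    ncol = aug_knots.size - 4
    out = np.empty((x.size, ncol))
    for j in range(ncol):
        c = np.zeros(ncol)
        c[j] = 1.0
        out[:, j] = interpolate.splev(x, (aug_knots, c, 3), der=nu)
    return out


def ns_basis(times: Sequence[float], knots: ResolvedKnots) -> np.ndarray:
    """Natural cubic spline design matrix, ``len(times) x knots.df``.

    Columns are continuous with continuous first and second derivatives; the
    second derivative vanishes at and beyond the boundary knots, so values
    outside the boundary are obtained by linear extrapolation (with a
    warning, since the fit is not informed by data there).
    """
    x = np.asarray(times, dtype=float)
    b0, b1 = knots.boundary
    aug = np.r_[[b0] * 4, list(knots.internal), [b1] * 4]

    inside = np.clip(x, b0, b1)
    basis = _bspline_design(inside, aug)
    outside = (x < b0) | (x > b1)
    if np.any(outside):
        warnings.warn(
            "evaluating natural spline outside its boundary knots; "
            "linear extrapolation applied",
            stacklevel=2,
        )
        for bnd in (b0, b1):
            mask = (x < bnd) if bnd == b0 else (x > bnd)
            if not np.any(mask):
                continue
            val = _bspline_design(np.array([bnd]), aug)
            der = _bspline_design(np.array([bnd]), aug, nu=1)
            basis[mask] = val + (x[mask, None] - bnd) * der

    # natural constraint: zero out the two second-derivative dof at the
    # boundaries, and absorb the intercept direction (dropped first column)
    const = _bspline_design(np.array([b0, b1]), aug, nu=2)
    basis = basis[:, 1:]
    const = const[:, 1:]
    q, _ = np.linalg.qr(const.T, mode="complete")
    return basis @ q[:, 2:]


# ---------------------------------------------------------------------------
# Random-intercept linear mixed model (maximum likelihood)
# ---------------------------------------------------------------------------

@dataclass
class LongitudinalSubmodelFit:
    """ML fit of one biomarker's log-scale random-intercept mixed model."""

    biomarker: str
    beta: np.ndarray
    beta_names: list[str]
    sigma: float
    d: float
    loglik: float
    knots: ResolvedKnots | None = None
    n_obs: int = 0
    n_subjects: int = 0

    def summary(self) -> dict:
        return {
            "biomarker": self.biomarker,
            "coefficients": dict(zip(self.beta_names, map(float, self.beta))),
            "residual_sd": float(self.sigma),
            "random_intercept_sd": float(np.sqrt(self.d)),
            "loglik": float(self.loglik),
            "knots": None
            if self.knots is None
            else {"internal": list(self.knots.internal), "boundary": list(self.knots.boundary)},
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "aic": float(2 * (len(self.beta) + 2) - 2 * self.loglik),
        }


def _profile_loglik(lam: float, y: np.ndarray, X: np.ndarray, idx: list[np.ndarray]):
    """Profile (over beta, sigma^2) ML log-likelihood at variance ratio lam=d/sigma^2.

    With a single random intercept, V_i^{-1} = I - lam/(1+lam*n_i) * J by
    Woodbury, so GLS reduces to shrinking per-subject means.
    """
    N = y.size
    XtVX = np.zeros((X.shape[1], X.shape[1]))
    XtVy = np.zeros(X.shape[1])
    logdet = 0.0
    shrink = []
    for rows in idx:
        n_i = rows.size
        w = lam / (1.0 + lam * n_i)
        shrink.append(w)
        Xi, yi = X[rows], y[rows]
        xs, ys = Xi.sum(axis=0), yi.sum()
        XtVX += Xi.T @ Xi - w * np.outer(xs, xs)
        XtVy += Xi.T @ yi - w * xs * ys
        logdet += np.log1p(lam * n_i)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = 0.0
    for rows, w in zip(idx, shrink):
        r = y[rows] - X[rows] @ beta
        rss += r @ r - w * r.sum() ** 2
    sigma2 = rss / N
    ll = -0.5 * (N * np.log(2 * np.pi * sigma2) + logdet + N)
    return ll, beta, sigma2


def fit_lmm_arrays(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, beta_names: list[str] | None = None
) -> LongitudinalSubmodelFit:
    """ML random-intercept LMM on already-built arrays (y on the log scale).

    The variance ratio d/sigma^2 is profiled out and maximized by bounded
    scalar optimization, so the fit is deterministic and the d = 0 boundary
    (e.g. a single subject, where the variance partition is not identifiable)
    is handled without failure.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        names = beta_names or [f"x{j}" for j in range(X.shape[1])]
        raise ValueError(f"singular fixed-effect design; check columns {names}")
    _, inv = np.unique(groups, return_inverse=True)
    idx = [np.flatnonzero(inv == g) for g in range(inv.max() + 1)]

    def neg(log_lam: float) -> float:
        return -_profile_loglik(np.exp(log_lam), y, X, idx)[0]

    ll0, beta0, s20 = _profile_loglik(0.0, y, X, idx)
    res = optimize.minimize_scalar(neg, bounds=(-12.0, 12.0), method="bounded")
    if res.success and -res.fun > ll0:
        lam = float(np.exp(res.x))
        ll, beta, s2 = _profile_loglik(lam, y, X, idx)
    else:  # boundary: no between-subject variance
        lam, ll, beta, s2 = 0.0, ll0, beta0, s20
    sigma = float(np.sqrt(s2))
    return LongitudinalSubmodelFit(
        biomarker="",
        beta=beta,
        beta_names=beta_names or [f"x{j}" for j in range(X.shape[1])],
        sigma=sigma,
        d=float(lam * s2),
        loglik=float(ll),
        n_obs=y.size,
        n_subjects=len(idx),
    )


def build_design(
    subjects: Sequence[SubjectRecord],
    observations: Sequence[LongitudinalObservation],
    biomarker: str,
    spec: SplineSpec,
    knots: ResolvedKnots | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], ResolvedKnots]:
    """Assemble (y_log, X, groups) for one biomarker's submodel.

    Fixed effects: intercept, age at diagnosis, sex (male = 1, female
    reference), natural spline in years since diagnosis.
    """
    subj = {s.subject_id: s for s in subjects}
    obs = [o for o in observations if o.biomarker == biomarker and o.subject_id in subj]
    if not obs:
        raise ValueError(f"no {biomarker} observations among provided subjects")
    times = np.array([o.time for o in obs])
    if knots is None:
        knots = resolve_knots(times, spec)
    B = ns_basis(times, knots)
    age = np.array([subj[o.subject_id].age_at_dx for o in obs])
    male = np.array([1.0 if subj[o.subject_id].sex == Sex.male else 0.0 for o in obs])
    X = np.column_stack([np.ones(len(obs)), age, male, B])
    names = ["intercept", "age_at_dx", "sex_male"] + [f"ns_time_{j+1}" for j in range(B.shape[1])]
    y = np.log([o.value for o in obs])
    groups = np.array([o.subject_id for o in obs])
    return y, X, groups, names, knots


def fit_lmm(
    subjects: Sequence[SubjectRecord],
    observations: Sequence[LongitudinalObservation],
    biomarker: str,
    spec: SplineSpec,
) -> LongitudinalSubmodelFit:
    """Fit the log-scale random-intercept submodel for one biomarker."""
    y, X, groups, names, knots = build_design(subjects, observations, biomarker, spec)
    fit = fit_lmm_arrays(y, X, groups, beta_names=names)
    fit.biomarker = biomarker
    fit.knots = knots
    return fit


def estimate_random_intercept(
    fit: LongitudinalSubmodelFit, y: np.ndarray, X: np.ndarray
) -> tuple[float, bool]:
    """Empirical Bayes posterior mean of one subject's random intercept.

    Returns ``(b_hat, had_data)``; a subject with no observations gets the
    prior mean 0 and ``had_data=False``.  Closed form: shrinkage
    ``d/(d + sigma^2/n)`` applied to the subject's mean residual.
    """
    y = np.atleast_1d(np.asarray(y, float))
    if y.size == 0:
        return 0.0, False
    resid = y - np.atleast_2d(X) @ fit.beta
    n = y.size
    denom = fit.d + fit.sigma**2 / n
    if denom == 0:
        return 0.0, True
    return float(fit.d / denom * resid.mean()), True


def select_spline_spec(
    subjects: Sequence[SubjectRecord],
    observations: Sequence[LongitudinalObservation],
    biomarker: str,
    candidates: Sequence[SplineSpec],
    criterion: Callable[[LongitudinalSubmodelFit], float] | None = None,
) -> tuple[SplineSpec, pd.DataFrame]:
    """Fit each candidate functional form and select the criterion minimizer.

    By default the criterion is AIC; at the joint-model stage the same
    comparison is made on DIC.  Returns the winning spec and the per-spec
    criterion table.
    """
    crit = criterion or (lambda f: f.summary()["aic"])
    rows = []
    for spec in candidates:
        f = fit_lmm(subjects, observations, biomarker, spec)
        rows.append({"df": spec.df, "percentiles": spec.internal_percentiles,
                     "loglik": f.loglik, "criterion": crit(f)})
    table = pd.DataFrame(rows)
    best = int(table["criterion"].idxmin())
    return candidates[best], table
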