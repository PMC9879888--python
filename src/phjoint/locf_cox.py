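"""LOCF time-dependent Cox regression on counting-process data.

The comparator analysis: each biomarker enters the proportional-hazards
model as a step function, holding its last observed (natural-log) value
until the next measurement.  Follow-up for a multivariable model begins at
the first time every requested biomarker has been observed at least once
(left truncation / delayed entry); subjects who never attain all biomarkers
before their event or censoring are excluded.

Conventions (pinned because registries are messy):

* covariate paths are left-continuous -- a measurement exactly at the event
  time does not update the covariate for the event row;
* intervals are half-open ``(start, stop]``; a subject is at risk at ``t``
  iff ``start < t <= stop`` for some row;
* duplicate measurements of one biomarker at one time: last parsed wins,
  with a warning;
* ties between event times are handled by Efron's method by default
  (Breslow available by flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import EventStatus, LongitudinalObservation, Sex, SubjectRecord

COVARIATE_PREFIX = "log_"


@dataclass
class CountingProcessLog:
    n_input: int = 0
    n_retained: int = 0
    excluded_never_complete: list[str] = field(default_factory=list)

    def as_text(self) -> str:
        return (
            f"subjects in: {self.n_input}\n"
            f"excluded, not all biomarkers observed before event/censoring: "
            f"{len(self.excluded_never_complete)} {self.excluded_never_complete}\n"
            f"subjects retained: {self.n_retained}\n"
        )


def build_counting_process(
    subjects: Sequence[SubjectRecord],
    observations: Sequence[LongitudinalObservation],
    biomarkers: Sequence[str],
) -> tuple[pd.DataFrame, CountingProcessLog]:
    """Build the (start, stop] LOCF table for a set of biomarkers.

    Returns a DataFrame with columns ``subject_id, start, stop, event,
    log_<biomarker>..., age_at_dx, sex_male`` and an exclusion log.  Within a
    subject the rows partition ``(entry, exit]`` contiguously; the event
    flag is true only on the final row of a failing subject.
    """
    if not biomarkers:
        raise ValueError("biomarker set must be nonempty")
    log = CountingProcessLog(n_input=len(subjects))
    by_subj: dict[str, dict[str, dict[float, float]]] = {}
    for o in observations:
        if o.biomarker not in biomarkers:
            continue
        slot = by_subj.setdefault(o.subject_id, {}).setdefault(o.biomarker, {})
        if o.time in slot:
            warnings.warn(
                f"duplicate {o.biomarker} measurement for {o.subject_id} at t={o.time}; "
                "last value wins",
                stacklevel=2,
            )
        slot[o.time] = o.value

    rows = []
    for s in subjects:
        series = by_subj.get(s.subject_id, {})
        if any(bm not in series or not series[bm] for bm in biomarkers):
            log.excluded_never_complete.append(s.subject_id)
            continue
        sorted_series = {bm: sorted(series[bm].items()) for bm in biomarkers}
        first_complete = max(ts[0][0] for ts in sorted_series.values())
        entry = max(s.entry_time, first_complete)
        exit_t = s.event_time
        if not entry < exit_t:
            log.excluded_never_complete.append(s.subject_id)
            continue
        # measurement exactly at the event time is ignored (left continuity)
        change_times = sorted(
            {t for ts in sorted_series.values() for t, _ in ts if entry < t < exit_t}
        )
        grid = [entry, *change_times, exit_t]
        for start, stop in zip(grid, grid[1:]):
            row = {
                "subject_id": s.subject_id,
                "start": start,
                "stop": stop,
                "event": stop == exit_t and s.event == EventStatus.kidney_failure,
                "age_at_dx": s.age_at_dx,
                "sex_male": 1.0 if s.sex == Sex.male else 0.0,
            }
            for bm in biomarkers:
                last = [v for t, v in sorted_series[bm] if t <= start]
                row[COVARIATE_PREFIX + bm] = np.log(last[-1])
            rows.append(row)
    log.n_retained = log.n_input - len(log.excluded_never_complete)
    cols = ["subject_id", "start", "stop", "event"] + [
        COVARIATE_PREFIX + bm for bm in biomarkers
    ] + ["age_at_dx", "sex_male"]
    return pd.DataFrame(rows, columns=cols), log


# ---------------------------------------------------------------------------
# Partial-likelihood estimation
# ---------------------------------------------------------------------------

@dataclass
class CoxTDFit:
    beta: np.ndarray
    se: np.ndarray
    names: list[str]
    loglik: float
    loglik_null: float
    n_subjects: int
    n_events: int
    ties: str
    converged: bool
    monotone_flag: bool = False

    def table(self) -> pd.DataFrame:
        z = self.beta / self.se
        p = 2 * stats.norm.sf(np.abs(z))
        lo, hi = self.beta - 1.959963984540054 * self.se, self.beta + 1.959963984540054 * self.se
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "z": z,
                "p": p,
                "hr_per_doubling": 2.0**self.beta,
                "hr_lo": 2.0**lo,
                "hr_hi": 2.0**hi,
            },
            index=self.names,
        )


def _partial_loglik(beta, X, start, stop, event, ties, center=True):
    """Log partial likelihood, gradient and Hessian for counting-process data.

    Covariates are centered internally; the partial likelihood is invariant
    to covariate location, so this only guards the exponentials.
    """
    if center:
        X = X - X.mean(axis=0)
    p = X.shape[1]
    eta = X @ beta
    w = np.exp(eta)
    ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    for t in np.unique(stop[event]):
        at_risk = (start < t) & (t <= stop)
        dead = event & (stop == t)
        Xr, wr = X[at_risk], w[at_risk]
        Xd, wd = X[dead], w[dead]
        d = int(dead.sum())
        S0 = wr.sum()
        S1 = wr @ Xr
        S2 = Xr.T @ (wr[:, None] * Xr)
        S0d, S1d, S2d = wd.sum(), wd @ Xd, Xd.T @ (wd[:, None] * Xd)
        ll += eta[dead].sum()
        fracs = (np.arange(d) / d) if (ties == "efron" and d > 1) else np.zeros(d)
        for f in fracs:
            s0 = S0 - f * S0d
            s1 = S1 - f * S1d
            s2 = S2 - f * S2d
            ll -= np.log(s0)
            grad_term = s1 / s0
            grad -= grad_term
            hess -= s2 / s0 - np.outer(grad_term, grad_term)
        grad += Xd.sum(axis=0)
    return ll, grad, hess


def fit_cox_td(
    table: pd.DataFrame,
    covariates: Sequence[str],
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxTDFit:
    """Fit the time-dependent Cox model by damped Newton iterations.

    Risk sets respect delayed entry (``start < t <= stop``).  A monotone
    partial likelihood (perfect separation) is flagged and the estimate at
    the iteration cap reported with a warning rather than an error.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    X = table[list(covariates)].to_numpy(float)
    start = table["start"].to_numpy(float)
    stop = table["stop"].to_numpy(float)
    event = table["event"].to_numpy(bool)
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events in the counting-process table")

    beta = np.zeros(X.shape[1])
    ll, grad, hess = _partial_loglik(beta, X, start, stop, event, ties)
    ll_null = ll
    converged = False
    monotone = False
    for _ in range(max_iter):
        step = np.linalg.solve(-hess, grad)
        damp = 1.0
        while damp > 1e-8:
            cand = beta + damp * step
            ll_new, grad_new, hess_new = _partial_loglik(cand, X, start, stop, event, ties)
            if ll_new >= ll - 1e-12:
                break
            damp /= 2
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.abs(grad).max() < tol:
            converged = True
            break
        if np.abs(beta).max() > 50:
            monotone = True
            break
    if not converged:
        warnings.warn(
            "Cox partial likelihood did not converge"
            + (" (monotone likelihood / separation suspected)" if monotone else ""),
            stacklevel=2,
        )
    cov = np.linalg.inv(-hess)
    return CoxTDFit(
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        names=list(covariates),
        loglik=float(ll),
        loglik_null=float(ll_null),
        n_subjects=table["subject_id"].nunique(),
        n_events=n_events,
        ties=ties,
        converged=converged,
        monotone_flag=monotone,
    )


def schoenfeld_residuals(fit: CoxTDFit, table: pd.DataFrame) -> pd.DataFrame:
    """Schoenfeld residuals at the fitted coefficients, one row per event.

    Each residual is the case's covariate minus the risk-set weighted mean
    (with Efron's within-tie downweighting when the fit used Efron ties), so
    the residuals sum to the score -- exactly zero per covariate at the MLE.
    """
    X = table[fit.names].to_numpy(float)
    X = X - X.mean(axis=0)  # residuals are location-invariant; centering
    start = table["start"].to_numpy(float)  # guards the exponentials
    stop = table["stop"].to_numpy(float)
    event = table["event"].to_numpy(bool)
    w = np.exp(X @ fit.beta)
    rows = []
    for t in np.unique(stop[event]):
        at_risk = (start < t) & (t <= stop)
        dead = np.flatnonzero(event & (stop == t))
        d = len(dead)
        S0, S1 = w[at_risk].sum(), w[at_risk] @ X[at_risk]
        S0d, S1d = w[dead].sum(), w[dead] @ X[dead]
        for l, idx in enumerate(dead):
            f = (l / d) if (fit.ties == "efron" and d > 1) else 0.0
            mean = (S1 - f * S1d) / (S0 - f * S0d)
            rows.append(
                {"time": t, "subject_id": table["subject_id"].iloc[idx]}
                | dict(zip(fit.names, X[idx] - mean))
            )
    return pd.DataFrame(rows)


def plot_schoenfeld(residuals: pd.DataFrame, names: Sequence[str], path) -> None:
    """Residual-vs-time panels with a lowess smooth (PH diagnostic plot)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from statsmodels.nonparametric.smoothers_lowess import lowess

    fig, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 3.2), squeeze=False)
    for ax, name in zip(axes[0], names):
        ax.scatter(residuals["time"], residuals[name], s=12, alpha=0.6)
        if len(residuals) >= 5:
            sm = lowess(residuals[name], residuals["time"], frac=0.8)
            ax.plot(sm[:, 0], sm[:, 1], color="crimson")
        ax.axhline(0.0, color="gray", lw=0.8)
        ax.set_xlabel("years since diagnosis")
        ax.set_title(name)
    axes[0][0].set_ylabel("Schoenfeld residual")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def subset_ckd3a(
    subjects: Sequence[SubjectRecord],
    observations: Sequence[LongitudinalObservation],
    threshold: float = 60.0,
) -> tuple[list[SubjectRecord], list[LongitudinalObservation]]:
    """Restrict follow-up to after entry into CKD stage 3a (eGFR < 60).

    Each retained subject's entry time becomes their first eGFR observation
    below the threshold; subjects whose eGFR never drops below it are
    excluded.  Observations before the new entry are kept -- they remain
    eligible as carried-forward values at entry.
    """
    first_low: dict[str, float] = {}
    for o in sorted(observations, key=lambda o: o.time):
        if o.biomarker == "eGFR" and o.value < threshold and o.subject_id not in first_low:
            first_low[o.subject_id] = o.time
    kept = []
    for s in subjects:
        t0 = first_low.get(s.subject_id)
        if t0 is None or t0 >= s.event_time:
            continue
        kept.append(
            SubjectRecord(
                subject_id=s.subject_id,
                age_at_dx=s.age_at_dx,
                sex=s.sex,
                entry_time=max(s.entry_time, t0),
                event_time=s.event_time,
                event=s.event,
            )
        )
    kept_ids = {s.subject_id for s in kept}
    return kept, [o for o in observations if o.subject_id in kept_ids]
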