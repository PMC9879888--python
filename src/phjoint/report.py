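"""Pipeline orchestration and publication-style reporting.

``run_pipeline`` chains the analyses the package provides -- cohort
simulation (optional), inclusion filtering, LOCF time-dependent Cox models
(univariable per biomarker and multivariable), joint models (univariate and
multivariate), and the optional multiple-imputation and CKD-3a sensitivity
paths -- and writes side-by-side hazard-ratio tables (per doubling, 2^beta),
the random-effect correlation table, MCMC diagnostics, and a per-subject
trajectory plot contrasting the LOCF step function with the smooth
subject-specific joint-model prediction.  Every stochastic stage takes an
explicit seed and the emitted bundle embeds the configuration, so a rerun
with the same config reproduces the tables byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (
    BIOMARKERS,
    EventStatus,
    LongitudinalObservation,
    SubjectRecord,
    apply_inclusion,
    read_cohort,
    write_cohort,
)
from .joint_model import (
    JointModelSpec,
    fit_joint,
    hazard_ratio_per_doubling,
    predict_subject_trajectory,
    random_effect_correlations,
)
from .locf_cox import (
    build_counting_process,
    fit_cox_td,
    plot_schoenfeld,
    schoenfeld_residuals,
    subset_ckd3a,
)
from .longitudinal_model import NS_DF2, NS_DF5, SplineSpec
from .mi_pooling import impute_baseline, pooled_hr_per_doubling

DEFAULT_SPLINES: dict[str, SplineSpec] = {"POX": NS_DF2, "UOX": NS_DF5, "eGFR": NS_DF2}


@dataclass
class PipelineConfig:
    """Switches, seeds and paths for :func:`run_pipeline`."""

    out_dir: str
    subject_table: str | None = None     # read cohort from CSVs ...
    long_table: str | None = None
    simulate: bool = False               # ... or simulate one
    n_subjects: int = 166
    seed: int = 20220901
    biomarkers: tuple[str, ...] = BIOMARKERS
    run_locf: bool = True
    run_joint: bool = True
    run_mi: bool = False
    run_ckd3a: bool = False
    m_imputations: int = 20
    mcmc_chains: int = 2
    mcmc_warmup: int = 1000
    mcmc_draws: int = 2500

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def summarize_cohort(
    subjects: Sequence[SubjectRecord],
    observations: Sequence[LongitudinalObservation],
) -> pd.DataFrame:
    """Descriptive cohort table: n, events, follow-up, and per-biomarker
    subject counts with median [IQR] measures per subject (quantiles by
    linear interpolation).  Only observations before the subject's
    event/censoring time are counted."""
    rows = []
    n = len(subjects)
    events = sum(s.event == EventStatus.kidney_failure for s in subjects)
    fu = np.array([s.event_time - s.entry_time for s in subjects])
    rows.append({"measure": "n_subjects", "value": n})
    rows.append({"measure": "n_events", "value": events})
    rows.append({"measure": "event_fraction", "value": events / n if n else np.nan})
    rows.append({"measure": "followup_mean", "value": fu.mean() if n else np.nan})
    rows.append({"measure": "followup_sd", "value": fu.std(ddof=1) if n > 1 else np.nan})
    end = {s.subject_id: s.event_time for s in subjects}
    for bm in BIOMARKERS:
        counts: dict[str, int] = {}
        for o in observations:
            if o.biomarker == bm and o.subject_id in end and o.time < end[o.subject_id]:
                counts[o.subject_id] = counts.get(o.subject_id, 0) + 1
        c = np.array(list(counts.values()))
        rows.append({"measure": f"{bm}_subjects_with_measure", "value": len(c)})
        rows.append({"measure": f"{bm}_total_measures", "value": int(c.sum()) if c.size else 0})
        if c.size:
            med, q1, q3 = np.percentile(c, [50, 25, 75])
            rows.append({"measure": f"{bm}_measures_median", "value": med})
            rows.append({"measure": f"{bm}_measures_q1", "value": q1})
            rows.append({"measure": f"{bm}_measures_q3", "value": q3})
    return pd.DataFrame(rows)


def plot_trajectory_contrast(
    subjects: Sequence[SubjectRecord],
    observations: Sequence[LongitudinalObservation],
    fit,
    subject_id: str,
    biomarker: str,
    path,
) -> None:
    """Observed points, LOCF step function, and the smooth subject-specific
    joint-model prediction with its credible band, for one subject."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    obs = sorted(
        (o for o in observations if o.subject_id == subject_id and o.biomarker == biomarker),
        key=lambda o: o.time,
    )
    subj = next(s for s in subjects if s.subject_id == subject_id)
    t_end = subj.event_time
    grid = np.linspace(max(0.0, min((o.time for o in obs), default=0.0)), t_end, 120)
    pred = predict_subject_trajectory(fit, subject_id, biomarker, grid)

    fig, ax = plt.subplots(figsize=(6, 4))
    if obs:
        ot = [o.time for o in obs]
        ov = [o.value for o in obs]
        ax.step([*ot, t_end], [*ov, ov[-1]], where="post", color="crimson",
                label="LOCF step function")
        ax.plot(ot, ov, "o", color="steelblue", label="observed")
    ax.plot(pred["time"], pred["value_median"], color="black",
            label="subject-specific prediction")
    ax.fill_between(pred["time"], pred["value_lo"], pred["value_hi"],
                    color="gray", alpha=0.25, lw=0)
    ax.set_xlabel("years since diagnosis")
    ax.set_ylabel(biomarker)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _locf_tables(subjects, observations, biomarkers):
    """Univariable (per biomarker) + multivariable LOCF Cox HR table."""
    rows = []
    model_sets = [[bm] for bm in biomarkers]
    if len(biomarkers) > 1:
        model_sets.append(list(biomarkers))
    for bset in model_sets:
        table, log = build_counting_process(subjects, observations, bset)
        if table.empty or not table["event"].any():
            continue
        covs = [f"log_{bm}" for bm in bset] + ["age_at_dx", "sex_male"]
        f = fit_cox_td(table, covs)
        tab = f.table()
        for bm in bset:
            r = tab.loc[f"log_{bm}"]
            rows.append(
                {
                    "model": "+".join(bset),
                    "biomarker": bm,
                    "hr_per_doubling": r["hr_per_doubling"],
                    "hr_lo": r["hr_lo"],
                    "hr_hi": r["hr_hi"],
                    "p": r["p"],
                    "n": f.n_subjects,
                    "events": f.n_events,
                }
            )
    return pd.DataFrame(rows)


def _joint_tables(subjects, observations, biomarkers, seed, chains, warmup, draws):
    """Univariate + multivariate joint-model HR tables and the correlation table."""
    rows, corr, diag, fits = [], None, [], {}
    model_sets = [[bm] for bm in biomarkers]
    if len(biomarkers) > 1:
        model_sets.append(list(biomarkers))
    for j, bset in enumerate(model_sets):
        spec = JointModelSpec(
            biomarkers={bm: DEFAULT_SPLINES[bm] for bm in bset},
            chains=chains, warmup=warmup, draws=draws,
        )
        fit = fit_joint(subjects, observations, spec, seed=seed + j,
                        enforce_convergence=False)
        fits["+".join(bset)] = fit
        for bm in bset:
            hr = hazard_ratio_per_doubling(fit, bm)
            rows.append(
                {
                    "model": "+".join(bset),
                    "biomarker": bm,
                    "hr_per_doubling": hr["hr"],
                    "hr_lo": hr["lo"],
                    "hr_hi": hr["hi"],
                    "dic": fit.dic,
                }
            )
        d = fit.diagnostics.copy()
        d.insert(0, "model", "+".join(bset))
        diag.append(d)
        if len(bset) > 1:
            corr = random_effect_correlations(fit)
    return pd.DataFrame(rows), corr, pd.concat(diag, ignore_index=True), fits


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns a manifest of written artifacts.

    Any stage failure aborts with the stage name; artifacts written by
    earlier stages persist for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    stage = "setup"
    try:
        stage = "load"
        if config.simulate:
            from .synthetic_cohort import default_config, simulate_cohort

            sim = default_config(n_subjects=config.n_subjects)
            subjects, observations, truth = simulate_cohort(sim, seed=config.seed)
            write_cohort(subjects, observations, out / "subjects.csv", out / "observations.csv")
            (out / "simulation_truth.json").write_text(
                json.dumps(truth.to_jsonable(), indent=1)
            )
            manifest["simulation_truth"] = str(out / "simulation_truth.json")
        else:
            if not (config.subject_table and config.long_table):
                raise ValueError("either simulate=True or both input CSV paths required")
            subjects, observations = read_cohort(config.subject_table, config.long_table)

        stage = "inclusion"
        subjects, observations, inc_log = apply_inclusion(subjects, observations)
        (out / "exclusion_log.txt").write_text(inc_log.as_text())
        manifest["exclusion_log"] = str(out / "exclusion_log.txt")

        stage = "summary"
        summary = summarize_cohort(subjects, observations)
        summary.to_csv(out / "cohort_summary.csv", index=False)
        manifest["cohort_summary"] = str(out / "cohort_summary.csv")

        datasets = {"main": (subjects, observations)}
        if config.run_ckd3a:
            stage = "ckd3a_subset"
            datasets["ckd3a"] = subset_ckd3a(subjects, observations)

        for label, (subj_d, obs_d) in datasets.items():
            suffix = "" if label == "main" else f"_{label}"
            if config.run_locf:
                stage = f"locf_cox{suffix}"
                locf = _locf_tables(subj_d, obs_d, config.biomarkers)
                locf.to_csv(out / f"locf_hr{suffix}.csv", index=False)
                manifest[f"locf_hr{suffix}"] = str(out / f"locf_hr{suffix}.csv")
                full = build_counting_process(subj_d, obs_d, list(config.biomarkers))[0]
                full.to_csv(out / f"counting_process{suffix}.csv", index=False)
                if not full.empty and full["event"].any():
                    covs = [f"log_{bm}" for bm in config.biomarkers] + ["age_at_dx", "sex_male"]
                    f = fit_cox_td(full, covs)
                    res = schoenfeld_residuals(f, full)
                    plot_schoenfeld(res, covs, out / f"schoenfeld{suffix}.png")
                    manifest[f"schoenfeld{suffix}"] = str(out / f"schoenfeld{suffix}.png")
            if config.run_joint:
                stage = f"joint_model{suffix}"
                jt, corr, diag, fits = _joint_tables(
                    subj_d, obs_d, config.biomarkers, config.seed,
                    config.mcmc_chains, config.mcmc_warmup, config.mcmc_draws,
                )
                jt.to_csv(out / f"joint_hr{suffix}.csv", index=False)
                manifest[f"joint_hr{suffix}"] = str(out / f"joint_hr{suffix}.csv")
                if corr is not None:
                    corr.to_csv(out / f"random_effect_correlations{suffix}.csv", index=False)
                diag.to_csv(out / f"mcmc_diagnostics{suffix}.csv", index=False)
                if label == "main":
                    stage = "trajectory_plot"
                    key = "+".join(config.biomarkers) if len(config.biomarkers) > 1 \
                        else config.biomarkers[0]
                    bm = config.biomarkers[0]
                    counts: dict[str, int] = {}
                    for o in obs_d:
                        if o.biomarker == bm:
                            counts[o.subject_id] = counts.get(o.subject_id, 0) + 1
                    if counts:
                        sid = max(counts, key=counts.get)
                        plot_trajectory_contrast(
                            subj_d, obs_d, fits[key], sid, bm,
                            out / "trajectory_contrast.png",
                        )
                        manifest["trajectory_contrast"] = str(out / "trajectory_contrast.png")

        if config.run_mi:
            stage = "multiple_imputation"
            datasets_mi = impute_baseline(
                subjects, observations, m=config.m_imputations,
                seed=config.seed + 1000, window=3.0,
                biomarkers=list(config.biomarkers),
            )
            per_imp = []
            for obs_m in datasets_mi:
                table, _ = build_counting_process(subjects, obs_m, list(config.biomarkers))
                if table.empty or not table["event"].any():
                    continue
                covs = [f"log_{bm}" for bm in config.biomarkers] + ["age_at_dx", "sex_male"]
                f = fit_cox_td(table, covs)
                per_imp.append(f)
            rows = []
            for bm in config.biomarkers:
                name = f"log_{bm}"
                est = [
                    (f.beta[f.names.index(name)], f.se[f.names.index(name)] ** 2)
                    for f in per_imp
                ]
                pooled = pooled_hr_per_doubling(est)
                rows.append(
                    {"biomarker": bm, "hr_per_doubling": pooled["hr_per_doubling"],
                     "hr_lo": pooled["hr_lo"], "hr_hi": pooled["hr_hi"],
                     "m": len(per_imp)}
                )
            pd.DataFrame(rows).to_csv(out / "mi_pooled_locf_hr.csv", index=False)
            manifest["mi_pooled_locf_hr"] = str(out / "mi_pooled_locf_hr.csv")

        stage = "provenance"
        prov = {
            "config": dataclasses.asdict(config),
            "config_digest": config.digest(),
            "phjoint_version": __version__,
            "python": sys.version,
            "numpy": np.__version__,
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=1))
        manifest["provenance"] = str(out / "provenance.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return manifest
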