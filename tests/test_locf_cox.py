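"""Counting-process construction, partial likelihood, diagnostics, subsets."""

import numpy as np
import pandas as pd
import pytest

from phjoint.data_model import EventStatus, LongitudinalObservation, Sex, SubjectRecord
from phjoint.locf_cox import (
    build_counting_process,
    fit_cox_td,
    schoenfeld_residuals,
    subset_ckd3a,
)


class TestCountingProcess:
    def test_hand_enumerated_interval_algebra(self, toy_subjects, toy_observations):
        # subject A: POX {0, 2}, UOX {1}, eGFR {0, 1.5}, event at 3
        # -> entry 1 (first time all observed), rows (1,1.5], (1.5,2], (2,3]
        table, _ = build_counting_process(toy_subjects, toy_observations,
                                          ["POX", "UOX", "eGFR"])
        a = table[table.subject_id == "A"].reset_index(drop=True)
        assert list(zip(a.start, a.stop)) == [(1.0, 1.5), (1.5, 2.0), (2.0, 3.0)]
        assert list(a.event) == [False, False, True]
        # LOCF values: row 1 carries POX@0, UOX@1, eGFR@0; row 2 updates eGFR;
        # row 3 updates POX
        assert a.log_POX.tolist() == pytest.approx(
            [np.log(8), np.log(8), np.log(12)]
        )
        assert a.log_UOX.tolist() == pytest.approx([np.log(1.5)] * 3)
        assert a.log_eGFR.tolist() == pytest.approx(
            [np.log(80), np.log(55), np.log(55)]
        )

    def test_all_measured_at_entry_single_row(self, toy_subjects, toy_observations):
        b = build_counting_process(toy_subjects, toy_observations,
                                   ["POX", "UOX", "eGFR"])[0]
        b = b[b.subject_id == "B"]
        assert len(b) == 1
        assert (b.start.iloc[0], b.stop.iloc[0]) == (0.0, 8.0)
        assert not b.event.iloc[0]

    def test_subject_missing_a_biomarker_excluded_and_logged(
        self, toy_subjects, toy_observations
    ):
        table, log = build_counting_process(toy_subjects, toy_observations,
                                            ["POX", "UOX", "eGFR"])
        assert "C" in log.excluded_never_complete
        assert "C" not in set(table.subject_id)
        assert log.n_retained == 2

    def test_measurement_at_event_time_ignored(self):
        subs = [SubjectRecord("X", 10, Sex.female, 0.0, 4.0, EventStatus.kidney_failure)]
        obs = [
            LongitudinalObservation("X", "POX", 0.0, 10.0),
            LongitudinalObservation("X", "POX", 4.0, 99.0),  # exactly at event
        ]
        table, _ = build_counting_process(subs, obs, ["POX"])
        assert len(table) == 1
        assert table.log_POX.iloc[0] == pytest.approx(np.log(10.0))

    def test_duplicate_measurement_last_wins_with_warning(self):
        subs = [SubjectRecord("X", 10, Sex.female, 0.0, 4.0, EventStatus.censored)]
        obs = [
            LongitudinalObservation("X", "POX", 0.0, 10.0),
            LongitudinalObservation("X", "POX", 0.0, 20.0),
        ]
        with pytest.warns(UserWarning, match="duplicate"):
            table, _ = build_counting_process(subs, obs, ["POX"])
        assert table.log_POX.iloc[0] == pytest.approx(np.log(20.0))

    def test_rows_reconstruct_entry_exit_event(self, toy_subjects, toy_observations):
        table, _ = build_counting_process(toy_subjects, toy_observations,
                                          ["POX", "UOX", "eGFR"])
        for sid, g in table.groupby("subject_id"):
            g = g.sort_values("start")
            assert np.all(g.start.to_numpy()[1:] == g.stop.to_numpy()[:-1])
            subj = next(s for s in toy_subjects if s.subject_id == sid)
            assert g.stop.iloc[-1] == subj.event_time
            assert g.event.iloc[-1] == (subj.event == EventStatus.kidney_failure)
            assert not g.event.iloc[:-1].any()

    def test_empty_biomarker_set_rejected(self, toy_subjects, toy_observations):
        with pytest.raises(ValueError):
            build_counting_process(toy_subjects, toy_observations, [])


def _toy_table():
    """4 untied subjects, one covariate, delayed entry for one of them."""
    return pd.DataFrame(
        {
            "subject_id": ["a", "b", "c", "d"],
            "start": [0.0, 0.0, 1.0, 0.0],
            "stop": [2.0, 4.0, 5.0, 7.0],
            "event": [True, True, True, False],
            "x": [0.5, -0.2, 0.8, 0.3],
        }
    )


class TestPartialLikelihood:
    def test_null_loglik_equals_neg_sum_log_risksets(self):
        from phjoint.locf_cox import _partial_loglik

        t = _toy_table()
        X = t[["x"]].to_numpy()
        ll, _, _ = _partial_loglik(
            np.zeros(1), X, t.start.to_numpy(), t.stop.to_numpy(),
            t.event.to_numpy(), "efron",
        )
        # risk sets: t=2 -> {a,b,d} (c enters at 1 but 2>1 so c also at risk)
        # start < t <= stop: at t=2: a,b,c,d? c: start=1 < 2 <= 5 yes. So 4.
        # at t=4: b,c,d (3); at t=5: c,d (2)
        assert ll == pytest.approx(-(np.log(4) + np.log(3) + np.log(2)))

    def test_mle_matches_grid_search(self):
        t = _toy_table()
        fit = fit_cox_td(t, ["x"])
        from phjoint.locf_cox import _partial_loglik

        X = t[["x"]].to_numpy()
        grid = np.arange(-3.0, 3.0, 1e-4)
        lls = [
            _partial_loglik(np.array([g]), X, t.start.to_numpy(),
                            t.stop.to_numpy(), t.event.to_numpy(), "efron")[0]
            for g in grid
        ]
        assert fit.beta[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)

    def test_efron_equals_breslow_without_ties(self):
        t = _toy_table()
        fe = fit_cox_td(t, ["x"], ties="efron")
        fb = fit_cox_td(t, ["x"], ties="breslow")
        assert fe.beta == pytest.approx(fb.beta, abs=1e-10)

    def test_matches_lifelines_cox_time_varying(self):
        # independent implementation cross-check on a richer simulated table
        from lifelines import CoxTimeVaryingFitter

        rng = np.random.default_rng(3)
        rows = []
        for i in range(120):
            entry = 0.0
            x = rng.normal()
            T = rng.exponential(2.0 / np.exp(0.5 * x))
            stop = min(T, 4.0)
            rows.append((f"s{i}", entry, stop, T <= 4.0, x, rng.normal()))
        t = pd.DataFrame(rows, columns=["subject_id", "start", "stop", "event", "x", "z"])
        t = t[t.stop > t.start]
        mine = fit_cox_td(t, ["x", "z"])
        ref = CoxTimeVaryingFitter(penalizer=0.0).fit(
            t.rename(columns={"subject_id": "id"}),
            id_col="id", start_col="start", stop_col="stop", event_col="event",
        )
        assert mine.beta == pytest.approx(ref.params_.to_numpy(), abs=1e-5)
        assert mine.se == pytest.approx(ref.standard_errors_.to_numpy(), abs=1e-5)

    def test_zero_events_rejected(self):
        t = _toy_table().assign(event=False)
        with pytest.raises(ValueError, match="no events"):
            fit_cox_td(t, ["x"])

    def test_separation_flagged_not_fatal(self):
        t = _toy_table()
        # covariate perfectly orders the events -> monotone likelihood
        t["x"] = [3.0, 2.0, 1.0, -5.0]
        with pytest.warns(UserWarning, match="converge"):
            fit = fit_cox_td(t, ["x"], max_iter=8)
        assert not fit.converged

    def test_hr_per_doubling_is_2_to_beta(self):
        t = _toy_table()
        fit = fit_cox_td(t, ["x"])
        tab = fit.table()
        assert tab.hr_per_doubling.iloc[0] == pytest.approx(2.0 ** fit.beta[0])


class TestSchoenfeld:
    def test_residuals_sum_to_zero_at_mle(self):
        t = _toy_table()
        fit = fit_cox_td(t, ["x"])
        res = schoenfeld_residuals(fit, t)
        assert res["x"].sum() == pytest.approx(0.0, abs=1e-7)

    def test_null_residual_is_case_minus_riskset_mean(self):
        # 3-subject toy, residual at beta = 0 computed by hand
        t = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c"],
                "start": [0.0, 0.0, 0.0],
                "stop": [1.0, 2.0, 3.0],
                "event": [True, False, False],
                "x": [2.0, 1.0, 0.0],
            }
        )
        fit = fit_cox_td(_toy_table(), ["x"])  # only for the container
        fit.beta = np.zeros(1)
        res = schoenfeld_residuals(fit, t)
        assert res["x"].iloc[0] == pytest.approx(2.0 - (2.0 + 1.0 + 0.0) / 3)

    def test_location_invariance(self):
        t = _toy_table()
        fit = fit_cox_td(t, ["x"])
        r1 = schoenfeld_residuals(fit, t)
        t2 = t.assign(x=t.x + 100.0)
        r2 = schoenfeld_residuals(fit, t2)
        assert r1["x"].to_numpy() == pytest.approx(r2["x"].to_numpy(), abs=1e-8)

    def test_plot_artifact_written(self, tmp_path):
        t = _toy_table()
        fit = fit_cox_td(t, ["x"])
        res = schoenfeld_residuals(fit, t)
        out = tmp_path / "sch.png"
        from phjoint.locf_cox import plot_schoenfeld

        plot_schoenfeld(res, ["x"], out)
        assert out.stat().st_size > 0


class TestCkd3aSubset:
    def _subj(self, sid, event_time=5.0):
        return SubjectRecord(sid, 10.0, Sex.female, 0.0, event_time,
                             EventStatus.kidney_failure)

    def test_threshold_crossing_sets_entry(self):
        subs = [self._subj("A")]
        obs = [
            LongitudinalObservation("A", "eGFR", 0.0, 70.0),
            LongitudinalObservation("A", "eGFR", 2.0, 55.0),
        ]
        kept, _ = subset_ckd3a(subs, obs)
        assert kept[0].entry_time == 2.0

    def test_never_below_threshold_excluded(self):
        subs = [self._subj("A")]
        obs = [LongitudinalObservation("A", "eGFR", 0.0, 70.0)]
        kept, kept_obs = subset_ckd3a(subs, obs)
        assert kept == [] and kept_obs == []

    def test_already_below_at_baseline_entry_unchanged(self):
        subs = [self._subj("A")]
        obs = [LongitudinalObservation("A", "eGFR", 0.0, 50.0)]
        kept, _ = subset_ckd3a(subs, obs)
        assert kept[0].entry_time == 0.0

    def test_earlier_observations_remain_for_locf(self):
        subs = [self._subj("A")]
        obs = [
            LongitudinalObservation("A", "POX", 0.5, 9.0),
            LongitudinalObservation("A", "eGFR", 0.0, 70.0),
            LongitudinalObservation("A", "eGFR", 2.0, 55.0),
        ]
        kept, kept_obs = subset_ckd3a(subs, obs)
        table, _ = build_counting_process(kept, kept_obs, ["POX", "eGFR"])
        assert table.start.min() == 2.0
        assert table.log_POX.iloc[0] == pytest.approx(np.log(9.0))
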