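"""Sample assembly, split schemes, classifier grid and reporting."""

import numpy as np
import pandas as pd
import pytest

from hfdeeg import (
    AccuracyReport,
    SampleTable,
    assemble_samples,
    best_per_scheme,
    make_split,
    run_grid,
    select_hyperparameters,
)
from hfdeeg.classify import (
    PRESENTATION_SPECIFIC,
    SUBJECT_PRESENTATION,
    SUBJECT_SPECIFIC,
)


def synthetic_samples(n_subjects=44, n_presentations=16, n_features=6,
                      separation=0.0, seed=0):
    """Sample table with optional group separation on the first feature."""
    rng = np.random.default_rng(seed)
    rows = []
    pres = [f"{k}{s}" for k in range(1, n_presentations // 2 + 1) for s in "AG"]
    for i in range(n_subjects):
        label = "expert" if i < n_subjects // 2 else "novice"
        sid = f"S{i:02d}"
        for pid in pres:
            feats = rng.normal(size=n_features)
            if label == "novice":
                feats[0] += separation
            rows.append({"subject_id": sid, "presentation_id": pid, "label": label,
                         **{f"f{j}": feats[j] for j in range(n_features)}})
    frame = pd.DataFrame(rows)
    return SampleTable(frame=frame, feature_names=tuple(f"f{j}" for j in range(n_features)))


class TestAssembleSamples:
    def test_rows_are_subject_presentation_pairs(self, effect_features, effect_cohort):
        mon = effect_cohort.montage
        samples = assemble_samples(effect_features, mon)
        n_subj = len(effect_cohort.manifest.subjects)
        n_pres = len(effect_cohort.manifest.presentations)
        assert len(samples) == n_subj * n_pres
        assert len(samples.feature_names) == len(mon.eeg_names)
        assert sorted(set(samples.frame.label)) == ["expert", "novice"]

    def test_standard_subset_restricts_columns(self, effect_features, effect_cohort):
        samples = assemble_samples(effect_features, effect_cohort.montage,
                                   channel_set="std32")
        assert set(samples.feature_names) == set(effect_cohort.montage.standard32_names)

    def test_windowed_single_presentation_has_channel_by_window_columns(
            self, effect_cohort):
        from hfdeeg import HfdParams, extract_features
        table = extract_features(effect_cohort, HfdParams(k_max=16, window_seconds=3.0),
                                 conditions=("task",))
        pid, _, dur = effect_cohort.manifest.presentations[0]
        samples = assemble_samples(table, effect_cohort.montage, windowed=True,
                                   presentation_id=pid)
        n_ch = len(effect_cohort.montage.eeg_names)
        assert len(samples.feature_names) == n_ch * int(dur // 3.0)
        assert len(samples) == len(effect_cohort.manifest.subjects)

    def test_inconsistent_window_counts_across_presentations_rejected(
            self, effect_cohort):
        from hfdeeg import HfdParams, extract_features
        durations = {p: d for p, _, d in effect_cohort.manifest.presentations}
        if len(set(int(d // 3.0) for d in durations.values())) > 1:
            table = extract_features(
                effect_cohort, HfdParams(k_max=16, window_seconds=3.0),
                conditions=("task",))
            with pytest.raises(ValueError, match="inconsistent window counts"):
                assemble_samples(table, effect_cohort.montage, windowed=True)


class TestMakeSplit:
    def test_case1_folds_partition_704_rows(self):
        samples = synthetic_samples()
        plan = make_split(samples, SUBJECT_PRESENTATION, n_folds=10, seed=0)
        sizes = sorted(len(v) for _, v in plan.folds)
        assert sizes == [70] * 6 + [71] * 4
        union = np.sort(np.concatenate([v for _, v in plan.folds]))
        assert np.array_equal(union, np.arange(704))

    def test_case2_never_splits_a_subject(self):
        samples = synthetic_samples()
        for seed in range(3):
            plan = make_split(samples, SUBJECT_SPECIFIC, n_folds=10, seed=seed)
            subj = samples.frame.subject_id.to_numpy()
            for train, val in plan.folds:
                assert not set(subj[train]) & set(subj[val])

    def test_case3_uses_only_that_presentations_rows(self):
        samples = synthetic_samples()
        plan = make_split(samples, PRESENTATION_SPECIFIC, n_folds=10, seed=1,
                          presentation_id="7A")
        rows = np.concatenate([v for _, v in plan.folds])
        assert len(rows) == 44
        assert (samples.frame.loc[rows, "presentation_id"] == "7A").all()

    def test_presentation_id_required_iff_case3(self):
        samples = synthetic_samples(n_subjects=4, n_presentations=2)
        with pytest.raises(ValueError):
            make_split(samples, SUBJECT_PRESENTATION, presentation_id="1A")
        with pytest.raises(ValueError):
            make_split(samples, PRESENTATION_SPECIFIC)

    def test_too_many_folds_rejected(self):
        samples = synthetic_samples(n_subjects=4, n_presentations=2)
        with pytest.raises(ValueError, match="folds exceed"):
            make_split(samples, SUBJECT_SPECIFIC, n_folds=10, seed=0)

    def test_plan_serialises_to_json(self, tmp_path):
        import json
        samples = synthetic_samples(n_subjects=6, n_presentations=2)
        plan = make_split(samples, SUBJECT_SPECIFIC, n_folds=3, seed=0)
        plan.to_json(tmp_path / "plan.json")
        loaded = json.loads((tmp_path / "plan.json").read_text())
        assert loaded["scheme"] == SUBJECT_SPECIFIC
        assert len(loaded["folds"]) == 3


class TestRunGrid:
    def test_separable_dataset_classified_perfectly(self):
        samples = synthetic_samples(n_subjects=12, n_presentations=4,
                                    separation=6.0, seed=1)
        hp = {"linear_svm": {"C": 0.5}}
        report = run_grid(samples, schemes=(SUBJECT_PRESENTATION,),
                          seeds=(0,), n_folds=5, hyperparameters=hp)
        assert report.mean_accuracy(SUBJECT_PRESENTATION, "linear_svm") == 1.0

    def test_report_is_reproducible(self):
        samples = synthetic_samples(n_subjects=12, n_presentations=4,
                                    separation=1.0, seed=2)
        hp = {"nearest_neighbors": {"n_neighbors": 3},
              "decision_tree": {"max_depth": 3}}
        r1 = run_grid(samples, schemes=(SUBJECT_PRESENTATION, SUBJECT_SPECIFIC),
                      seeds=(0, 1), n_folds=4, hyperparameters=hp)
        r2 = run_grid(samples, schemes=(SUBJECT_PRESENTATION, SUBJECT_SPECIFIC),
                      seeds=(0, 1), n_folds=4, hyperparameters=hp)
        pd.testing.assert_frame_equal(r1.frame, r2.frame)

    def test_hyperparameters_chosen_from_grid(self):
        samples = synthetic_samples(n_subjects=8, n_presentations=2,
                                    separation=2.0, seed=3)
        grid = {"nearest_neighbors": {"n_neighbors": [3, 5]},
                "decision_tree": {"max_depth": [3, 7]}}
        hp = select_hyperparameters(samples, grid, seeds=(0,), n_folds=4)
        assert hp["nearest_neighbors"]["n_neighbors"] in (3, 5)
        assert hp["decision_tree"]["max_depth"] in (3, 7)

    def test_case3_reports_per_presentation(self):
        samples = synthetic_samples(n_subjects=10, n_presentations=4,
                                    separation=3.0, seed=4)
        hp = {"linear_svm": {"C": 0.5}}
        report = run_grid(samples, schemes=(PRESENTATION_SPECIFIC,), seeds=(0,),
                          n_folds=5, hyperparameters=hp)
        assert sorted(report.frame.presentation_id.unique()) == ["1A", "1G", "2A", "2G"]


class TestBestPerScheme:
    def _report(self, accs):
        rows = [{"scheme": "subject_presentation", "presentation_id": None,
                 "algorithm": alg, "seed": 0, "accuracy": a, "n_folds_used": 10}
                for alg, a in accs.items()]
        return AccuracyReport(frame=pd.DataFrame(rows), hyperparameters={})

    def test_maximum_over_algorithms(self):
        best = best_per_scheme(self._report(
            {"nearest_neighbors": 0.6, "linear_svm": 0.7, "decision_tree": 0.65}))
        assert best.accuracy.iloc[0] == pytest.approx(0.7)
        assert best.algorithms.iloc[0] == ["linear_svm"]

    def test_ties_report_all_algorithms(self):
        best = best_per_scheme(self._report({"linear_svm": 0.7, "adaboost": 0.7}))
        assert best.algorithms.iloc[0] == ["adaboost", "linear_svm"]

    def test_single_algorithm_report(self):
        best = best_per_scheme(self._report({"adaboost": 0.61}))
        assert best.accuracy.iloc[0] == pytest.approx(0.61)


def test_permuted_labels_are_permuted_deterministically():
    samples = synthetic_samples(n_subjects=8, n_presentations=2, seed=5)
    p1 = samples.with_permuted_labels(7)
    p2 = samples.with_permuted_labels(7)
    assert (p1.frame.label == p2.frame.label).all()
    assert sorted(p1.frame.label) == sorted(samples.frame.label)
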