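"""Evaluation tests: metrics arithmetic, LOSO mechanics, down-selection
structure, extended-phase contract and isolation audits."""

import numpy as np
import pytest

from peblkit import (
    audit_blind_isolation,
    default_spec,
    evaluate_extended,
    feature_matrices,
    loso_evaluate,
    metrics,
    simulate_aligned_cohort,
)
from peblkit.evaluation import downselect, extended_setups
from peblkit.synthetic import CohortJitter
from peblkit.tuning import TuningConfig

from conftest import SHORT_PROTOCOL

RNG = np.random.default_rng(99)


class TestMetrics:
    def test_perfect_predictions(self):
        m = metrics(np.array([0.1, 0.2, 0.3]), np.array([0.1, 0.2, 0.3]))
        assert (m.r2, m.mse, m.mae) == (1.0, 0.0, 0.0)

    def test_mean_predictor_has_zero_r2(self):
        truth = np.array([0.0, 0.2, 0.4, 0.6])
        m = metrics(np.full(4, truth.mean()), truth)
        assert m.r2 == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        m = metrics(np.array([0.1, 0.2, 0.3]), np.array([0.0, 0.2, 0.4]))
        assert m.mae == pytest.approx(0.2 / 3)
        assert m.mse == pytest.approx(0.02 / 3)
        assert m.r2 == pytest.approx(0.75)

    def test_agrees_with_sklearn_to_machine_precision(self):
        from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

        for _ in range(10):
            t = RNG.normal(size=50)
            p = t + RNG.normal(0, 0.3, 50)
            m = metrics(p, t)
            assert m.r2 == pytest.approx(r2_score(t, p), abs=1e-12)
            assert m.mse == pytest.approx(mean_squared_error(t, p), abs=1e-12)
            assert m.mae == pytest.approx(mean_absolute_error(t, p), abs=1e-12)

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            metrics(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError):
            metrics(np.zeros(3), np.full(3, 0.5))  # constant truth


@pytest.fixture(scope="module")
def tiny_cohort_matrices():
    """6-subject compact cohort: 5 s and 10 s un-normalized matrices."""
    trunc, full = simulate_aligned_cohort(6, seed=21, protocol=SHORT_PROTOCOL)
    return (
        feature_matrices(trunc, (5, 10)),
        feature_matrices(full, (5, 10), target="fluid_balance"),
    )


class TestLoso:
    def test_each_subject_blind_exactly_once(self, tiny_cohort_matrices):
        mats, _ = tiny_cohort_matrices
        res = loso_evaluate(default_spec("enet"), mats[5])
        assert sorted(res.per_subject["subject_id"]) == sorted(mats[5].subjects())
        assert res.per_subject["subject_id"].is_unique
        assert audit_blind_isolation(res)

    def test_identical_noiseless_subjects_recover_nearly_perfectly(self):
        # zero jitter + zero noise, coupling on: three identical subjects
        from peblkit import align_cohort, simulate_cohort
        from peblkit.synthetic import NoiseParams, SubjectParams

        coupled = SubjectParams(subject_id="c", noise=NoiseParams(0, 0, 0), seed=0)
        recs = simulate_cohort(
            3, base_params=coupled, protocol=SHORT_PROTOCOL,
            seed=1, jitter=CohortJitter(0, 0, 0, 0),
        )
        mats = feature_matrices(align_cohort(recs), (5,))
        res = loso_evaluate(default_spec("rf", seed=0), mats[5])
        assert (res.per_subject["r2"] > 0.95).all()

    def test_summary_matches_recomputation_from_predictions(self, tiny_cohort_matrices):
        mats, _ = tiny_cohort_matrices
        res = loso_evaluate(default_spec("enet"), mats[5])
        for _, row in res.per_subject.iterrows():
            y_true, y_pred = res.predictions[row["subject_id"]]
            m = metrics(y_pred, y_true)
            assert row["r2"] == pytest.approx(m.r2)
            assert row["mae"] == pytest.approx(m.mae)
        assert res.mean_r2 == pytest.approx(res.per_subject["r2"].mean())

    def test_needs_three_subjects(self, tiny_cohort_matrices):
        from peblkit.features import split_by_subjects

        mats, _ = tiny_cohort_matrices
        subjects = mats[5].subjects()
        two, _ = split_by_subjects(mats[5], set(subjects[2:]))
        with pytest.raises(ValueError):
            loso_evaluate(default_spec("enet"), two)


@pytest.fixture(scope="module")
def table(tiny_cohort_matrices):
    mats, _ = tiny_cohort_matrices
    cfg = TuningConfig(n_iterations=8, n_validation_subjects=2, seed=0)
    return downselect(
        mats, architectures=("rf", "enet", "svr", "xgb"), seed=0, tuning_config=cfg
    )


class TestDownselect:
    def test_stage_structure(self, table):
        df = table.df
        assert len(df[df["stage"] == 1]) == 8  # 4 architectures x 2 windows
        assert len(table.stage_architectures(2)) == 3
        assert len(table.stage_architectures(3)) == 2
        assert df["final"].sum() == 1

    def test_final_flag_is_best_mean_r2_among_candidates(self, table):
        final = table.final_row()
        advanced = table.df[table.df["advanced"]]
        assert final["mean_r2"] == advanced["mean_r2"].max()

    def test_downselection_is_deterministic(self, tiny_cohort_matrices):
        mats, _ = tiny_cohort_matrices
        cfg = TuningConfig(n_iterations=5, n_validation_subjects=2, seed=4)
        t1 = downselect(mats, architectures=("xgb", "enet", "svr"), seed=2, tuning_config=cfg)
        t2 = downselect(mats, architectures=("xgb", "enet", "svr"), seed=2, tuning_config=cfg)
        assert t1.df.equals(t2.df)


class TestExtended:
    def test_extended_report_covers_all_architectures(self, tiny_cohort_matrices):
        mats, full_mats = tiny_cohort_matrices
        setups = {
            arch: {
                "architecture": arch, "window_s": 5, "normalization": "none",
                "tuned": False, "spec": default_spec(arch, seed=0),
            }
            for arch in ("xgb", "rf", "enet", "svr")
        }
        results = evaluate_extended(setups, mats, full_mats)
        assert sorted(results) == ["enet", "rf", "svr", "xgb"]
        for res in results.values():
            assert len(res.per_subject) == 6
            assert audit_blind_isolation(res)

    def test_missing_resuscitation_is_an_error(self, tiny_cohort_matrices):
        mats, _ = tiny_cohort_matrices
        setups = {
            "enet": {
                "architecture": "enet", "window_s": 5, "normalization": "none",
                "tuned": False, "spec": default_spec("enet"),
            }
        }
        with pytest.raises(ValueError, match="resuscitation"):
            evaluate_extended(setups, mats, mats)

    def test_setups_from_table_have_one_entry_per_architecture(self, table):
        setups = extended_setups(table)
        assert sorted(setups) == ["enet", "rf", "svr", "xgb"]
        # eliminated-at-stage-1 architecture keeps untuned, un-normalized setup
        stage1_only = set(table.df["architecture"]) - set(table.stage_architectures(2))
        for arch in stage1_only:
            assert setups[arch]["normalization"] == "none"
            assert setups[arch]["tuned"] is False
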