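"""Leave-one-subject-out evaluation, staged down-selection and the
extended fluid-balance phase.

LOSO evaluation holds each subject out in turn as a fully blind test set,
trains on the remaining subjects and scores the blind predictions with
R², MSE and MAE.  The staged down-selection mirrors the optimization
workflow: (1) every architecture x sampling-window combination is
evaluated un-normalized and the worst architecture (at its best window)
is eliminated 4 -> 3; (2) survivors are evaluated with and without
per-subject 0-1 normalization and the worst is eliminated 3 -> 2; (3) the
two survivors are Bayesian-tuned, tuned vs untuned is decided per
architecture, and the single highest mean-R² configuration is flagged
final.  Mean R² over subjects drives every decision; ties break on lower
mean MSE, then architecture name.

The extended phase redefines the target from PEBL to fluid balance and
scores models trained only on baseline + hemorrhage + hold data against
the full timeline including resuscitation, for all four architectures in
their best pre-elimination setups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import (
    FeatureMatrix,
    normalize_per_subject,
    split_by_subjects,
)
from .modeling import ARCHITECTURES, ModelSpec, default_spec, fit, predict
from .stats import StatTestResult, compare_statistics  # noqa: F401  (re-export)
from .tuning import TuningConfig, TuningResult, tune_bayesian

__all__ = [
    "Metrics",
    "LosoResult",
    "ComparisonTable",
    "metrics",
    "loso_evaluate",
    "downselect",
    "extended_setups",
    "evaluate_extended",
    "compare_statistics",
    "audit_blind_isolation",
    "audit_tuning_isolation",
]


@dataclass(frozen=True)
class Metrics:
    r2: float
    mse: float
    mae: float


def metrics(predictions: np.ndarray, truth: np.ndarray) -> Metrics:
    """R² (about the truth mean), MSE and MAE of a prediction series."""
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    if truth.size < 2:
        raise ValueError("need at least 2 samples")
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 is undefined for constant truth")
    resid = predictions - truth
    ss_res = float(np.sum(resid**2))
    return Metrics(
        r2=1.0 - ss_res / ss_tot,
        mse=float(np.mean(resid**2)),
        mae=float(np.mean(np.abs(resid))),
    )


@dataclass
class LosoResult:
    """Per-blind-subject metrics for one model configuration."""

    configuration: dict
    per_subject: pd.DataFrame  # subject_id, r2, mse, mae, n_windows
    predictions: dict[str, tuple[np.ndarray, np.ndarray]]  # id -> (truth, pred)
    fold_training_subjects: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def mean_r2(self) -> float:
        return float(self.per_subject["r2"].mean())

    @property
    def sd_r2(self) -> float:
        return float(self.per_subject["r2"].std(ddof=1))

    @property
    def mean_mse(self) -> float:
        return float(self.per_subject["mse"].mean())

    @property
    def mean_mae(self) -> float:
        return float(self.per_subject["mae"].mean())

    def summary(self) -> dict[str, float]:
        s = self.per_subject
        return {
            f"{m}_{stat}": float(getattr(s[m], fn)(**kw))
            for m in ("r2", "mse", "mae")
            for stat, fn, kw in (("mean", "mean", {}), ("sd", "std", {"ddof": 1}))
        }


def loso_evaluate(
    spec: ModelSpec,
    matrix: FeatureMatrix,
    configuration: dict | None = None,
) -> LosoResult:
    """Leave-one-subject-out evaluation of one spec on one matrix."""
    subjects = matrix.subjects()
    if len(subjects) < 3:
        raise ValueError("LOSO evaluation needs at least 3 subjects")
    rows, preds, fold_train = [], {}, {}
    for subject in subjects:
        train_m, test_m = split_by_subjects(matrix, {subject})
        if len(test_m.df) < 2:
            continue
        model = fit(spec, train_m)
        y_pred = predict(model, test_m)
        y_true = test_m.y()
        m = metrics(y_pred, y_true)
        rows.append(
            {
                "subject_id": subject,
                "r2": m.r2,
                "mse": m.mse,
                "mae": m.mae,
                "n_windows": len(y_true),
            }
        )
        preds[subject] = (y_true, y_pred)
        fold_train[subject] = model.training_subjects
    return LosoResult(
        configuration=configuration
        or {"architecture": spec.architecture, "spec": spec},
        per_subject=pd.DataFrame(rows),
        predictions=preds,
        fold_training_subjects=fold_train,
    )


# ---------------------------------------------------------------------------
# staged down-selection


@dataclass
class ComparisonTable:
    """All evaluated configurations with their down-selection flags."""

    df: pd.DataFrame
    loso_results: dict[tuple, LosoResult]
    tuning_results: dict[str, TuningResult]

    def final_row(self) -> pd.Series:
        final = self.df[self.df["final"]]
        if len(final) != 1:
            raise ValueError("exactly one configuration must be flagged final")
        return final.iloc[0]

    def stage_architectures(self, stage: int) -> list[str]:
        return sorted(self.df.loc[self.df["stage"] == stage, "architecture"].unique())


def _rank_key(row: dict) -> tuple:
    # higher mean R² first; ties: lower mean MSE, then architecture name
    return (-row["mean_r2"], row["mean_mse"], row["architecture"])


def downselect(
    matrices_by_window: dict[float, FeatureMatrix],
    architectures: tuple[str, ...] = ARCHITECTURES,
    seed: int = 0,
    tuning_config: TuningConfig | None = None,
) -> ComparisonTable:
    """Run the three-stage window -> normalization -> tuning down-selection.

    ``matrices_by_window`` maps window length (s) to the cohort's
    un-normalized feature matrix; tuning uses ``tuning_config`` (default:
    100 iterations, 4 validation subjects) once per surviving architecture
    on a seeded validation split.
    """
    if len(architectures) < 2 or len(matrices_by_window) < 2:
        raise ValueError("need at least 2 architectures and 2 windows")
    rows: list[dict] = []
    loso_results: dict[tuple, LosoResult] = {}
    tuning_results: dict[str, TuningResult] = {}

    def run(arch, window, normalization, tuned, spec, stage) -> dict:
        matrix = matrices_by_window[window]
        if normalization == "per_subject":
            matrix = normalize_per_subject(matrix)
        config = {
            "architecture": arch,
            "window_s": window,
            "normalization": normalization,
            "tuned": tuned,
        }
        res = loso_evaluate(spec, matrix, configuration={**config, "spec": spec})
        key = (arch, window, normalization, tuned)
        loso_results[key] = res
        row = {
            **config,
            "stage": stage,
            "mean_r2": res.mean_r2,
            "sd_r2": res.sd_r2,
            "mean_mse": res.mean_mse,
            "mean_mae": res.mean_mae,
            "advanced": False,
            "final": False,
        }
        rows.append(row)
        return row

    # stage 1: all architecture x window combinations, un-normalized defaults
    best_stage1: dict[str, dict] = {}
    for arch in architectures:
        spec = default_spec(arch, seed=seed)
        arch_rows = [
            run(arch, w, "none", False, spec, stage=1)
            for w in sorted(matrices_by_window)
        ]
        best_stage1[arch] = min(arch_rows, key=_rank_key)
    ranked = sorted(best_stage1.values(), key=_rank_key)
    stage2_archs = [r["architecture"] for r in ranked[:-1]]
    for r in ranked[:-1]:
        r["advanced"] = True

    # stage 2: survivors with vs without per-subject normalization
    best_stage2: dict[str, dict] = {}
    for arch in stage2_archs:
        window = best_stage1[arch]["window_s"]
        spec = default_spec(arch, seed=seed)
        norm_row = run(arch, window, "per_subject", False, spec, stage=2)
        plain_row = best_stage1[arch]
        best_stage2[arch] = min((plain_row, norm_row), key=_rank_key)
    ranked2 = sorted(best_stage2.values(), key=_rank_key)
    stage3_archs = [r["architecture"] for r in ranked2[:-1]]
    for r in ranked2[:-1]:
        r["advanced"] = True

    # stage 3: Bayesian tuning of the two survivors
    candidates: list[dict] = []
    for arch in stage3_archs:
        best = best_stage2[arch]
        window, normalization = best["window_s"], best["normalization"]
        matrix = matrices_by_window[window]
        if normalization == "per_subject":
            matrix = normalize_per_subject(matrix)
        cfg = tuning_config if tuning_config is not None else TuningConfig(seed=seed)
        tuning_results[arch] = tune_bayesian(default_spec(arch, seed=seed), matrix, cfg)
        tuned_row = run(
            arch, window, normalization, True, tuning_results[arch].best_spec, stage=3
        )
        candidates.append(min((best, tuned_row), key=_rank_key))
    winner = min(candidates, key=_rank_key)
    winner["advanced"] = True
    winner["final"] = True

    df = pd.DataFrame(rows)
    return ComparisonTable(df=df, loso_results=loso_results, tuning_results=tuning_results)


# ---------------------------------------------------------------------------
# extended fluid-balance phase


def extended_setups(table: ComparisonTable) -> dict[str, dict]:
    """Best pre-elimination setup per architecture for the extended phase.

    Architectures eliminated before the normalization / tuning stages keep
    un-normalized features and untuned defaults; survivors keep whatever
    configuration won for them.
    """
    setups: dict[str, dict] = {}
    for arch in sorted(table.df["architecture"].unique()):
        sub = table.df[table.df["architecture"] == arch]
        best = sub.sort_values(
            ["mean_r2", "mean_mse", "architecture"], ascending=[False, True, True]
        ).iloc[0]
        key = (arch, best["window_s"], best["normalization"], best["tuned"])
        spec = table.loso_results[key].configuration["spec"]
        setups[arch] = {
            "architecture": arch,
            "window_s": best["window_s"],
            "normalization": best["normalization"],
            "tuned": bool(best["tuned"]),
            "spec": spec,
        }
    return setups


def evaluate_extended(
    setups: dict[str, dict],
    truncated_by_window: dict[float, FeatureMatrix],
    extended_by_window: dict[float, FeatureMatrix],
) -> dict[str, LosoResult]:
    """Score PEBL-trained models against full-timeline fluid balance.

    For each architecture's setup, each LOSO fold trains on the other
    subjects' truncated (baseline + hemorrhage + hold, PEBL-target)
    windows and predicts the blind subject's full timeline, scored against
    the fluid-balance ground truth.
    """
    results: dict[str, LosoResult] = {}
    for arch, setup in setups.items():
        w = setup["window_s"]
        train_mat = truncated_by_window[w]
        test_mat = extended_by_window[w]
        if test_mat.df["start_s"].max() <= train_mat.df["start_s"].max():
            raise ValueError(
                "extended matrix does not reach beyond the truncated timeline: "
                "resuscitation phase is missing"
            )
        if setup["normalization"] == "per_subject":
            train_mat = normalize_per_subject(train_mat)
            test_mat = normalize_per_subject(test_mat)
        spec = setup["spec"]
        subjects = train_mat.subjects()
        rows, preds, fold_train = [], {}, {}
        for subject in subjects:
            train_m, _ = split_by_subjects(train_mat, {subject})
            _, test_m = split_by_subjects(test_mat, {subject})
            if len(test_m.df) < 2:
                continue
            model = fit(spec, train_m)
            y_pred = predict(model, test_m)
            y_true = test_m.y()
            m = metrics(y_pred, y_true)
            rows.append(
                {
                    "subject_id": subject,
                    "r2": m.r2,
                    "mse": m.mse,
                    "mae": m.mae,
                    "n_windows": len(y_true),
                }
            )
            preds[subject] = (y_true, y_pred)
            fold_train[subject] = model.training_subjects
        results[arch] = LosoResult(
            configuration={**setup, "target": "fluid_balance"},
            per_subject=pd.DataFrame(rows),
            predictions=preds,
            fold_training_subjects=fold_train,
        )
    return results


# ---------------------------------------------------------------------------
# protocol audits


def audit_blind_isolation(result: LosoResult) -> bool:
    """True iff no blind subject appears among its own fold's training subjects."""
    return all(
        subject not in trained
        for subject, trained in result.fold_training_subjects.items()
    )


def audit_tuning_isolation(result: TuningResult) -> bool:
    """True iff tuning validation subjects are disjoint from its training subjects."""
    return not set(result.validation_subjects) & set(result.training_subjects)
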