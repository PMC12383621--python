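"""The staged down-selection: window -> normalization -> Bayesian tuning.

Runs all four architectures x four window lengths on a compact cohort,
eliminates the worst architecture after each stage, tunes the two
finalists (here with a reduced tuning budget to keep the example quick)
and prints the comparison table with the final flag.
"""

from peblkit import ProtocolSpec, feature_matrices, simulate_aligned_cohort
from peblkit.evaluation import downselect
from peblkit.tuning import TuningConfig

protocol = ProtocolSpec(
    baseline_duration_s=120, hemorrhage_rate_ml_min=120,
    hemorrhage_target_pebl=0.35, hold_duration_s=120,
    wholeblood_volume_ml=300, wholeblood_rate_ml_min=150,
    crystalloid_rate_ml_min=150, resuscitation_duration_s=300,
)
trunc, _ = simulate_aligned_cohort(6, seed=11, protocol=protocol)
mats = feature_matrices(trunc, (5, 10, 30, 60))

table = downselect(
    mats, seed=0,
    tuning_config=TuningConfig(n_iterations=20, n_validation_subjects=2, seed=0),
)
cols = ["architecture", "window_s", "normalization", "tuned", "stage",
        "mean_r2", "mean_mae", "advanced", "final"]
print(table.df[cols].to_string(index=False,
                               float_format=lambda v: f"{v:.3f}"))
final = table.final_row()
print(f"\nfinal configuration: {final['architecture']} "
      f"({final['window_s']:.0f} s, {final['normalization']}, "
      f"tuned={bool(final['tuned'])}), mean R2 {final['mean_r2']:.3f}")
# Stage 1 evaluates 16 configurations; one architecture is eliminated per
# stage until a single configuration carries the final flag.
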