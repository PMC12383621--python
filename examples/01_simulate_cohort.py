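"""Simulate a small hemorrhage/resuscitation cohort and inspect one subject.

Generates three synthetic subjects on the default protocol (600 s
baseline, hemorrhage to 40% estimated blood loss, hold, whole blood then
crystalloid) and prints each subject's weight, estimated blood volume,
final hemorrhage volume and phase boundaries.
"""

from peblkit import simulate_cohort, total_blood_volume, write_cohort

recordings = simulate_cohort(3, seed=1)
for rec in recordings:
    v_total = total_blood_volume(rec.weight_kg)
    hem = rec.fluid_log["hemorrhage_mL"].max()
    print(f"{rec.subject_id}: weight {rec.weight_kg:.1f} kg, "
          f"blood volume {v_total:.0f} mL, hemorrhaged {hem:.0f} mL "
          f"(PEBL {hem / v_total:.2f})")
    print("  phases: " + ", ".join(
        f"{k}={v:.0f}s" for k, v in rec.phase_boundaries.items()))

# write CSV pairs + manifest for downstream tools
path = write_cohort(recordings, "scratch/example_cohort")
print(f"cohort written; manifest at {path}")
# Each subject hemorrhages to 40% of its estimated blood volume; phase
# boundaries mark where the fluid channels start and stop changing.
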