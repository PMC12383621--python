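"""Ground-truth construction: 100 Hz harmonization, PEBL and fluid balance.

The two acquisition streams (500 Hz PPG, 0.2 Hz cumulative fluid volumes)
are resampled onto a common 100 Hz grid.  The regression targets are

* PEBL(t) = V_hem(t) / V_total — percent estimated blood loss, a fraction
  in [0, 1], where V_total = 60 mL/kg x body weight;
* FB(t) = (V_hem(t) - V_wb(t) - V_cr(t)/3) / V_total — net fluid balance,
  counting whole blood 1:1 and crystalloid by the 3:1 replacement rule.
  Positive values are net blood loss; the sign swaps to negative when
  infusion overtakes the maximum loss (net fluid gain).

For model training the timeline is truncated to the final 10 baseline
minutes, the hemorrhage event and the hypovolemic hold; the resuscitation
phase is reserved for the extended fluid-balance evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import json
import numpy as np
import pandas as pd
from scipy import signal

from .synthetic import BLOOD_VOLUME_ML_PER_KG, SubjectRecording

TARGET_RATE_HZ = 100.0
CRYSTALLOID_DIVISOR = 3.0
BASELINE_KEEP_S = 600.0

__all__ = [
    "AlignedRecording",
    "GroundTruthSeries",
    "resample_recording",
    "total_blood_volume",
    "compute_pebl",
    "compute_fluid_balance",
    "build_ground_truth",
    "truncate_for_training",
    "read_recording",
    "write_aligned",
]


@dataclass
class AlignedRecording:
    """PPG and cumulative volumes harmonized to a common 100 Hz grid."""

    subject_id: str
    time_s: np.ndarray
    ppg: np.ndarray
    v_hem: np.ndarray
    v_wb: np.ndarray
    v_cr: np.ndarray
    weight_kg: float
    phase_boundaries: dict[str, float]
    fs: float = TARGET_RATE_HZ

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("ppg", "v_hem", "v_wb", "v_cr"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match the time grid")


@dataclass
class GroundTruthSeries:
    """Regression targets on the aligned grid."""

    pebl: np.ndarray
    fluid_balance: np.ndarray
    total_blood_volume_mL: float
    crystalloid_divisor: float = CRYSTALLOID_DIVISOR
    blood_volume_constant: float = BLOOD_VOLUME_ML_PER_KG


def total_blood_volume(weight_kg: float) -> float:
    """Estimated total blood volume, 60 mL per kilogram of body weight."""
    if weight_kg <= 0:
        raise ValueError("weight_kg must be positive")
    return BLOOD_VOLUME_ML_PER_KG * weight_kg


def compute_pebl(v_hem: np.ndarray, v_total: float) -> np.ndarray:
    """PEBL(t) = hemorrhaged volume / estimated total blood volume."""
    v_hem = np.asarray(v_hem, dtype=float)
    if v_total <= 0:
        raise ValueError("total blood volume must be positive")
    if v_hem.size and v_hem.min() < -1e-9:
        raise ValueError("hemorrhage volume must be non-negative")
    if v_hem.size and v_hem.max() > v_total * (1 + 1e-9):
        raise ValueError("hemorrhaged volume exceeds total blood volume")
    return v_hem / v_total


def compute_fluid_balance(
    v_hem: np.ndarray,
    v_wb: np.ndarray,
    v_cr: np.ndarray,
    v_total: float,
    crystalloid_divisor: float = CRYSTALLOID_DIVISOR,
) -> np.ndarray:
    """FB(t) = (V_hem - V_wb - V_cr / 3) / V_total.

    Whole blood counts 1:1 against blood loss; crystalloid is divided by
    three because only about a third of it stays intravascular.  Positive
    values mean net blood loss, negative net fluid gain.
    """
    if v_total <= 0:
        raise ValueError("total blood volume must be positive")
    v_hem = np.asarray(v_hem, dtype=float)
    v_wb = np.asarray(v_wb, dtype=float)
    v_cr = np.asarray(v_cr, dtype=float)
    for name, v in (("v_hem", v_hem), ("v_wb", v_wb), ("v_cr", v_cr)):
        if v.size and v.min() < -1e-9:
            raise ValueError(f"{name} must be non-negative")
    return (v_hem - v_wb - v_cr / crystalloid_divisor) / v_total


def resample_recording(raw: SubjectRecording) -> AlignedRecording:
    """Harmonize the two-rate recording onto a uniform 100 Hz grid.

    The 500 Hz PPG is decimated 5:1 behind an anti-alias FIR low-pass
    (cutoff below the 50 Hz Nyquist of the target rate); the 0.2 Hz
    cumulative volume channels are interpolated linearly, which preserves
    their monotonicity between log points.
    """
    if len(raw.ppg) == 0 or len(raw.fluid_log) == 0:
        raise ValueError("empty PPG or fluid stream")
    raw.validate()
    q = int(round(raw.fs_ppg / TARGET_RATE_HZ))
    # polyphase FIR anti-alias decimation; linear edge padding avoids
    # boundary transients on trended signals
    ppg100 = signal.resample_poly(raw.ppg, up=1, down=q, padtype="line")
    time_s = np.arange(len(ppg100)) / TARGET_RATE_HZ

    ft = raw.fluid_log["time_s"].to_numpy()
    channels = {}
    for col in ("hemorrhage_mL", "wholeblood_mL", "crystalloid_mL"):
        v = raw.fluid_log[col].to_numpy()
        out = np.interp(time_s, ft, v)
        # linear interpolation of a monotone sequence is monotone; guard
        # against floating-point jitter all the same
        channels[col] = np.maximum.accumulate(out)
    return AlignedRecording(
        subject_id=raw.subject_id,
        time_s=time_s,
        ppg=ppg100,
        v_hem=channels["hemorrhage_mL"],
        v_wb=channels["wholeblood_mL"],
        v_cr=channels["crystalloid_mL"],
        weight_kg=raw.weight_kg,
        phase_boundaries=dict(raw.phase_boundaries),
    )


def build_ground_truth(aligned: AlignedRecording) -> GroundTruthSeries:
    """Compute PEBL and fluid-balance target series for an aligned recording."""
    v_total = total_blood_volume(aligned.weight_kg)
    pebl = compute_pebl(aligned.v_hem, v_total)
    fb = compute_fluid_balance(aligned.v_hem, aligned.v_wb, aligned.v_cr, v_total)
    return GroundTruthSeries(
        pebl=pebl, fluid_balance=fb, total_blood_volume_mL=v_total
    )


def truncate_for_training(
    aligned: AlignedRecording, gt: GroundTruthSeries
) -> tuple[AlignedRecording, GroundTruthSeries]:
    """Keep the final 10 baseline minutes, hemorrhage and hypovolemic hold.

    Resuscitation samples are removed; the pairing between PPG samples and
    targets is preserved.  Shorter baselines are kept whole.
    """
    pb = aligned.phase_boundaries
    required = {"hemorrhage_start", "resuscitation_start"}
    if not pb or not required.issubset(pb):
        raise ValueError("phase boundaries are missing")
    start = max(0.0, pb["hemorrhage_start"] - BASELINE_KEEP_S)
    end = pb["resuscitation_start"]
    mask = (aligned.time_s >= start - 1e-9) & (aligned.time_s < end - 1e-9)
    new_aligned = replace(
        aligned,
        time_s=aligned.time_s[mask],
        ppg=aligned.ppg[mask],
        v_hem=aligned.v_hem[mask],
        v_wb=aligned.v_wb[mask],
        v_cr=aligned.v_cr[mask],
    )
    new_gt = GroundTruthSeries(
        pebl=gt.pebl[mask],
        fluid_balance=gt.fluid_balance[mask],
        total_blood_volume_mL=gt.total_blood_volume_mL,
    )
    return new_aligned, new_gt


# ---------------------------------------------------------------------------
# CSV round trip


def read_recording(cohort_dir: str | Path, subject_id: str) -> SubjectRecording:
    """Read the ``<id>_ppg.csv`` / ``<id>_fluids.csv`` pair written by the generator."""
    d = Path(cohort_dir)
    ppg_df = pd.read_csv(d / f"{subject_id}_ppg.csv")
    fluids = pd.read_csv(d / f"{subject_id}_fluids.csv")
    manifest = json.loads((d / "cohort_manifest.json").read_text())
    entry = next(m for m in manifest if m["subject_id"] == subject_id)
    return SubjectRecording(
        subject_id=subject_id,
        ppg=ppg_df["ppg"].to_numpy(),
        fluid_log=fluids,
        weight_kg=entry["weight_kg"],
        phase_boundaries=entry["phase_boundaries"],
    )


def write_aligned(
    aligned: AlignedRecording, gt: GroundTruthSeries, out_dir: str | Path
) -> Path:
    """Write ``<id>_aligned.csv`` with signals, volumes and both targets."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"{aligned.subject_id}_aligned.csv"
    pd.DataFrame(
        {
            "time_s": aligned.time_s,
            "ppg": aligned.ppg,
            "V_hem": aligned.v_hem,
            "V_wb": aligned.v_wb,
            "V_cr": aligned.v_cr,
            "pebl": gt.pebl,
            "fluid_balance": gt.fluid_balance,
        }
    ).to_csv(path, index=False)
    return path
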