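"""Synthetic hemorrhage/resuscitation cohort generator.

Emulates the acquisition protocol of a controlled-hemorrhage large-animal
study: an anesthetized ~40 kg subject is recorded through a baseline period,
a constant-rate controlled hemorrhage toward a hypovolemic target, a
hypovolemic hold, and a staged resuscitation (whole blood first, then
crystalloid).  Two data streams are produced per subject:

* a photoplethysmography (PPG) waveform sampled at 500 Hz, and
* a cumulative fluid log (hemorrhage, whole-blood and crystalloid volumes,
  mL) sampled at 0.2 Hz,

together with the subject weight.  The pulse waveform is a two-lobe
(systolic + dicrotic) Gaussian template whose beat-to-beat morphology is
coupled monotonically to the instantaneous percent estimated blood loss
(PEBL): pulse amplitude decays exponentially with PEBL, heart rate grows
linearly with PEBL, and the dicrotic wave attenuates exponentially.  This
coupling is the recoverability premise of the downstream regression
pipeline — it is a designed signal carrier, not a physiological model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PPG_SAMPLE_RATE_HZ = 500.0
FLUID_SAMPLE_RATE_HZ = 0.2
BLOOD_VOLUME_ML_PER_KG = 60.0

__all__ = [
    "PulseTemplate",
    "CouplingParams",
    "NoiseParams",
    "SubjectParams",
    "ProtocolSpec",
    "SubjectRecording",
    "InvalidParameterError",
    "InvalidProtocolError",
    "pulse_waveform",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
    "default_subject_params",
    "default_protocol",
]


class InvalidParameterError(ValueError):
    """Raised for out-of-range subject or template parameters."""


class InvalidProtocolError(ValueError):
    """Raised for protocols that violate the phase or volume constraints."""


@dataclass(frozen=True)
class PulseTemplate:
    """Two-Gaussian pulse shape, parameterized in fractions of the cycle.

    The systolic lobe is a Gaussian centred at ``systolic_center`` (fraction
    of the beat period) and the dicrotic lobe a smaller Gaussian delayed by
    ``dicrotic_delay``.  Default values give a waveform that is ~0 at the
    cycle start and exposes all fiducials (foot, systolic peak, dicrotic
    notch, diastolic peak) the feature extractor needs.
    """

    systolic_amplitude: float = 1.0
    systolic_center: float = 0.22
    systolic_width: float = 0.07
    dicrotic_fraction: float = 0.35
    dicrotic_delay: float = 0.25
    dicrotic_width: float = 0.09


@dataclass(frozen=True)
class CouplingParams:
    """PEBL-sensitivity of the pulse morphology.

    amplitude = base * exp(-amplitude_decay * PEBL)
    heart rate = baseline * (1 + heart_rate_gain * PEBL)
    dicrotic fraction = base * exp(-dicrotic_attenuation * PEBL)
    """

    amplitude_decay: float = 2.5
    heart_rate_gain: float = 0.8
    dicrotic_attenuation: float = 3.0


@dataclass(frozen=True)
class NoiseParams:
    """Additive Gaussian noise plus a low-frequency baseline-wander sinusoid."""

    std: float = 0.02
    wander_amplitude: float = 0.10
    wander_freq_hz: float = 0.2


@dataclass(frozen=True)
class SubjectParams:
    subject_id: str = "s00"
    weight_kg: float = 40.0
    baseline_heart_rate: float = 90.0  # beats/min
    pulse_template: PulseTemplate = field(default_factory=PulseTemplate)
    coupling: CouplingParams = field(default_factory=CouplingParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def validate(self) -> None:
        if self.weight_kg <= 0:
            raise InvalidParameterError("weight_kg must be positive")
        if not 40.0 <= self.baseline_heart_rate <= 240.0:
            raise InvalidParameterError(
                "baseline_heart_rate must lie in [40, 240] beats/min"
            )
        if self.noise.std < 0:
            raise InvalidParameterError("noise std must be non-negative")


@dataclass(frozen=True)
class ProtocolSpec:
    """Phase timing and fluid-delivery rates of the study protocol.

    Phases are contiguous and ordered baseline -> hemorrhage -> hold ->
    resuscitation.  Hemorrhage proceeds at ``hemorrhage_rate_ml_min`` until
    the target PEBL is reached or ``max_hemorrhage_duration_s`` elapses.
    Resuscitation delivers whole blood first (up to ``wholeblood_volume_ml``),
    then crystalloid for the remainder of ``resuscitation_duration_s``.
    """

    baseline_duration_s: float = 600.0
    hemorrhage_rate_ml_min: float = 60.0
    hemorrhage_target_pebl: float = 0.40
    max_hemorrhage_duration_s: float = 5400.0
    hold_duration_s: float = 600.0
    wholeblood_volume_ml: float = 600.0
    wholeblood_rate_ml_min: float = 100.0
    crystalloid_rate_ml_min: float = 100.0
    resuscitation_duration_s: float = 1200.0

    def validate(self) -> None:
        durations = (
            self.baseline_duration_s,
            self.max_hemorrhage_duration_s,
            self.hold_duration_s,
            self.resuscitation_duration_s,
        )
        if any(d < 0 for d in durations):
            raise InvalidProtocolError("all durations must be non-negative")
        if not 0.0 < self.hemorrhage_target_pebl < 1.0:
            raise InvalidProtocolError(
                "hemorrhage_target_pebl must lie in (0, 1): the target may "
                "not exceed the total blood volume"
            )
        if self.hemorrhage_rate_ml_min <= 0:
            raise InvalidProtocolError("hemorrhage_rate_ml_min must be positive")


@dataclass
class SubjectRecording:
    """Raw two-rate record for one subject — the unit of LOSO evaluation."""

    subject_id: str
    ppg: np.ndarray  # 500 Hz, arbitrary units
    fluid_log: pd.DataFrame  # 0.2 Hz: time_s + three cumulative mL channels
    weight_kg: float
    phase_boundaries: dict[str, float]
    fs_ppg: float = PPG_SAMPLE_RATE_HZ
    fs_fluid: float = FLUID_SAMPLE_RATE_HZ
    # generator metadata, usable as test oracles
    beat_onsets_s: np.ndarray | None = None
    beat_amplitudes: np.ndarray | None = None
    beat_periods_s: np.ndarray | None = None
    beat_pebl: np.ndarray | None = None

    @property
    def duration_s(self) -> float:
        return len(self.ppg) / self.fs_ppg

    def validate(self) -> None:
        if not np.all(np.isfinite(self.ppg)):
            raise ValueError("ppg contains non-finite values")
        t = self.fluid_log["time_s"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise ValueError("fluid_log timestamps must be strictly increasing")
        for col in ("hemorrhage_mL", "wholeblood_mL", "crystalloid_mL"):
            v = self.fluid_log[col].to_numpy()
            if v.min() < 0 or np.any(np.diff(v) < 0):
                raise ValueError(f"cumulative channel {col} must be non-decreasing")


def pulse_waveform(
    t_in_cycle: np.ndarray | float,
    template: PulseTemplate,
    period_s: float = 1.0,
) -> np.ndarray:
    """Evaluate the two-lobe pulse template at times within one beat.

    Parameters
    ----------
    t_in_cycle
        Time(s) since the beat onset, in seconds, each in ``[0, period_s)``.
    template
        Morphology parameters (lobe centers/widths as cycle fractions).
    period_s
        Beat period; must be positive.

    Returns
    -------
    Waveform amplitude(s); ~0 at the cycle start by construction.
    """
    if period_s <= 0:
        raise InvalidParameterError("cycle length must be positive")
    frac = np.asarray(t_in_cycle, dtype=float) / period_s
    tpl = template
    sys_lobe = np.exp(-0.5 * ((frac - tpl.systolic_center) / tpl.systolic_width) ** 2)
    dic_center = tpl.systolic_center + tpl.dicrotic_delay
    dic_lobe = tpl.dicrotic_fraction * np.exp(
        -0.5 * ((frac - dic_center) / tpl.dicrotic_width) ** 2
    )
    return tpl.systolic_amplitude * (sys_lobe + dic_lobe)


# ---------------------------------------------------------------------------
# fluid trajectory


def _phase_times(protocol: ProtocolSpec, weight_kg: float) -> dict[str, float]:
    v_total = BLOOD_VOLUME_ML_PER_KG * weight_kg
    target_ml = protocol.hemorrhage_target_pebl * v_total
    hem_dur = min(
        target_ml / protocol.hemorrhage_rate_ml_min * 60.0,
        protocol.max_hemorrhage_duration_s,
    )
    b = protocol.baseline_duration_s
    return {
        "baseline_start": 0.0,
        "hemorrhage_start": b,
        "hold_start": b + hem_dur,
        "resuscitation_start": b + hem_dur + protocol.hold_duration_s,
        "end": b + hem_dur + protocol.hold_duration_s + protocol.resuscitation_duration_s,
    }


def _cumulative_volumes(
    t: np.ndarray, protocol: ProtocolSpec, bounds: dict[str, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-linear cumulative hemorrhage / whole-blood / crystalloid (mL)."""
    t = np.asarray(t, dtype=float)
    hem_start = bounds["hemorrhage_start"]
    hold_start = bounds["hold_start"]
    res_start = bounds["resuscitation_start"]
    end = bounds["end"]

    hem_rate = protocol.hemorrhage_rate_ml_min / 60.0  # mL/s
    v_hem = np.clip(t - hem_start, 0.0, hold_start - hem_start) * hem_rate

    wb_rate = protocol.wholeblood_rate_ml_min / 60.0
    res_dur = end - res_start
    wb_dur = min(
        protocol.wholeblood_volume_ml / wb_rate if wb_rate > 0 else 0.0, res_dur
    )
    v_wb = np.clip(t - res_start, 0.0, wb_dur) * wb_rate

    cr_rate = protocol.crystalloid_rate_ml_min / 60.0
    cr_start = res_start + wb_dur
    v_cr = np.clip(t - cr_start, 0.0, end - cr_start) * cr_rate
    return v_hem, v_wb, v_cr


# ---------------------------------------------------------------------------
# subject simulation


def simulate_subject(
    params: SubjectParams,
    protocol: ProtocolSpec | None = None,
    seed: int | None = None,
) -> SubjectRecording:
    """Simulate one subject's 500 Hz PPG and 0.2 Hz cumulative fluid log.

    Beats are laid down sequentially; at each beat onset the instantaneous
    PEBL determines the beat's period, amplitude and dicrotic fraction via
    the coupling model.  Additive noise and baseline wander are applied last.
    Identical ``(params, protocol, seed)`` reproduce identical output.
    """
    protocol = protocol if protocol is not None else ProtocolSpec()
    params.validate()
    protocol.validate()
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    bounds = _phase_times(protocol, params.weight_kg)
    total_dur = bounds["end"]
    v_total = BLOOD_VOLUME_ML_PER_KG * params.weight_kg
    hem_rate = protocol.hemorrhage_rate_ml_min / 60.0
    hem_start, hold_start = bounds["hemorrhage_start"], bounds["hold_start"]

    def pebl_at(t: float) -> float:
        return np.clip(t - hem_start, 0.0, hold_start - hem_start) * hem_rate / v_total

    n_samples = int(round(total_dur * PPG_SAMPLE_RATE_HZ))
    ppg = np.zeros(n_samples)
    ts = np.arange(n_samples) / PPG_SAMPLE_RATE_HZ

    tpl = params.pulse_template
    cpl = params.coupling
    onsets, amplitudes, periods, pebls = [], [], [], []
    t_beat = 0.0
    while t_beat < total_dur:
        pebl = pebl_at(t_beat)
        hr = params.baseline_heart_rate * (1.0 + cpl.heart_rate_gain * pebl)
        period = 60.0 / hr
        amp = tpl.systolic_amplitude * np.exp(-cpl.amplitude_decay * pebl)
        dic = tpl.dicrotic_fraction * np.exp(-cpl.dicrotic_attenuation * pebl)
        beat_tpl = dataclasses.replace(
            tpl, systolic_amplitude=amp, dicrotic_fraction=dic
        )
        i0 = int(np.ceil(t_beat * PPG_SAMPLE_RATE_HZ))
        i1 = min(int(np.ceil((t_beat + period) * PPG_SAMPLE_RATE_HZ)), n_samples)
        if i1 > i0:
            ppg[i0:i1] = pulse_waveform(ts[i0:i1] - t_beat, beat_tpl, period)
        onsets.append(t_beat)
        amplitudes.append(amp)
        periods.append(period)
        pebls.append(pebl)
        t_beat += period

    noise = params.noise
    if noise.std > 0:
        ppg = ppg + rng.normal(0.0, noise.std, n_samples)
    if noise.wander_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        ppg = ppg + noise.wander_amplitude * np.sin(
            2.0 * np.pi * noise.wander_freq_hz * ts + phase
        )

    fluid_t = np.arange(0.0, total_dur + 1e-9, 1.0 / FLUID_SAMPLE_RATE_HZ)
    v_hem, v_wb, v_cr = _cumulative_volumes(fluid_t, protocol, bounds)
    fluid_log = pd.DataFrame(
        {
            "time_s": fluid_t,
            "hemorrhage_mL": v_hem,
            "wholeblood_mL": v_wb,
            "crystalloid_mL": v_cr,
        }
    )

    rec = SubjectRecording(
        subject_id=params.subject_id,
        ppg=ppg,
        fluid_log=fluid_log,
        weight_kg=params.weight_kg,
        phase_boundaries=bounds,
        beat_onsets_s=np.asarray(onsets),
        beat_amplitudes=np.asarray(amplitudes),
        beat_periods_s=np.asarray(periods),
        beat_pebl=np.asarray(pebls),
    )
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class CohortJitter:
    """Relative half-widths of the uniform inter-subject parameter jitter."""

    weight_frac: float = 0.10
    heart_rate_frac: float = 0.10
    amplitude_frac: float = 0.20
    coupling_frac: float = 0.15


def simulate_cohort(
    n_subjects: int,
    base_params: SubjectParams | None = None,
    protocol: ProtocolSpec | None = None,
    seed: int = 0,
    jitter: CohortJitter | None = None,
) -> list[SubjectRecording]:
    """Simulate a cohort of subjects jittered around ``base_params``.

    Each subject's weight, baseline heart rate, pulse amplitude and coupling
    coefficients are drawn uniformly within the relative bounds of
    ``jitter``; each subject receives its own child seed so cohorts are
    reproducible as a whole.
    """
    if n_subjects < 2:
        raise InvalidParameterError(
            "n_subjects must be >= 2 (leave-one-subject-out is undefined otherwise)"
        )
    base = base_params if base_params is not None else default_subject_params()
    protocol = protocol if protocol is not None else ProtocolSpec()
    jit = jitter if jitter is not None else CohortJitter()
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)

    def u(frac: float) -> float:
        return 1.0 + rng.uniform(-frac, frac)

    recordings = []
    for i in range(n_subjects):
        weight = base.weight_kg * u(jit.weight_frac)
        hr = base.baseline_heart_rate * u(jit.heart_rate_frac)
        tpl = dataclasses.replace(
            base.pulse_template,
            systolic_amplitude=base.pulse_template.systolic_amplitude
            * u(jit.amplitude_frac),
        )
        cpl = dataclasses.replace(
            base.coupling,
            amplitude_decay=base.coupling.amplitude_decay * u(jit.coupling_frac),
            heart_rate_gain=base.coupling.heart_rate_gain * u(jit.coupling_frac),
            dicrotic_attenuation=base.coupling.dicrotic_attenuation
            * u(jit.coupling_frac),
        )
        params = dataclasses.replace(
            base,
            subject_id=f"{base.subject_id}_{i:02d}" if n_subjects > 1 else base.subject_id,
            weight_kg=weight,
            baseline_heart_rate=hr,
            pulse_template=tpl,
            coupling=cpl,
            seed=int(child_seeds[i]),
        )
        recordings.append(simulate_subject(params, protocol))
    return recordings


def default_subject_params(subject_id: str = "s00", seed: int = 0) -> SubjectParams:
    return SubjectParams(subject_id=subject_id, seed=seed)


def default_protocol() -> ProtocolSpec:
    return ProtocolSpec()


# ---------------------------------------------------------------------------
# writers


def write_cohort(recordings: list[SubjectRecording], out_dir: str | Path) -> Path:
    """Write per-subject CSV pairs and a cohort manifest JSON.

    ``<id>_ppg.csv`` holds (time_s, ppg) at 500 Hz; ``<id>_fluids.csv`` holds
    (time_s, hemorrhage_mL, wholeblood_mL, crystalloid_mL) at 0.2 Hz.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rec in recordings:
        t = np.arange(len(rec.ppg)) / rec.fs_ppg
        pd.DataFrame({"time_s": t, "ppg": rec.ppg}).to_csv(
            out / f"{rec.subject_id}_ppg.csv", index=False
        )
        rec.fluid_log.to_csv(out / f"{rec.subject_id}_fluids.csv", index=False)
        manifest.append(
            {
                "subject_id": rec.subject_id,
                "weight_kg": rec.weight_kg,
                "phase_boundaries": rec.phase_boundaries,
            }
        )
    manifest_path = out / "cohort_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
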