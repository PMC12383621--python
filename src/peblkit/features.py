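"""Windowed PPG feature extraction.

The 100 Hz PPG is cut into fixed-length, non-overlapping sampling windows
(5, 10, 30 or 60 s).  Within each window, pulses are detected from the
first derivative, fiducial points (foot/onset, systolic peak, dicrotic
notch, diastolic peak) are located per pulse, and per-pulse morphology,
width and derivative features are averaged across the valid pulses of the
window.  Frequency and statistical features are computed once per window.
The result is the fixed 58-feature vector declared in
:mod:`peblkit.manifest`, paired with the window's mean ground-truth target.

Per-subject 0-1 normalization rescales each feature within each subject
(including a blind test subject within itself); this mirrors the study
procedure and its known information-leakage caveat is documented rather
than altered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .ground_truth import AlignedRecording, GroundTruthSeries
from .manifest import FEATURE_NAMES, MANIFEST_VERSION

logger = logging.getLogger(__name__)

WINDOW_LENGTHS_S = (5, 10, 30, 60)
WIDTH_LEVELS = (10, 25, 33, 50, 66, 75)
#: plausible beat-rate band, beats/min
MIN_RATE_BPM, MAX_RATE_BPM = 40.0, 240.0

__all__ = [
    "Window",
    "Pulse",
    "FeatureMatrix",
    "segment_windows",
    "detect_pulses",
    "pulse_features",
    "window_features",
    "extract_features",
    "cohort_feature_matrix",
    "normalize_per_subject",
]


@dataclass
class Window:
    subject_id: str
    start_s: float
    end_s: float
    window_length_s: float
    samples: np.ndarray
    fs: float
    target: float


@dataclass
class Pulse:
    onset_idx: int
    systolic_peak_idx: int
    dicrotic_notch_idx: int
    diastolic_peak_idx: int
    end_idx: int
    valid: bool = True


@dataclass
class FeatureMatrix:
    """Windows x features table with metadata columns.

    ``df`` carries ``subject_id``, ``start_s``, ``target`` plus the 58
    manifest features; ``normalization`` is "none" or "per_subject".
    """

    df: pd.DataFrame
    window_length_s: float
    normalization: str = "none"
    manifest_version: str = MANIFEST_VERSION

    @property
    def feature_names(self) -> tuple[str, ...]:
        return FEATURE_NAMES

    def X(self) -> np.ndarray:
        return self.df[list(FEATURE_NAMES)].to_numpy()

    def y(self) -> np.ndarray:
        return self.df["target"].to_numpy()

    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.df["subject_id"]))


# ---------------------------------------------------------------------------
# windowing


def segment_windows(
    aligned: AlignedRecording,
    gt: GroundTruthSeries,
    window_length_s: float,
    target: str = "pebl",
) -> list[Window]:
    """Cut a recording into contiguous, non-overlapping sampling windows.

    The trailing partial window is discarded.  Each window's target is the
    mean of the chosen ground-truth series (``"pebl"`` or
    ``"fluid_balance"``) over the window's span.
    """
    if window_length_s not in WINDOW_LENGTHS_S:
        raise ValueError(f"window_length_s must be one of {WINDOW_LENGTHS_S}")
    series = getattr(gt, target)
    n_per = int(round(window_length_s * aligned.fs))
    n_windows = len(aligned.ppg) // n_per
    if n_windows == 0:
        warnings.warn(
            f"recording {aligned.subject_id} shorter than one "
            f"{window_length_s}s window; no windows produced",
            stacklevel=2,
        )
        return []
    out = []
    t0 = aligned.time_s[0]
    for k in range(n_windows):
        i0, i1 = k * n_per, (k + 1) * n_per
        out.append(
            Window(
                subject_id=aligned.subject_id,
                start_s=t0 + i0 / aligned.fs,
                end_s=t0 + i1 / aligned.fs,
                window_length_s=window_length_s,
                samples=aligned.ppg[i0:i1],
                fs=aligned.fs,
                target=float(np.mean(series[i0:i1])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# pulse detection


def detect_pulses(window: Window) -> list[Pulse]:
    """Locate pulse onsets and fiducial points within a window.

    Onsets are waveform feet: the local minimum preceding each steep
    upstroke, where upstrokes are prominent peaks of the first derivative.
    Beats with implausible rate (outside [40, 240] bpm) or amplitude below
    the window's noise floor are flagged invalid.  The dicrotic notch is
    the most prominent local minimum after the systolic peak, falling back
    to the second-derivative maximum (the e-wave region) for weak-notch
    pulses; the diastolic peak is the first local maximum after the notch.
    """
    x = np.asarray(window.samples, dtype=float)
    fs = window.fs
    if len(x) < int(0.25 * fs) or np.ptp(x) < 1e-12:
        return []
    d1 = np.gradient(x) * fs
    d1_pos = np.clip(d1, 0.0, None)
    thresh = 0.4 * np.percentile(d1_pos, 98)
    if thresh <= 0:
        return []
    min_spacing = int(fs * 60.0 / MAX_RATE_BPM)
    upstrokes, _ = sps.find_peaks(d1, height=thresh, distance=max(min_spacing, 1))
    if len(upstrokes) < 2:
        return []

    onsets = []
    back = int(0.35 * fs)
    for u in upstrokes:
        lo = max(0, u - back)
        onsets.append(lo + int(np.argmin(x[lo : u + 1])))
    onsets = sorted(set(onsets))
    if len(onsets) < 2:
        return []

    d2 = _second_derivative(x, fs)
    amps = [
        x[o : onsets[i + 1] + 1].max() - x[o] for i, o in enumerate(onsets[:-1])
    ]
    amp_floor = max(0.25 * float(np.median(amps)), 1e-9) if amps else 1e-9

    pulses = []
    for i in range(len(onsets) - 1):
        o, e = onsets[i], onsets[i + 1]
        seg = x[o : e + 1]
        peak = o + int(np.argmax(seg))
        period_s = (e - o) / fs
        rate = 60.0 / period_s if period_s > 0 else np.inf
        amp = x[peak] - x[o]
        valid = (
            MIN_RATE_BPM <= rate <= MAX_RATE_BPM
            and amp >= amp_floor
            and o < peak < e
        )
        notch, dia = _locate_notch(x, d2, peak, e)
        pulses.append(
            Pulse(
                onset_idx=o,
                systolic_peak_idx=peak,
                dicrotic_notch_idx=notch,
                diastolic_peak_idx=dia,
                end_idx=e,
                valid=bool(valid),
            )
        )
    return pulses


def _second_derivative(x: np.ndarray, fs: float) -> np.ndarray:
    win = min(7, len(x) if len(x) % 2 == 1 else len(x) - 1)
    if win < 5:
        return np.gradient(np.gradient(x)) * fs * fs
    return sps.savgol_filter(x, win, 3, deriv=2, delta=1.0 / fs)


def _locate_notch(
    x: np.ndarray, d2: np.ndarray, peak: int, end: int
) -> tuple[int, int]:
    """Dicrotic notch and diastolic peak between the systolic peak and the end."""
    lo, hi = peak + 1, end
    if hi - lo < 4:
        return end, end
    seg = x[lo:hi]
    minima, props = sps.find_peaks(-seg, prominence=0.0)
    if len(minima):
        notch = lo + int(minima[np.argmax(props["prominences"])])
    else:
        # weak-notch fallback: the second-derivative maximum (e-wave region)
        notch = lo + int(np.argmax(d2[lo:hi]))
    dseg = x[notch + 1 : hi]
    maxima, _ = sps.find_peaks(dseg)
    if len(maxima):
        dia = notch + 1 + int(maxima[0])
    else:
        dia = notch
    return notch, dia


# ---------------------------------------------------------------------------
# per-pulse features


def _crossing_before(seg: np.ndarray, peak: int, level: float, dt: float) -> float:
    """Time of the last upward crossing of ``level`` before ``peak`` (linear interp)."""
    below = np.nonzero(seg[: peak + 1] < level)[0]
    if len(below) == 0:
        return 0.0
    i = below[-1]
    if i == peak:
        return peak * dt
    y0, y1 = seg[i], seg[i + 1]
    frac = 0.0 if y1 == y0 else (level - y0) / (y1 - y0)
    return (i + frac) * dt


def _crossing_after(seg: np.ndarray, peak: int, level: float, dt: float) -> float:
    """Time of the first downward crossing of ``level`` after ``peak``."""
    rel = np.nonzero(seg[peak:] < level)[0]
    if len(rel) == 0:
        return (len(seg) - 1) * dt
    i = peak + rel[0]
    if i == peak:
        return peak * dt
    y0, y1 = seg[i - 1], seg[i]
    frac = 0.0 if y1 == y0 else (y0 - level) / (y0 - y1)
    return (i - 1 + frac) * dt


def pulse_features(pulse: Pulse, samples: np.ndarray, fs: float) -> dict[str, float]:
    """Morphology, width and derivative features of one valid pulse.

    Amplitudes are referenced to the pulse foot (onset value); widths at a
    given percent of the systolic amplitude are obtained by linear
    interpolation between the samples bracketing each threshold crossing
    and split into systolic (before-peak) and diastolic (after-peak)
    portions.
    """
    if not pulse.valid:
        raise ValueError("features are defined only for valid pulses")
    x = np.asarray(samples, dtype=float)
    dt = 1.0 / fs
    o, p, e = pulse.onset_idx, pulse.systolic_peak_idx, pulse.end_idx
    seg = x[o : e + 1] - x[o]
    peak = p - o
    amp = seg[peak]
    notch = min(max(pulse.dicrotic_notch_idx - o, peak), len(seg) - 1)
    dia = min(max(pulse.diastolic_peak_idx - o, notch), len(seg) - 1)

    feats: dict[str, float] = {}
    # morphology
    feats["systolic_amplitude"] = amp
    feats["diastolic_amplitude"] = seg[dia]
    feats["notch_amplitude"] = seg[notch]
    feats["diastolic_systolic_ratio"] = seg[dia] / amp if amp else 0.0
    feats["notch_systolic_ratio"] = seg[notch] / amp if amp else 0.0
    feats["pulse_duration"] = (len(seg) - 1) * dt
    feats["rise_time"] = peak * dt
    feats["decay_time"] = (len(seg) - 1 - peak) * dt
    feats["pulse_area"] = float(np.trapezoid(seg, dx=dt))
    feats["systolic_area"] = float(np.trapezoid(seg[: notch + 1], dx=dt))
    feats["diastolic_area"] = float(np.trapezoid(seg[notch:], dx=dt))
    feats["area_ratio"] = (
        feats["diastolic_area"] / feats["systolic_area"]
        if feats["systolic_area"]
        else 0.0
    )
    # widths
    t_peak = peak * dt
    for lvl in WIDTH_LEVELS:
        level = amp * lvl / 100.0
        t_rise = _crossing_before(seg, peak, level, dt)
        t_fall = _crossing_after(seg, peak, level, dt)
        feats[f"sys_width_{lvl}"] = t_peak - t_rise
        feats[f"dia_width_{lvl}"] = t_fall - t_peak
    feats["width_50"] = feats["sys_width_50"] + feats["dia_width_50"]
    feats["width_75"] = feats["sys_width_75"] + feats["dia_width_75"]
    for lvl in (50, 75):
        sw = feats[f"sys_width_{lvl}"]
        feats[f"dia_sys_ratio_{lvl}"] = feats[f"dia_width_{lvl}"] / sw if sw else 0.0
    # derivatives
    d1 = np.gradient(seg, dt)
    feats["d1_max"] = float(d1.max())
    feats["d1_min"] = float(d1.min())
    feats["d1_max_time"] = float(np.argmax(d1)) * dt
    d2 = _second_derivative(seg, fs)
    a_idx = int(np.argmax(d2[: peak + 1]))
    a = d2[a_idx]
    b_idx = a_idx + int(np.argmin(d2[a_idx:]))
    b = d2[b_idx]
    c_idx, d_idx, e_idx = _cde_waves(d2, b_idx)
    feats["a_wave"] = float(a)
    feats["b_wave"] = float(b)
    feats["c_wave"] = float(d2[c_idx])
    feats["d_wave"] = float(d2[d_idx])
    feats["e_wave"] = float(d2[e_idx])
    for name in ("b", "c", "d", "e"):
        feats[f"{name}_a_ratio"] = feats[f"{name}_wave"] / a if a else 0.0
    return feats


def _cde_waves(d2: np.ndarray, b_idx: int) -> tuple[int, int, int]:
    """c (first max after b), d (first min after c), e (first max after d).

    Missing extrema fall back to fixed fractions of the post-b span so the
    features stay finite for weak-notch pulses.
    """
    n = len(d2)
    span = n - 1 - b_idx

    def fallback(frac: float) -> int:
        return min(b_idx + max(int(frac * span), 1), n - 1)

    after = d2[b_idx:]
    maxima, _ = sps.find_peaks(after)
    c_idx = b_idx + int(maxima[0]) if len(maxima) else fallback(0.25)
    minima, _ = sps.find_peaks(-d2[c_idx:])
    d_idx = c_idx + int(minima[0]) if len(minima) else fallback(0.5)
    maxima2, _ = sps.find_peaks(d2[d_idx:])
    e_idx = d_idx + int(maxima2[0]) if len(maxima2) else fallback(0.75)
    return c_idx, d_idx, e_idx


# ---------------------------------------------------------------------------
# per-window features


def window_features(window: Window, pulses: list[Pulse]) -> dict[str, float] | None:
    """Assemble the full 58-feature vector for one window.

    Per-pulse features are averaged across the window's valid pulses;
    frequency features come from the mean-removed window spectrum and
    statistical features from the raw window.  Returns ``None`` when the
    window has no valid pulse (the window is excluded upstream).
    """
    valid = [p for p in pulses if p.valid]
    if not valid:
        return None
    per_pulse = [pulse_features(p, window.samples, window.fs) for p in valid]
    feats = {k: float(np.mean([pf[k] for pf in per_pulse])) for k in per_pulse[0]}
    feats.update(_frequency_features(window.samples, window.fs))
    feats.update(_statistical_features(window.samples))
    return {name: feats[name] for name in FEATURE_NAMES}


def _frequency_features(x: np.ndarray, fs: float) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    mag = np.abs(np.fft.rfft(xc))
    freqs = np.fft.rfftfreq(len(xc), d=1.0 / fs)
    band = (freqs >= 0.5) & (freqs <= 4.0)
    if not band.any() or mag[band].max() == 0:
        f0, m0 = 0.0, 0.0
    else:
        idx = np.nonzero(band)[0][np.argmax(mag[band])]
        f0, m0 = float(freqs[idx]), float(mag[idx])

    def mag_at(f: float) -> float:
        if f <= 0 or f > freqs[-1]:
            return 0.0
        return float(mag[int(np.argmin(np.abs(freqs - f)))])

    m2, m3 = mag_at(2 * f0), mag_at(3 * f0)
    nz = mag[1:]
    total = nz.sum()
    if total > 0:
        centroid = float((freqs[1:] * nz).sum() / total)
        bandwidth = float(np.sqrt(((freqs[1:] - centroid) ** 2 * nz).sum() / total))
        p = nz**2 / (nz**2).sum()
        p = p[p > 0]
        entropy = float(-(p * np.log(p)).sum() / np.log(len(nz)))
    else:
        centroid = bandwidth = entropy = 0.0
    return {
        "fundamental_freq": f0,
        "fundamental_mag": m0,
        "harmonic2_mag": m2,
        "harmonic3_mag": m3,
        "harmonic2_ratio": m2 / m0 if m0 else 0.0,
        "harmonic3_ratio": m3 / m0 if m0 else 0.0,
        "spectral_centroid": centroid,
        "spectral_bandwidth": bandwidth,
        "spectral_entropy": entropy,
    }


def _statistical_features(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    detrended = sps.detrend(x)
    zc = int(np.count_nonzero(np.diff(np.signbit(detrended))))
    return {
        "stat_mean": float(x.mean()),
        "stat_std": float(x.std()),
        "stat_skewness": float(spstats.skew(x)),
        "stat_kurtosis": float(spstats.kurtosis(x)),
        "stat_min": float(x.min()),
        "stat_max": float(x.max()),
        "stat_iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "stat_rms": float(np.sqrt(np.mean(x**2))),
        "zero_crossings": float(zc),
    }


# ---------------------------------------------------------------------------
# matrix assembly and normalization


def extract_features(windows: list[Window]) -> FeatureMatrix:
    """Run pulse detection + feature extraction over a window list."""
    rows = []
    n_excluded = 0
    wl = windows[0].window_length_s if windows else float("nan")
    for w in windows:
        feats = window_features(w, detect_pulses(w))
        if feats is None:
            n_excluded += 1
            continue
        row = {"subject_id": w.subject_id, "start_s": w.start_s, "target": w.target}
        row.update(feats)
        rows.append(row)
    if n_excluded:
        logger.info("excluded %d windows with no valid pulses", n_excluded)
    df = pd.DataFrame(rows, columns=["subject_id", "start_s", "target", *FEATURE_NAMES])
    return FeatureMatrix(df=df, window_length_s=wl)


def cohort_feature_matrix(
    pairs: list[tuple[AlignedRecording, GroundTruthSeries]],
    window_length_s: float,
    target: str = "pebl",
) -> FeatureMatrix:
    """Extract one pooled feature matrix from a cohort of aligned recordings."""
    windows: list[Window] = []
    for aligned, gt in pairs:
        windows.extend(segment_windows(aligned, gt, window_length_s, target=target))
    return extract_features(windows)


def split_by_subjects(
    matrix: FeatureMatrix, subjects: set[str]
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Partition a matrix into (rows not in ``subjects``, rows in ``subjects``)."""
    in_mask = matrix.df["subject_id"].isin(subjects)
    return (
        replace(matrix, df=matrix.df[~in_mask].reset_index(drop=True)),
        replace(matrix, df=matrix.df[in_mask].reset_index(drop=True)),
    )


def normalize_per_subject(matrix: FeatureMatrix) -> FeatureMatrix:
    """Min-max rescale every feature to [0, 1] within each subject.

    Constant features map to 0.  Each subject — including a blind test
    subject — is scaled within itself.
    """
    if matrix.normalization != "none":
        raise ValueError("matrix is already normalized")
    df = matrix.df.copy()
    cols = list(FEATURE_NAMES)
    for _, idx in df.groupby("subject_id", sort=False).groups.items():
        block = df.loc[idx, cols]
        lo, hi = block.min(axis=0), block.max(axis=0)
        rng = (hi - lo).replace(0.0, np.inf)  # constant features -> 0
        df.loc[idx, cols] = (block - lo) / rng
    return replace(matrix, df=df, normalization="per_subject")
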