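"""The fixed 58-feature manifest for PPG pulse-wave windows.

Every feature the extractor emits is declared here with its category and
its scaling signature: ``amp_exp`` / ``time_exp`` give the exponents with
which the feature responds to an amplitude scaling (signal x c) or a time
stretch (t -> s*t) of the underlying pulse.  A ratio feature has (0, 0); a
raw amplitude (1, 0); a duration (0, 1); a second-derivative amplitude
(1, -2).  The manifest is frozen by test — any drift in names, order or
count is an API break.

Categories (58 total): morphology 12, width 16, derivative 12,
frequency 9, statistical 9.
"""

from __future__ import annotations

from dataclasses import dataclass

MANIFEST_VERSION = "1.0"

__all__ = ["FeatureDef", "FEATURE_MANIFEST", "FEATURE_NAMES", "MANIFEST_VERSION",
           "PER_PULSE_CATEGORIES", "PER_WINDOW_CATEGORIES", "category_counts"]


@dataclass(frozen=True)
class FeatureDef:
    name: str
    category: str  # morphology | width | derivative | frequency | statistical
    amp_exp: int
    time_exp: int


def _m(name: str, a: int, t: int) -> FeatureDef:
    return FeatureDef(name, "morphology", a, t)


def _w(name: str, a: int, t: int) -> FeatureDef:
    return FeatureDef(name, "width", a, t)


def _d(name: str, a: int, t: int) -> FeatureDef:
    return FeatureDef(name, "derivative", a, t)


def _f(name: str, a: int, t: int) -> FeatureDef:
    return FeatureDef(name, "frequency", a, t)


def _s(name: str, a: int, t: int) -> FeatureDef:
    return FeatureDef(name, "statistical", a, t)


FEATURE_MANIFEST: tuple[FeatureDef, ...] = (
    # --- morphology (12): foot-referenced amplitudes, timings, areas
    _m("systolic_amplitude", 1, 0),
    _m("diastolic_amplitude", 1, 0),
    _m("notch_amplitude", 1, 0),
    _m("diastolic_systolic_ratio", 0, 0),
    _m("notch_systolic_ratio", 0, 0),
    _m("pulse_duration", 0, 1),
    _m("rise_time", 0, 1),
    _m("decay_time", 0, 1),
    _m("pulse_area", 1, 1),
    _m("systolic_area", 1, 1),
    _m("diastolic_area", 1, 1),
    _m("area_ratio", 0, 0),
    # --- width (16): widths at % of systolic amplitude, split at the peak
    _w("sys_width_10", 0, 1),
    _w("sys_width_25", 0, 1),
    _w("sys_width_33", 0, 1),
    _w("sys_width_50", 0, 1),
    _w("sys_width_66", 0, 1),
    _w("sys_width_75", 0, 1),
    _w("dia_width_10", 0, 1),
    _w("dia_width_25", 0, 1),
    _w("dia_width_33", 0, 1),
    _w("dia_width_50", 0, 1),
    _w("dia_width_66", 0, 1),
    _w("dia_width_75", 0, 1),
    _w("width_50", 0, 1),
    _w("width_75", 0, 1),
    _w("dia_sys_ratio_50", 0, 0),
    _w("dia_sys_ratio_75", 0, 0),
    # --- derivative (12): 1st-derivative extremes, 2nd-derivative a-e waves
    _d("d1_max", 1, -1),
    _d("d1_min", 1, -1),
    _d("d1_max_time", 0, 1),
    _d("a_wave", 1, -2),
    _d("b_wave", 1, -2),
    _d("c_wave", 1, -2),
    _d("d_wave", 1, -2),
    _d("e_wave", 1, -2),
    _d("b_a_ratio", 0, 0),
    _d("c_a_ratio", 0, 0),
    _d("d_a_ratio", 0, 0),
    _d("e_a_ratio", 0, 0),
    # --- frequency (9): whole-window spectrum after mean removal
    _f("fundamental_freq", 0, -1),
    _f("fundamental_mag", 1, 0),
    _f("harmonic2_mag", 1, 0),
    _f("harmonic3_mag", 1, 0),
    _f("harmonic2_ratio", 0, 0),
    _f("harmonic3_ratio", 0, 0),
    _f("spectral_centroid", 0, -1),
    _f("spectral_bandwidth", 0, -1),
    _f("spectral_entropy", 0, 0),
    # --- statistical (9): raw-window summary statistics
    _s("stat_mean", 1, 0),
    _s("stat_std", 1, 0),
    _s("stat_skewness", 0, 0),
    _s("stat_kurtosis", 0, 0),
    _s("stat_min", 1, 0),
    _s("stat_max", 1, 0),
    _s("stat_iqr", 1, 0),
    _s("stat_rms", 1, 0),
    _s("zero_crossings", 0, 0),
)

FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in FEATURE_MANIFEST)

PER_PULSE_CATEGORIES = ("morphology", "width", "derivative")
PER_WINDOW_CATEGORIES = ("frequency", "statistical")


def category_counts() -> dict[str, int]:
    counts: dict[str, int] = {}
    for f in FEATURE_MANIFEST:
        counts[f.category] = counts.get(f.category, 0) + 1
    return counts
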