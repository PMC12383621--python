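"""Feature-extraction tests: manifest lock, fiducials, width oracle,
scaling equivariance, spectral and normalization behavior."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import spearmanr

from peblkit import (
    PulseTemplate,
    build_ground_truth,
    detect_pulses,
    extract_features,
    normalize_per_subject,
    pulse_features,
    pulse_waveform,
    resample_recording,
    segment_windows,
    simulate_cohort,
    simulate_subject,
    truncate_for_training,
    window_features,
)
from peblkit.features import Pulse, Window
from peblkit.manifest import (
    FEATURE_MANIFEST,
    FEATURE_NAMES,
    category_counts,
)
from peblkit.synthetic import CohortJitter

from conftest import SHORT_PROTOCOL, quiet_params


def make_window(samples, fs=100.0, target=0.0):
    n = len(samples)
    return Window(
        subject_id="w",
        start_s=0.0,
        end_s=n / fs,
        window_length_s=5,
        samples=np.asarray(samples, dtype=float),
        fs=fs,
        target=target,
    )


def triangle(fs=100.0, base_s=1.0, amplitude=1.0):
    """Symmetric triangular pulse with its apex exactly on the sample grid."""
    n = int(base_s * fs)
    half = n // 2
    up = np.linspace(0, amplitude, half + 1)
    down = np.linspace(amplitude, 0, half + 1)[1:]
    return np.concatenate([up, down])


def manual_pulse(samples, peak=None):
    n = len(samples)
    p = int(np.argmax(samples)) if peak is None else peak
    notch = p + (n - 1 - p) // 2
    return Pulse(
        onset_idx=0,
        systolic_peak_idx=p,
        dicrotic_notch_idx=notch,
        diastolic_peak_idx=notch,
        end_idx=n - 1,
    )


def brute_force_width(samples, dt, peak, frac):
    """Independent dense-grid + bisection oracle for width at a fraction of
    the foot-referenced systolic amplitude, on the piecewise-linear interpolant."""
    samples = np.asarray(samples, dtype=float) - samples[0]
    t = np.arange(len(samples)) * dt
    level = samples[peak] * frac

    def f(x):
        return np.interp(x, t, samples)

    def bisect(lo, hi, rising):
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if (f(mid) < level) == rising:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    grid = np.linspace(0, t[peak], 20001)
    below = grid[f(grid) < level]
    t_rise = bisect(below[-1], t[peak], True) if len(below) else 0.0
    grid = np.linspace(t[peak], t[-1], 20001)
    below = grid[f(grid) < level]
    t_fall = bisect(t[peak], below[0], False) if len(below) else t[-1]
    return t[peak] - t_rise, t_fall - t[peak]


class TestManifest:
    def test_manifest_is_frozen(self):
        assert len(FEATURE_NAMES) == 58
        assert len(set(FEATURE_NAMES)) == 58
        assert category_counts() == {
            "morphology": 12,
            "width": 16,
            "derivative": 12,
            "frequency": 9,
            "statistical": 9,
        }


class TestSegmentation:
    @pytest.mark.parametrize("window_s,expected", [(5, 120), (60, 10)])
    def test_window_counts(self, window_s, expected):
        aligned, gt = _aligned_600s()
        assert len(segment_windows(aligned, gt, window_s)) == expected

    def test_too_short_recording_yields_no_windows(self):
        aligned, gt = _aligned_600s()
        aligned = dataclasses.replace(
            aligned,
            time_s=aligned.time_s[:400],
            ppg=aligned.ppg[:400],
            v_hem=aligned.v_hem[:400],
            v_wb=aligned.v_wb[:400],
            v_cr=aligned.v_cr[:400],
        )
        gt = dataclasses.replace(gt, pebl=gt.pebl[:400], fluid_balance=gt.fluid_balance[:400])
        with pytest.warns(UserWarning):
            assert segment_windows(aligned, gt, 5) == []

    def test_window_target_is_mean_ground_truth(self):
        aligned, gt = _aligned_600s()
        ws = segment_windows(aligned, gt, 10)
        np.testing.assert_allclose(ws[3].target, gt.pebl[3000:4000].mean())


def _aligned_600s():
    from peblkit.synthetic import ProtocolSpec

    proto = ProtocolSpec(
        baseline_duration_s=200.0,
        hemorrhage_rate_ml_min=120.0,
        hemorrhage_target_pebl=0.25,
        hold_duration_s=100.0,
        resuscitation_duration_s=0.0,
    )
    rec = simulate_subject(quiet_params(seed=2), proto)
    aligned = resample_recording(rec)
    return aligned, build_ground_truth(aligned)


class TestDetectPulses:
    def test_counts_and_onsets_match_generator_manifest(self):
        rec = simulate_subject(quiet_params(heart_rate=75), SHORT_PROTOCOL)
        aligned = resample_recording(rec)
        gt = build_ground_truth(aligned)
        w = segment_windows(aligned, gt, 5)[2]
        pulses = detect_pulses(w)
        manifest = rec.beat_onsets_s[
            (rec.beat_onsets_s >= w.start_s) & (rec.beat_onsets_s < w.end_s)
        ]
        assert len(manifest) == 6  # 75 bpm over a 5 s window
        assert len(pulses) == len(manifest) - 1  # last onset opens an incomplete beat
        detected = np.array([p.onset_idx for p in pulses]) / w.fs + w.start_s
        np.testing.assert_allclose(detected, manifest[:-1], atol=0.03)

    def test_constant_window_has_no_pulses(self):
        assert detect_pulses(make_window(np.ones(500))) == []
        assert window_features(make_window(np.ones(500)), []) is None

    def test_fiducials_invariant_to_amplitude_scale(self):
        rec = simulate_subject(quiet_params(seed=1), SHORT_PROTOCOL)
        aligned = resample_recording(rec)
        gt = build_ground_truth(aligned)
        w = segment_windows(aligned, gt, 5)[1]
        doubled = dataclasses.replace(w, samples=2.0 * w.samples)
        assert detect_pulses(w) == detect_pulses(doubled)


class TestPulseFeatures:
    def test_triangle_width_geometry(self):
        seg = triangle()
        f = pulse_features(manual_pulse(seg), seg, fs=100.0)
        assert f["width_50"] == pytest.approx(0.50, abs=1e-12)
        assert f["sys_width_25"] + f["dia_width_25"] == pytest.approx(0.75, abs=1e-12)

    @pytest.mark.parametrize("kind", ["triangle", "gaussian"])
    def test_widths_match_brute_force_oracle(self, kind):
        fs = 100.0
        if kind == "triangle":
            seg = triangle(fs)
        else:
            t = np.arange(0, 1.0, 1 / fs)
            seg = np.exp(-0.5 * ((t - 0.4) / 0.1) ** 2)
        pulse = manual_pulse(seg)
        f = pulse_features(pulse, seg, fs=fs)
        for lvl in (10, 25, 33, 50, 66, 75):
            sw, dw = brute_force_width(seg, 1 / fs, pulse.systolic_peak_idx, lvl / 100)
            assert f[f"sys_width_{lvl}"] == pytest.approx(sw, abs=1e-9)
            assert f[f"dia_width_{lvl}"] == pytest.approx(dw, abs=1e-9)

    def test_unimodal_widths_nest(self):
        t = np.arange(0, 1.0, 0.01)
        seg = np.exp(-0.5 * ((t - 0.5) / 0.15) ** 2)
        f = pulse_features(manual_pulse(seg), seg, fs=100.0)
        assert f["width_75"] < f["width_50"] < f["sys_width_25"] + f["dia_width_25"]


@pytest.fixture(scope="module")
def coupled_window():
    rec = simulate_subject(quiet_params(seed=3), SHORT_PROTOCOL)
    aligned = resample_recording(rec)
    gt = build_ground_truth(aligned)
    return segment_windows(aligned, gt, 5)[4]


class TestScalingEquivariance:
    def test_amplitude_scaling_every_feature(self, coupled_window):
        """x -> c*x multiplies each feature by c**amp_exp, exactly."""
        w = coupled_window
        c = 3.0
        scaled = dataclasses.replace(w, samples=c * w.samples)
        f1 = window_features(w, detect_pulses(w))
        f2 = window_features(scaled, detect_pulses(scaled))
        for fd in FEATURE_MANIFEST:
            expected = f1[fd.name] * c**fd.amp_exp
            assert f2[fd.name] == pytest.approx(expected, rel=1e-9, abs=1e-12), fd.name

    def test_time_stretch_per_pulse_features(self):
        """Stretching the pulse 2x scales each per-pulse feature by 2**time_exp
        (up to sampling-grid interpolation error)."""
        tpl = PulseTemplate()
        fs = 2000.0  # fine grid keeps peak-index quantization below tolerance
        t1 = np.arange(0, 0.8, 1 / fs)
        t2 = np.arange(0, 1.6, 1 / fs)
        seg1 = pulse_waveform(t1, tpl, 0.8)
        seg2 = pulse_waveform(t2, tpl, 1.6)

        def frac_pulse(seg):
            # fiducials at fixed cycle fractions so both grids mark the
            # same anatomical points (notch dip, dicrotic-lobe center)
            n = len(seg) - 1
            return Pulse(
                onset_idx=0,
                systolic_peak_idx=int(np.argmax(seg)),
                dicrotic_notch_idx=int(round(0.40 * n)),
                diastolic_peak_idx=int(round(0.47 * n)),
                end_idx=n,
            )

        f1 = pulse_features(frac_pulse(seg1), seg1, fs)
        f2 = pulse_features(frac_pulse(seg2), seg2, fs)
        for fd in FEATURE_MANIFEST:
            if fd.category not in ("morphology", "width", "derivative"):
                continue
            expected = f1[fd.name] * 2.0**fd.time_exp
            assert f2[fd.name] == pytest.approx(expected, rel=2e-2, abs=1e-4), fd.name


class TestWindowFeatures:
    def test_pure_sinusoid_fundamental(self):
        fs = 100.0
        t = np.arange(0, 10, 1 / fs)
        w = make_window(np.sin(2 * np.pi * 1.5 * t), fs)
        f = window_features(w, [manual_pulse(w.samples)])
        assert f["fundamental_freq"] == pytest.approx(1.5, abs=fs / len(t))

    def test_identical_pulses_average_to_single_pulse(self):
        rec = simulate_subject(quiet_params(seed=5), SHORT_PROTOCOL)
        aligned = resample_recording(rec)
        gt = build_ground_truth(aligned)
        w = segment_windows(aligned, gt, 5)[2]
        pulses = [p for p in detect_pulses(w) if p.valid][1:-1]
        f_all = window_features(w, pulses)
        f_one = pulse_features(pulses[0], w.samples, w.fs)
        for name, v in f_one.items():
            assert f_all[name] == pytest.approx(v, rel=1e-6, abs=1e-9), name


class TestNormalization:
    def test_min_max_arithmetic(self):
        from conftest import make_matrix

        X = np.zeros((3, 58))
        X[:, 0] = [2.0, 4.0, 6.0]
        X[:, 1] = [5.0, 5.0, 5.0]  # constant feature
        m = normalize_per_subject(make_matrix(X, np.zeros(3)))
        np.testing.assert_allclose(m.df[FEATURE_NAMES[0]], [0.0, 0.5, 1.0])
        np.testing.assert_allclose(m.df[FEATURE_NAMES[1]], 0.0)
        assert m.normalization == "per_subject"

    def test_idempotent_on_full_range_feature(self):
        from conftest import make_matrix

        X = np.zeros((4, 58))
        X[:, 0] = [0.0, 0.25, 0.75, 1.0]
        m = normalize_per_subject(make_matrix(X, np.zeros(4)))
        np.testing.assert_allclose(m.df[FEATURE_NAMES[0]], X[:, 0])

    def test_per_subject_scaling_is_independent(self):
        from conftest import make_matrix

        X = np.zeros((4, 58))
        X[:, 0] = [1.0, 3.0, 10.0, 30.0]
        m = normalize_per_subject(
            make_matrix(X, np.zeros(4), subjects=["a", "a", "b", "b"])
        )
        np.testing.assert_allclose(m.df[FEATURE_NAMES[0]], [0, 1, 0, 1])


class TestRecoverability:
    def test_systolic_amplitude_tracks_pebl_noiselessly(self):
        from peblkit.synthetic import NoiseParams
        import dataclasses as dc

        base = dc.replace(
            quiet_params(), coupling=type(quiet_params().coupling)(2.5, 0.8, 3.0)
        )
        base = dc.replace(base, noise=NoiseParams(0.0, 0.0, 0.0))
        recs = simulate_cohort(
            3, base_params=base, protocol=SHORT_PROTOCOL, seed=13,
            jitter=CohortJitter(0.05, 0.05, 0.05, 0.05),
        )
        for rec in recs:
            aligned = resample_recording(rec)
            gt = build_ground_truth(aligned)
            aligned, gt = truncate_for_training(aligned, gt)
            m = extract_features(segment_windows(aligned, gt, 5))
            rho = spearmanr(m.df["systolic_amplitude"], m.df["target"]).statistic
            assert rho <= -0.95
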