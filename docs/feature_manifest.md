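# PPG feature manifest (version 1.0)

The extractor emits exactly these 58 features per sampling window, in this
order. The manifest is frozen by test: any change to names, order, counts
or scaling signatures is an API break and requires a version bump.

Scaling signature: a feature responds to an amplitude scaling of the
signal (`x -> c*x`) as `c^amp` and to a time stretch (`t -> s*t`) as
`s^time`. Per-pulse features (morphology, width, derivative) are averaged
over the valid pulses of a window; frequency and statistical features are
computed once per window.

## Morphology (12) — foot-referenced amplitudes, timings, areas

| name | amp | time | description |
|---|---|---|---|
| systolic_amplitude | 1 | 0 | systolic peak above the pulse foot |
| diastolic_amplitude | 1 | 0 | diastolic peak above the foot |
| notch_amplitude | 1 | 0 | dicrotic notch above the foot |
| diastolic_systolic_ratio | 0 | 0 | diastolic / systolic amplitude |
| notch_systolic_ratio | 0 | 0 | notch / systolic amplitude |
| pulse_duration | 0 | 1 | onset to onset, s |
| rise_time | 0 | 1 | onset to systolic peak, s |
| decay_time | 0 | 1 | systolic peak to pulse end, s |
| pulse_area | 1 | 1 | trapezoidal area of the foot-referenced pulse |
| systolic_area | 1 | 1 | area from onset to the notch |
| diastolic_area | 1 | 1 | area from the notch to the end |
| area_ratio | 0 | 0 | diastolic_area / systolic_area |

## Width (16) — widths at % of systolic amplitude, split at the peak

Crossing times are linearly interpolated between the bracketing samples.
`sys_width_P` is the time from the rising crossing of P% amplitude to the
systolic peak; `dia_width_P` from the peak to the falling crossing.

| name | amp | time |
|---|---|---|
| sys_width_10, sys_width_25, sys_width_33, sys_width_50, sys_width_66, sys_width_75 | 0 | 1 |
| dia_width_10, dia_width_25, dia_width_33, dia_width_50, dia_width_66, dia_width_75 | 0 | 1 |
| width_50, width_75 (systolic + diastolic portions) | 0 | 1 |
| dia_sys_ratio_50, dia_sys_ratio_75 | 0 | 0 |

## Derivative (12) — velocity and acceleration waves

| name | amp | time | description |
|---|---|---|---|
| d1_max | 1 | -1 | maximum upstroke slope |
| d1_min | 1 | -1 | steepest downslope |
| d1_max_time | 0 | 1 | time of max slope from onset |
| a_wave, b_wave, c_wave, d_wave, e_wave | 1 | -2 | second-derivative wave amplitudes |
| b_a_ratio, c_a_ratio, d_a_ratio, e_a_ratio | 0 | 0 | acceleration-wave ratios |

## Frequency (9) — window spectrum after mean removal

| name | amp | time | description |
|---|---|---|---|
| fundamental_freq | 0 | -1 | spectral argmax in [0.5, 4] Hz (cardiac band) |
| fundamental_mag | 1 | 0 | magnitude at the fundamental |
| harmonic2_mag, harmonic3_mag | 1 | 0 | magnitudes at 2x and 3x the fundamental |
| harmonic2_ratio, harmonic3_ratio | 0 | 0 | harmonic / fundamental magnitude |
| spectral_centroid | 0 | -1 | amplitude-weighted mean frequency |
| spectral_bandwidth | 0 | -1 | amplitude-weighted frequency spread |
| spectral_entropy | 0 | 0 | normalized power-spectral entropy |

## Statistical (9) — raw-window summary statistics

| name | amp | time | description |
|---|---|---|---|
| stat_mean, stat_std, stat_min, stat_max, stat_iqr, stat_rms | 1 | 0 | location / scale summaries |
| stat_skewness, stat_kurtosis | 0 | 0 | shape summaries |
| zero_crossings | 0 | 0 | sign changes of the linearly detrended window |
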