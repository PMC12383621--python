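"""End-to-end convenience wrappers: cohort -> aligned -> feature matrices.

These helpers glue the generator, ground-truth and feature modules
together for the common case of a fully synthetic study: simulate a
cohort, harmonize each recording to 100 Hz, build PEBL / fluid-balance
targets, truncate for training, and extract pooled feature matrices at
one or several window lengths.
"""

from __future__ import annotations

from .features import FeatureMatrix, cohort_feature_matrix
from .ground_truth import (
    AlignedRecording,
    GroundTruthSeries,
    build_ground_truth,
    resample_recording,
    truncate_for_training,
)
from .synthetic import ProtocolSpec, SubjectParams, SubjectRecording, simulate_cohort

__all__ = [
    "align_cohort",
    "simulate_aligned_cohort",
    "feature_matrices",
]

Pair = tuple[AlignedRecording, GroundTruthSeries]


def align_cohort(
    recordings: list[SubjectRecording], truncate: bool = True
) -> list[Pair]:
    """Resample + ground truth for every recording; optionally truncate to
    the training span (final 10 baseline minutes + hemorrhage + hold)."""
    pairs: list[Pair] = []
    for rec in recordings:
        aligned = resample_recording(rec)
        gt = build_ground_truth(aligned)
        if truncate:
            aligned, gt = truncate_for_training(aligned, gt)
        pairs.append((aligned, gt))
    return pairs


def simulate_aligned_cohort(
    n_subjects: int,
    seed: int = 0,
    base_params: SubjectParams | None = None,
    protocol: ProtocolSpec | None = None,
) -> tuple[list[Pair], list[Pair]]:
    """Simulate a cohort and return (truncated, full-timeline) aligned pairs."""
    recordings = simulate_cohort(
        n_subjects, base_params=base_params, protocol=protocol, seed=seed
    )
    return align_cohort(recordings, truncate=True), align_cohort(
        recordings, truncate=False
    )


def feature_matrices(
    pairs: list[Pair],
    window_lengths_s: tuple[float, ...] = (5,),
    target: str = "pebl",
) -> dict[float, FeatureMatrix]:
    """Pooled un-normalized feature matrix per requested window length."""
    return {
        w: cohort_feature_matrix(pairs, w, target=target) for w in window_lengths_s
    }
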