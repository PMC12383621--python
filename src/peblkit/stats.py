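"""Nonparametric comparison of model configurations.

Per-subject R² (or other metric) vectors are paired across configurations
— the same blind subjects underlie every configuration — so comparisons
use matched nonparametric tests: Shapiro–Wilk for normality per group,
the Friedman test with Dunn's post-hoc multiple comparisons when more
than two configurations are compared, and the Wilcoxon matched-pairs
signed-rank test for exactly two.  Significance is judged at alpha = 0.05.

Dunn's post hoc is computed on the Friedman within-block ranks: with k
groups and n blocks, the difference of mean ranks between groups i and j
is referred to z = (R_i - R_j) / sqrt(k(k+1)/(6n)), with Bonferroni
adjustment over the k(k-1)/2 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

ALPHA = 0.05

__all__ = ["StatTestResult", "shapiro_wilk", "friedman", "dunn_posthoc",
           "wilcoxon_paired", "compare_statistics", "ALPHA"]


@dataclass(frozen=True)
class StatTestResult:
    test: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _result(test: str, groups: tuple[str, ...], stat: float, p: float,
            alpha: float) -> StatTestResult:
    return StatTestResult(test, groups, float(stat), float(p), bool(p < alpha))


def shapiro_wilk(name: str, values: np.ndarray, alpha: float = ALPHA) -> StatTestResult:
    stat, p = spstats.shapiro(np.asarray(values, dtype=float))
    return _result("shapiro-wilk", (name,), stat, p, alpha)


def friedman(groups: dict[str, np.ndarray], alpha: float = ALPHA) -> StatTestResult:
    stat, p = spstats.friedmanchisquare(*[np.asarray(v) for v in groups.values()])
    return _result("friedman", tuple(groups), stat, p, alpha)


def dunn_posthoc(
    groups: dict[str, np.ndarray], alpha: float = ALPHA, adjust: str = "bonferroni"
) -> list[StatTestResult]:
    """Pairwise Dunn tests on the Friedman within-block mean ranks."""
    names = list(groups)
    data = np.column_stack([np.asarray(groups[n], dtype=float) for n in names])
    n, k = data.shape
    if k < 3:
        raise ValueError("Dunn's post hoc needs at least 3 groups")
    ranks = np.apply_along_axis(spstats.rankdata, 1, data)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    n_pairs = k * (k - 1) // 2
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * spstats.norm.sf(abs(z))
            if adjust == "bonferroni":
                p = min(p * n_pairs, 1.0)
            elif adjust != "none":
                raise ValueError(f"unknown adjustment {adjust!r}")
            out.append(_result("dunn", (names[i], names[j]), z, p, alpha))
    return out


def wilcoxon_paired(
    name_a: str, a: np.ndarray, name_b: str, b: np.ndarray, alpha: float = ALPHA
) -> StatTestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if np.allclose(a, b):
        # all differences zero: no evidence of any difference
        return _result("wilcoxon", (name_a, name_b), 0.0, 1.0, alpha)
    stat, p = spstats.wilcoxon(a, b)
    return _result("wilcoxon", (name_a, name_b), stat, p, alpha)


def compare_statistics(
    groups: dict[str, np.ndarray], alpha: float = ALPHA
) -> list[StatTestResult]:
    """The full comparison battery over paired-by-subject metric vectors.

    Shapiro–Wilk per group; then Friedman + Dunn's post hoc for more than
    two groups, or the Wilcoxon matched-pairs test for exactly two.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    lengths = {len(v) for v in groups.values()}
    if len(lengths) != 1:
        raise ValueError("metric vectors must be paired (equal length)")
    results = [shapiro_wilk(name, v, alpha) for name, v in groups.items()]
    if len(groups) == 2:
        (na, va), (nb, vb) = groups.items()
        results.append(wilcoxon_paired(na, va, nb, vb, alpha))
    else:
        results.append(friedman(groups, alpha))
        results.extend(dunn_posthoc(groups, alpha))
    return results
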