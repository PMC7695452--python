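"""Bespoke statistical procedures used with clone-scoring data.

Two-proportion comparisons use the 'N-1' chi-squared test: the Pearson
chi-squared statistic for the 2x2 table scaled by (N-1)/N, reported as a
signed z score.  Proliferation-pattern comparisons use a weighted
expected-EdU layer-distribution chi-squared test.  Uncertainty on scored
proportions is the standard error of a proportion.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .model import LayerEduData, TestResult

__all__ = [
    "n1_chi2_two_proportions",
    "proportion_se",
    "edu_layer_distribution_test",
    "binomial_labeling_pmf",
]


def n1_chi2_two_proportions(s1: int, n1: int, s2: int, n2: int) -> TestResult:
    """'N-1' chi-squared comparison of two proportions s1/n1 vs s2/n2.

    The Pearson chi-squared statistic on the 2x2 success/failure table is
    scaled by (N-1)/N with N = n1 + n2; the signed square root (sign of
    p1 - p2) is the z score, and the two-sided p-value comes from the
    standard normal.  Degenerate margins (all successes or all failures
    pooled) give statistic 0 and p-value 1.
    """
    for label, s, n in (("first", s1, n1), ("second", s2, n2)):
        if not 0 <= s <= n:
            raise ValueError(f"{label} sample: need 0 <= successes <= n, got {s}/{n}")
    N = n1 + n2
    if N < 2:
        raise ValueError("need at least two observations in total")

    s = s1 + s2
    f = N - s
    if s == 0 or f == 0 or n1 == 0 or n2 == 0:
        return TestResult(statistic=0.0, z=0.0, p_value=1.0, df=1, method="n1_chi2")

    f1, f2 = n1 - s1, n2 - s2
    # Pearson chi-squared for a 2x2 table, cross-product form
    pearson = N * (s1 * f2 - s2 * f1) ** 2 / (n1 * n2 * s * f)
    statistic = pearson * (N - 1) / N
    z = math.copysign(math.sqrt(statistic), s1 / n1 - s2 / n2)
    # two-sided standard-normal tail: 2*Phi(-|z|) = erfc(|z|/sqrt(2))
    p_value = math.erfc(abs(z) / math.sqrt(2.0))
    return TestResult(statistic=statistic, z=z, p_value=min(p_value, 1.0), df=1, method="n1_chi2")


def proportion_se(s: int, n: int) -> float:
    """Standard error of a proportion: sqrt(p*(1-p)/n) with p = s/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= s <= n:
        raise ValueError(f"need 0 <= s <= n, got {s}/{n}")
    p = s / n
    return math.sqrt(p * (1.0 - p) / n)


def edu_layer_distribution_test(
    mutant: LayerEduData,
    control_layer_weights: Sequence[float],
    control_edu_index: Sequence[float],
    control_overall_edu: float,
) -> TestResult:
    """Test whether a genotype's EdU gradient across FSC layers matches the
    control pattern, independent of its overall proliferation level.

    The genotype's overall EdU index M is computed as the weighted mean of
    its per-layer indices, weighted by the control layer-occupancy
    distribution.  Expected per-layer indices preserve M but impose the
    control shape: E_L = M * control_edu_index[L] / control_overall_edu.
    Expected EdU counts E_L * n_L are compared with observed counts by
    Pearson chi-squared; df = (tested layers) - 1.

    A genotype whose per-layer indices are proportional to the control
    indices scores statistic 0, provided ``control_overall_edu`` is the
    weight-blended control index (the self-consistent choice).  Layers with
    no scored cells are dropped with a warning and df reduced.
    """
    weights = list(control_layer_weights)
    ctrl_idx = list(control_edu_index)
    if len(weights) != 3 or len(ctrl_idx) != 3:
        raise ValueError("need three layer weights and three control indices")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError(f"layer weights must sum to 1, got {sum(weights)}")
    if control_overall_edu <= 0:
        raise ValueError("control overall EdU index must be positive")

    kept = [i for i, (_, n) in enumerate(mutant.layers) if n > 0]
    if len(kept) < len(mutant.layers):
        dropped = [i + 1 for i in range(3) if i not in kept]
        warnings.warn(
            f"dropping layer(s) {dropped} with no scored cells; df reduced",
            stacklevel=2,
        )
    if len(kept) <= 1:
        return TestResult(statistic=0.0, z=0.0, p_value=1.0, df=0, method="edu_layer_chi2")

    obs_idx = {i: mutant.layers[i][0] / mutant.layers[i][1] for i in kept}
    m_overall = sum(weights[i] * obs_idx[i] for i in kept) / sum(weights[i] for i in kept)

    statistic = 0.0
    for i in kept:
        n_i = mutant.layers[i][1]
        expected_idx = m_overall * ctrl_idx[i] / control_overall_edu
        expected = expected_idx * n_i
        observed = mutant.layers[i][0]
        if expected > 0:
            statistic += (observed - expected) ** 2 / expected
    df = len(kept) - 1
    p_value = float(sps.chi2.sf(statistic, df)) if df > 0 else 1.0
    return TestResult(
        statistic=statistic, z=float("nan"), p_value=p_value, df=df, method="edu_layer_chi2"
    )


def binomial_labeling_pmf(n: int, mean: float) -> np.ndarray:
    """Binomial(n, mean/n) pmf over 0..n: the distribution of initially
    labeled FSCs per germarium when each of n FSCs is independently marked
    at clone induction with probability mean/n."""
    if n <= 0:
        raise ValueError("n must be a positive integer")
    if not 0.0 <= mean <= n:
        raise ValueError("mean must be in [0, n]")
    return sps.binom.pmf(np.arange(n + 1), n, mean / n)
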