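"""The immediate-FC conversion-probability estimator and related metrics.

Model
-----
Let p be the per-budding-cycle probability that a layer-1 FSC becomes a
follicle cell (FC) and q the per-cycle probability that it divides.  A
division is assumed to occur, on average, halfway through the cycle, so a
newborn layer-1 FSC faces conversion probability p/2.  The total per-cycle
probability that a single layer-1 FSC lineage yields at least one FC is

    P(p, q) = p + (1 - p) * q * (p / 2) = p + p*q/2 - p**2*q/2.

Scoring records whether a germarium with k marked layer-1 FSCs lacks a
marked "immediate FC" (an FC produced in the most recent cycle).  For k
independent layer-1 FSCs the no-FC probability is (1 - P)**k, so the k-th
root of the observed no-FC fraction estimates 1 - P, and p is recovered by
solving the quadratic 0 = (q/2) p**2 - (1 + q/2) p + (1 - x) for the root
in [0, 1].

q itself is obtained from EdU incorporation: the layer-1 EdU index relative
to the overall control FSC EdU index, scaled by 7/16 (seven of sixteen FSCs
divide in an average cycle).
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Tuple

from .model import (
    EcRatioResult,
    NoInformativeGermariaError,
    PfcEstimate,
    ScoringTable,
)

__all__ = [
    "forward_conversion_probability",
    "invert_conversion_probability",
    "per_fsc_no_fc_fraction",
    "division_probability",
    "estimate_pfc",
    "expected_fc_yield",
    "founder_fc_per_cycle",
    "ec_per_afsc",
    "ec_per_afsc_from_table",
    "percent_increase",
    "normalized_pathway_activity",
]

#: Division budget: seven of sixteen FSCs divide in an average budding cycle.
DIVIDING_FRACTION = 7.0 / 16.0

_Q_ZERO_THRESHOLD = 1e-9


def _require_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def forward_conversion_probability(p: float, q: float) -> float:
    """Total per-cycle probability P that a layer-1 FSC lineage yields an FC.

    ``P = p + p*q/2 - p**2*q/2``; monotone non-decreasing in both arguments,
    with P(p, 0) = p and P(1, q) = 1.
    """
    _require_unit("p", p)
    _require_unit("q", q)
    return p + p * q / 2.0 - p * p * q / 2.0


def invert_conversion_probability(x: float, q: float) -> float:
    """Solve for p given the no-FC fraction x = 1 - P and division probability q.

    Takes the minus root of ``0 = (q/2) p**2 - (1 + q/2) p + (1 - x)``,
    the unique root in [0, 1]; it satisfies the boundary cases p(x=1) = 0
    and p(x=0) = 1 exactly.  For q below 1e-9 the closed-form limit
    p = 1 - x is used to avoid 0/0.
    """
    _require_unit("x", x)
    _require_unit("q", q)
    if q < _Q_ZERO_THRESHOLD:
        return 1.0 - x
    b = 1.0 + q / 2.0
    disc = b * b - 2.0 * q * (1.0 - x)
    if disc < 0.0:
        # cannot occur for x, q in [0,1]; guard against float pathology
        raise ArithmeticError(f"negative discriminant {disc} for x={x}, q={q}")
    p = (b - math.sqrt(disc)) / q
    # clamp float dust at the boundaries
    return min(1.0, max(0.0, p))


def per_fsc_no_fc_fraction(n_no_fc: int, n_total: int, k: int) -> float:
    """Per-FSC no-FC fraction x_k = (n_no_fc / n_total)**(1/k).

    With k independent marked layer-1 FSCs the germarium-level no-FC
    probability is the per-FSC probability to the k-th power; the k-th root
    converts the observed germarium-level fraction back to the per-FSC
    scale (k in {1, 2, 3}).
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    if n_total <= 0:
        raise ValueError("n_total must be positive (empty group)")
    if not 0 <= n_no_fc <= n_total:
        raise ValueError(f"n_no_fc must be in [0, n_total], got {n_no_fc}/{n_total}")
    return (n_no_fc / n_total) ** (1.0 / k)


def division_probability(edu_layer1: float, edu_overall_control: float) -> float:
    """Per-cycle layer-1 division probability q from EdU incorporation.

    ``q = (edu_layer1 / edu_overall_control) * 7/16`` with both arguments as
    percentages (or any common scale).  The layer-1 index may come from a
    mutant genotype; the denominator is always the overall control FSC EdU
    index, which anchors the 7-of-16 division budget.  Values above 1 are
    clipped with a warning (extreme ratios arise from small samples).
    """
    if edu_layer1 < 0 or edu_overall_control < 0:
        raise ValueError("EdU percentages must be non-negative")
    if edu_overall_control == 0:
        raise ValueError("control overall EdU index must be positive")
    q = (edu_layer1 / edu_overall_control) * DIVIDING_FRACTION
    if q > 1.0:
        warnings.warn(
            f"division probability {q:.3f} exceeds 1; clipping to 1 "
            "(extreme EdU ratio)",
            stacklevel=2,
        )
        q = 1.0
    return q


def estimate_pfc(
    table: ScoringTable,
    edu_overall_control: float,
    edu_layer1: float,
    genotype: Optional[str] = None,
    day: Optional[float] = None,
) -> PfcEstimate:
    """Immediate-FC estimate of the per-cycle layer-1 FSC to FC conversion
    probability from a scoring table.

    Grouping rules (k = marked layer-1 FSC count at scoring):

    * k in {1, 2, 3}: informative, assigned to group k;
    * k = 0 with a marked immediate FC present: the only explanation is a
      layer-1 FSC that converted during the last cycle, so the germarium
      joins the k=1 group as FC-positive (denominator only);
    * k = 0 without a marked immediate FC: uninformative, excluded;
    * k > 3: excluded (such germaria almost invariably contain marked
      immediate FCs and carry no signal about single-FSC conversion).

    Group fractions are root-adjusted (:func:`per_fsc_no_fc_fraction`) and
    pooled with weights equal to group sizes; the pooled x feeds
    :func:`invert_conversion_probability` with q from
    :func:`division_probability`.
    """
    subset = table.filter(genotype=genotype, day=day)
    totals = {1: 0, 2: 0, 3: 0}
    no_fc = {1: 0, 2: 0, 3: 0}
    for obs in subset:
        k = obs.n_marked_l1
        if k == 0:
            if obs.immediate_fc_present:
                totals[1] += 1  # FC-positive by construction
            continue
        if k > 3:
            continue
        totals[k] += 1
        if not obs.immediate_fc_present:
            no_fc[k] += 1

    n_informative = sum(totals.values())
    if n_informative == 0:
        raise NoInformativeGermariaError(
            "no informative germaria (need marked layer-1 FSCs <= 3, or a "
            "marked immediate FC)"
        )

    weight_sum = 0.0
    weighted_x = 0.0
    group_counts: dict[int, Tuple[int, int]] = {}
    for k in (1, 2, 3):
        if totals[k] == 0:
            continue
        x_k = per_fsc_no_fc_fraction(no_fc[k], totals[k], k)
        weighted_x += totals[k] * x_k
        weight_sum += totals[k]
        group_counts[k] = (totals[k], no_fc[k])

    x_bar = weighted_x / weight_sum
    q = division_probability(edu_layer1, edu_overall_control)
    p_hat = invert_conversion_probability(x_bar, q)
    return PfcEstimate(
        p_hat=p_hat,
        q_used=q,
        x_weighted=x_bar,
        group_counts=group_counts,
        n_informative=n_informative,
    )


def expected_fc_yield(n_layer1: float, p: float, q: float) -> float:
    """Expected FCs produced per budding cycle from the layer-1 census.

    ``n_layer1 * (1 + q/2) * p``: the census is inflated by q/2 because
    newborn FSCs are present for half a cycle on average, and every
    effective layer-1 FSC converts with probability p.
    """
    if n_layer1 < 0:
        raise ValueError("n_layer1 must be non-negative")
    _require_unit("p", p)
    _require_unit("q", q)
    return n_layer1 * (1.0 + q / 2.0) * p


def founder_fc_per_cycle(mean_patch_fraction: float) -> float:
    """Founder FCs per cycle from the mean single-founder patch fraction.

    If one founder FC's descendants occupy a fraction f of the egg-chamber
    monolayer on average, 1/f founders seeded the chamber.
    """
    if not 0.0 < mean_patch_fraction <= 1.0:
        raise ValueError("mean_patch_fraction must be in (0, 1]")
    return 1.0 / mean_patch_fraction


def ec_per_afsc(
    mean_ec_at_t: float,
    afsc_control_6d: float,
    afsc_at_t: float,
    period: str = "0-6d",
) -> EcRatioResult:
    """Marked ECs per inferred marked anterior FSC over a scoring period.

    The anterior-FSC census over the period is inferred as the average of
    the control 6-day value (the best proxy for the 0-day census in every
    genotype) and the genotype's census at the endpoint.  For control data
    at 6 days the two coincide by construction.
    """
    if mean_ec_at_t < 0:
        raise ValueError("mean_ec_at_t must be non-negative")
    inferred = (afsc_control_6d + afsc_at_t) / 2.0
    if inferred <= 0:
        raise ValueError("inferred anterior-FSC census must be positive")
    return EcRatioResult(
        ratio=mean_ec_at_t / inferred,
        n_germaria=0,
        mean_ec=mean_ec_at_t,
        mean_afsc_inferred=inferred,
        period=period,
    )


def ec_per_afsc_from_table(
    table: ScoringTable,
    afsc_control_6d: float,
    genotype: Optional[str] = None,
    day: Optional[float] = None,
) -> EcRatioResult:
    """Convenience wrapper computing the EC/aFSC ratio from a scoring table.

    Only germaria with at least one marked FSC (any layer) contribute, so
    every contributing germarium had the opportunity to produce marked ECs
    throughout the period.
    """
    subset = [o for o in table.filter(genotype=genotype, day=day) if o.n_marked_fsc >= 1]
    if not subset:
        raise NoInformativeGermariaError("no germaria with >= 1 marked FSC")
    mean_ec = sum(o.n_marked_ec for o in subset) / len(subset)
    mean_afsc = sum(o.n_marked_afsc for o in subset) / len(subset)
    days = {o.day for o in subset}
    period = f"0-{int(max(days))}d" if days else ""
    result = ec_per_afsc(mean_ec, afsc_control_6d, mean_afsc, period=period)
    result.n_germaria = len(subset)
    return result


def percent_increase(earlier: float, later: float) -> float:
    """Percentage change from ``earlier`` to ``later``."""
    if earlier <= 0:
        raise ValueError("earlier value must be positive")
    return 100.0 * (later - earlier) / earlier


def normalized_pathway_activity(observed_pct: float, null_pct: float) -> float:
    """Reporter intensity as a multiple of the normal pathway-induced level.

    Both arguments are percentages of unmarked-neighbor intensity.  The
    pathway-null reporter baseline is subtracted from both observed and
    normal (100%) levels, so 100% maps to 1 and the null baseline to 0.
    """
    if null_pct >= 100.0:
        raise ValueError("null baseline must be below 100%")
    return (observed_pct - null_pct) / (100.0 - null_pct)
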