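"""Record types shared across the package.

The central object is the per-germarium scoring record
(:class:`Observation`): counts of GFP-marked follicle stem cells (FSCs) in
each of the three anteroposterior layers, EdU flags for those cells, marked
escort cell (EC) counts, and two presence/absence flags — whether a marked
"immediate FC" (the first Fas3-positive cell layer posterior to the FSC
domain, indicating FC production in the most recent budding cycle) was seen,
and whether any marked FC was seen.  A :class:`ScoringTable` is an ordered
collection of such records plus free-form metadata.

:class:`CycleParams` carries the per-budding-cycle population model (layer
censuses, per-layer division probabilities, differentiation probabilities,
EC turnover, EdU indices) used both by the simulator and by the estimators'
control calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Tuple

__all__ = [
    "Observation",
    "ScoringTable",
    "CycleParams",
    "LabelingConfig",
    "PfcEstimate",
    "EcRatioResult",
    "TestResult",
    "LayerEduData",
    "SchemaError",
    "ValidationError",
    "NoInformativeGermariaError",
    "EmptyTableError",
    "SCORING_COLUMNS",
]

#: Canonical scoring-table CSV column names, in writing order.
SCORING_COLUMNS: Tuple[str, ...] = (
    "germarium_id",
    "genotype",
    "day",
    "n_marked_l1",
    "n_marked_l2",
    "n_marked_l3",
    "edu_l1",
    "edu_l2",
    "edu_l3",
    "n_marked_ec",
    "edu_ec",
    "immediate_fc_present",
    "any_fc_present",
)


class SchemaError(ValueError):
    """A scoring-table file does not have the required columns."""


class ValidationError(ValueError):
    """A record violates a count invariant."""


class EmptyTableError(ValueError):
    """An operation requiring observations received none."""


class NoInformativeGermariaError(EmptyTableError):
    """No germarium in the table is informative for the requested estimate."""


@dataclass
class Observation:
    """One scored germarium.

    EdU fields may be ``None``: EdU incorporation is scored at the 6-day
    timepoint only, so 12-day tables legitimately omit those columns
    (absent, not zero).
    """

    germarium_id: str
    genotype: str
    day: float
    n_marked_l1: int
    n_marked_l2: int
    n_marked_l3: int
    edu_l1: Optional[int]
    edu_l2: Optional[int]
    edu_l3: Optional[int]
    n_marked_ec: int
    edu_ec: Optional[int]
    immediate_fc_present: bool
    any_fc_present: bool

    @property
    def n_marked_fsc(self) -> int:
        """Total marked FSCs across the three layers."""
        return self.n_marked_l1 + self.n_marked_l2 + self.n_marked_l3

    @property
    def n_marked_afsc(self) -> int:
        """Marked anterior FSCs (layers 2 and 3), the EC precursor pool."""
        return self.n_marked_l2 + self.n_marked_l3

    def violations(self) -> list[str]:
        """Return human-readable invariant violations (empty if valid)."""
        out: list[str] = []
        gid = self.germarium_id
        counts = {
            "n_marked_l1": self.n_marked_l1,
            "n_marked_l2": self.n_marked_l2,
            "n_marked_l3": self.n_marked_l3,
            "n_marked_ec": self.n_marked_ec,
        }
        for name, value in counts.items():
            if value < 0:
                out.append(f"{gid}: {name} is negative ({value})")
        if self.day < 0:
            out.append(f"{gid}: day is negative ({self.day})")
        pairs = [
            ("edu_l1", self.edu_l1, self.n_marked_l1, "n_marked_l1"),
            ("edu_l2", self.edu_l2, self.n_marked_l2, "n_marked_l2"),
            ("edu_l3", self.edu_l3, self.n_marked_l3, "n_marked_l3"),
            ("edu_ec", self.edu_ec, self.n_marked_ec, "n_marked_ec"),
        ]
        for name, edu, total, total_name in pairs:
            if edu is None:
                continue
            if edu < 0:
                out.append(f"{gid}: {name} is negative ({edu})")
            elif edu > total:
                out.append(f"{gid}: {name} ({edu}) exceeds {total_name} ({total})")
        return out


@dataclass
class ScoringTable:
    """Ordered collection of :class:`Observation` with table-level metadata."""

    observations: list[Observation] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self) -> Iterator[Observation]:
        return iter(self.observations)

    def filter(self, genotype: Optional[str] = None, day: Optional[float] = None) -> "ScoringTable":
        """Subset by genotype and/or day (both optional), preserving order."""
        obs = [
            o
            for o in self.observations
            if (genotype is None or o.genotype == genotype)
            and (day is None or o.day == day)
        ]
        return ScoringTable(observations=obs, metadata=dict(self.metadata))

    def violations(self) -> list[str]:
        """All record-level violations plus duplicate-id checks."""
        out: list[str] = []
        seen: set[tuple[str, float, str]] = set()
        for o in self.observations:
            out.extend(o.violations())
            key = (o.genotype, o.day, o.germarium_id)
            if key in seen:
                out.append(
                    f"duplicate germarium_id {o.germarium_id!r} within "
                    f"(genotype={o.genotype!r}, day={o.day})"
                )
            seen.add(key)
        return out


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class CycleParams:
    """Per-budding-cycle population model of the FSC domain.

    Parameters
    ----------
    layer_sizes
        Target FSC census per layer, posterior (layer 1) first.  The control
        steady-state censuses are 7.6/5.3/2.8, rounded to 8/5/3 for the
        integer-valued simulator.
    q_div
        Per-cycle division probability for an FSC in each layer.
    p_fc
        Per-cycle probability that a layer-1 FSC becomes a follicle cell
        (the quantity the immediate-FC estimator recovers).
    p_ec
        Per-cycle probability that an anterior (layer-2/3) FSC becomes an
        escort cell.
    ec_return, ec_death
        Per-cycle probability that a marked EC reverts to a layer-3 FSC, or
        is lost.  Their sum must not exceed 1.
    edu_index
        Per-layer probability that a cycling FSC scores EdU-positive in a
        1-hour pulse at snapshot time.
    cycle_hours
        Budding-cycle length; 12 h under optimal conditions.
    """

    layer_sizes: Tuple[float, float, float]
    q_div: Tuple[float, float, float]
    p_fc: float
    p_ec: float
    ec_return: float
    ec_death: float
    edu_index: Tuple[float, float, float]
    cycle_hours: float = 12.0

    def __post_init__(self) -> None:
        if len(self.layer_sizes) != 3 or any(s <= 0 for s in self.layer_sizes):
            raise ValueError("layer_sizes must be three positive numbers")
        for i, q in enumerate(self.q_div, start=1):
            _check_prob(f"q_div[layer {i}]", q)
        _check_prob("p_fc", self.p_fc)
        _check_prob("p_ec", self.p_ec)
        _check_prob("ec_return", self.ec_return)
        _check_prob("ec_death", self.ec_death)
        if self.ec_return + self.ec_death > 1.0 + 1e-12:
            raise ValueError("ec_return + ec_death must not exceed 1")
        for i, e in enumerate(self.edu_index, start=1):
            _check_prob(f"edu_index[layer {i}]", e)
        if self.cycle_hours <= 0:
            raise ValueError("cycle_hours must be positive")

    @property
    def census(self) -> Tuple[int, int, int]:
        """Integer per-layer census used by the simulator (rounded targets)."""
        return tuple(int(round(s)) for s in self.layer_sizes)  # type: ignore[return-value]


@dataclass
class LabelingConfig:
    """Binomial initial clone labeling: each of ``n_fsc_total`` FSCs is
    independently marked with probability ``mean_labeled / n_fsc_total``."""

    n_fsc_total: int = 16
    mean_labeled: float = 3.2
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_fsc_total <= 0:
            raise ValueError("n_fsc_total must be positive")
        if not 0.0 <= self.mean_labeled <= self.n_fsc_total:
            raise ValueError("mean_labeled must be in [0, n_fsc_total]")

    @property
    def p_label(self) -> float:
        return self.mean_labeled / self.n_fsc_total


@dataclass
class PfcEstimate:
    """Output of the immediate-FC conversion-probability estimator.

    ``group_counts`` maps k (marked layer-1 FSC count, 1..3) to
    ``(n_total, n_no_fc)``: germaria in that group and, of those, germaria
    lacking a marked immediate FC.
    """

    p_hat: float
    q_used: float
    x_weighted: float
    group_counts: dict[int, Tuple[int, int]]
    n_informative: int

    def to_dict(self) -> dict:
        return {
            "p_hat": self.p_hat,
            "q_used": self.q_used,
            "x_weighted": self.x_weighted,
            "group_counts": {str(k): list(v) for k, v in sorted(self.group_counts.items())},
            "n_informative": self.n_informative,
        }


@dataclass
class EcRatioResult:
    """Marked ECs per inferred marked anterior FSC over a scoring period."""

    ratio: float
    n_germaria: int
    mean_ec: float
    mean_afsc_inferred: float
    period: str = ""

    def to_dict(self) -> dict:
        return {
            "ratio": self.ratio,
            "n_germaria": self.n_germaria,
            "mean_ec": self.mean_ec,
            "mean_afsc_inferred": self.mean_afsc_inferred,
            "period": self.period,
        }


@dataclass
class TestResult:
    """Result of a significance test: statistic, signed z where defined,
    two-sided p-value, degrees of freedom and a method label."""

    statistic: float
    z: float
    p_value: float
    df: int
    method: str

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "z": self.z,
            "p_value": self.p_value,
            "df": self.df,
            "method": self.method,
        }


@dataclass
class LayerEduData:
    """Per-layer EdU scoring for one genotype: (EdU-positive, total) pairs
    for layers 1..3, posterior first."""

    layers: Tuple[Tuple[int, int], Tuple[int, int], Tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.layers) != 3:
            raise ValueError("exactly three (edu_count, n_total) pairs required")
        for i, (edu, total) in enumerate(self.layers, start=1):
            if edu < 0 or total < 0:
                raise ValueError(f"layer {i}: counts must be non-negative")
            if edu > total:
                raise ValueError(f"layer {i}: edu_count ({edu}) exceeds n_total ({total})")

    @property
    def indices(self) -> Tuple[float, ...]:
        """Per-layer EdU index (fraction), NaN for layers with no cells."""
        return tuple(
            (edu / total) if total > 0 else float("nan") for edu, total in self.layers
        )
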