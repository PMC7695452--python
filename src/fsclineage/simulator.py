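"""Stochastic per-budding-cycle model of a germarium's FSC population.

The germarium holds a fixed census of follicle stem cells (FSCs) in three
anteroposterior layers (control: 8/5/3, rounded from the measured
steady-state 7.6/5.3/2.8).  Each 12-hour budding cycle, every FSC divides
with a layer-specific probability; layer-1 FSCs convert to follicle cells
(FCs) with probability ``p_fc`` (newborns, present on average for half a
cycle, with ``p_fc / 2``); anterior FSCs convert to escort cells (ECs) with
probability ``p_ec``; newly derived ECs either revert to layer-3 FSCs or
are lost; and the census is restored by random inter-layer exchange and
compensatory divisions.  Marked and unmarked cells obey identical rules, so
the expected marked-cell count is conserved (neutral drift) while its
variance grows — the population-asymmetry signature.

A cohort of independent germaria, initialized with binomial clone labeling
and snapshotted at scoring days, yields a synthetic
:class:`~fsclineage.model.ScoringTable` with the statistical structure the
immediate-FC estimator assumes, enabling parameter-recovery validation.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import CycleParams, EmptyTableError, LabelingConfig, Observation, ScoringTable

__all__ = [
    "FscRecord",
    "GermariumState",
    "SimConfig",
    "control_params",
    "init_germarium",
    "step_cycle",
    "snapshot",
    "simulate_cohort",
    "summarize_cohort",
]

# Control calibration constants (fractions, not percentages)
_CONTROL_EDU_BY_LAYER = (0.334, 0.200, 0.082)
_CONTROL_EDU_OVERALL = 0.251
_DIVIDING_FRACTION = 7.0 / 16.0


@dataclass(slots=True)
class FscRecord:
    """One FSC: its layer (1 = posterior), mark status, and whether it was
    born in the current cycle (newborns face half the FC-conversion risk)."""

    layer: int
    marked: bool
    born_this_cycle: bool = False


@dataclass
class GermariumState:
    """Mutable state of one simulated germarium.

    ``marked_ec_count``/``unmarked_ec_count`` track only ECs newly derived
    from FSCs during the simulation (the pre-existing bulk EC population
    does not turn over and never re-enters the FSC pool); both pools obey
    the same turnover rules so that marking stays neutral.
    """

    fscs: list[FscRecord]
    marked_ec_count: int = 0
    unmarked_ec_count: int = 0
    marked_fc_last_cycle: int = 0
    cumulative_marked_fc: int = 0
    cycle_index: int = 0
    fc_history: deque = field(default_factory=lambda: deque(maxlen=10))
    #: marked counts per layer as seen at scoring time: the configuration at
    #: the start of the most recent cycle — the cells that were at risk of
    #: producing the immediate FCs the same snapshot reports.  This is the
    #: estimator's stationarity assumption ("the scored layer-1 FSCs were
    #: present at the start of the prior cycle"), adopted as the model's
    #: scoring convention.
    scored_layers: tuple[int, int, int] = (0, 0, 0)

    @property
    def n_marked_fsc(self) -> int:
        return sum(1 for f in self.fscs if f.marked)

    def marked_by_layer(self) -> tuple[int, int, int]:
        counts = [0, 0, 0]
        for f in self.fscs:
            if f.marked:
                counts[f.layer - 1] += 1
        return tuple(counts)  # type: ignore[return-value]


@dataclass
class SimConfig:
    """Configuration of one simulated cohort.

    ``snapshot_days`` must convert to whole budding cycles at
    ``params.cycle_hours``; EdU is scored only on days listed in
    ``edu_days`` (the scoring protocol applies the EdU pulse at 6 days
    only).  ``fc_window`` is the FC residence window in cycles: marked FCs
    produced within the window are still visible in the ovariole
    (10 cycles, about 5 days of transit).
    """

    params: CycleParams
    labeling: LabelingConfig
    n_germaria: int
    snapshot_days: tuple[float, ...] = (6.0,)
    seed: int = 0
    genotype: str = "control"
    edu_days: tuple[float, ...] = (6.0,)
    fc_window: int = 10

    def __post_init__(self) -> None:
        if self.n_germaria <= 0:
            raise ValueError("n_germaria must be positive")
        for day in self.snapshot_days:
            cycles = day * 24.0 / self.params.cycle_hours
            if abs(cycles - round(cycles)) > 1e-9:
                raise ValueError(
                    f"snapshot day {day} is not a whole number of "
                    f"{self.params.cycle_hours}-hour cycles"
                )

    def cycles_for_day(self, day: float) -> int:
        return int(round(day * 24.0 / self.params.cycle_hours))


def control_params() -> CycleParams:
    """The control parameterization measured across 31 MARCM experiments.

    Layer censuses 7.6/5.3/2.8 (integer model 8/5/3); per-layer division
    probabilities from the EdU gradient (33.4/20.0/8.2% against an overall
    25.1%) scaled by the 7-of-16 division budget; layer-1 FC conversion
    probability 0.616; EC conversion set so the 8-cell anterior census
    yields about 1.4 ECs per cycle; EC turnover return-dominated (2:1)
    with magnitudes placing the marked-EC plateau near 1.5 per germarium
    by 12 days.
    """
    q_div = tuple(
        (e / _CONTROL_EDU_OVERALL) * _DIVIDING_FRACTION for e in _CONTROL_EDU_BY_LAYER
    )
    return CycleParams(
        layer_sizes=(7.6, 5.3, 2.8),
        q_div=q_div,  # type: ignore[arg-type]
        p_fc=0.616,
        p_ec=1.4 / 8.0,
        ec_return=0.24,
        ec_death=0.12,
        edu_index=_CONTROL_EDU_BY_LAYER,
        cycle_hours=12.0,
    )


def init_germarium(
    params: CycleParams,
    labeling: LabelingConfig,
    rng: np.random.Generator,
    fc_window: int = 10,
) -> GermariumState:
    """Create a germarium at clone induction: full integer census, each FSC
    independently marked with probability ``labeling.mean_labeled / n_fsc_total``."""
    census = params.census
    p = labeling.p_label
    fscs: list[FscRecord] = []
    u = rng.random(sum(census))
    i = 0
    for layer, n in enumerate(census, start=1):
        for _ in range(n):
            fscs.append(FscRecord(layer=layer, marked=bool(u[i] < p)))
            i += 1
    state = GermariumState(fscs=fscs, fc_history=deque(maxlen=fc_window))
    state.scored_layers = state.marked_by_layer()
    return state


def _rebalance(state: GermariumState, params: CycleParams, rng: np.random.Generator) -> None:
    """Restore the per-layer census exactly.

    Shortfall: uniformly-random surviving FSCs divide to refill (mark
    inherited).  Overflow (more newborns than that cycle's losses): surplus
    divisions found no vacancy and are cancelled, removing uniformly-random
    surviving newborns — niche capacity limits effective division.  Both
    rules are mark-blind, so labeling stays neutral.  Remaining per-layer
    imbalance is fixed by moving uniformly-random FSCs between adjacent
    layers toward depleted layers.
    """
    fscs = state.fscs
    targets = list(params.census)
    total_target = sum(targets)

    while len(fscs) < total_target:
        if not fscs:
            raise RuntimeError("total FSC extinction; refill rule requires survivors")
        src = fscs[int(rng.integers(len(fscs)))]
        fscs.append(FscRecord(layer=src.layer, marked=src.marked, born_this_cycle=True))

    while len(fscs) > total_target:
        # prefer cancelling this cycle's surviving newborns; fall back to
        # any cell in the rare case returns alone overfill the niche
        idxs = [i for i, f in enumerate(fscs) if f.born_this_cycle]
        if not idxs:
            idxs = list(range(len(fscs)))
        fscs.pop(idxs[int(rng.integers(len(idxs)))])

    counts = [0, 0, 0]
    for f in fscs:
        counts[f.layer - 1] += 1
    while counts != targets:
        for i in (0, 1, 2):
            if counts[i] > targets[i]:
                if any(counts[j] < targets[j] for j in range(i + 1, 3)):
                    dest = i + 1
                else:
                    dest = i - 1
                idxs = [k for k, f in enumerate(fscs) if f.layer == i + 1]
                mover = fscs[idxs[int(rng.integers(len(idxs)))]]
                mover.layer = dest + 1
                counts[i] -= 1
                counts[dest] += 1
                break


def step_cycle(
    state: GermariumState, params: CycleParams, rng: np.random.Generator
) -> GermariumState:
    """Advance one budding cycle in place (also returns the state).

    Event order: division -> FC conversion -> EC conversion -> EC turnover
    -> census rebalancing.  Newborn FSCs face half the FC-conversion
    probability, realizing the assumption that division occurs midway
    through a cycle.
    """
    fscs = state.fscs
    state.marked_fc_last_cycle = 0

    # the configuration a microscopist scores alongside this cycle's
    # immediate FCs: the layer occupancy at the start of the cycle that
    # produced them (the estimator's stationarity assumption, adopted as
    # the model's scoring convention)
    state.scored_layers = state.marked_by_layer()

    # one uniform buffer serves the whole cycle (hot loop: one vector draw)
    n0 = len(fscs)
    n_ec = state.marked_ec_count + state.unmarked_ec_count
    buf = rng.random(3 * n0 + n_ec + 8)

    # 1. division: each FSC divides with its layer's probability; daughters
    # are born in place and flagged (they face half the conversion risk)
    q_div = params.q_div
    newborns: list[FscRecord] = []
    for i, f in enumerate(fscs):
        f.born_this_cycle = False
        if buf[i] < q_div[f.layer - 1]:
            newborns.append(FscRecord(layer=f.layer, marked=f.marked, born_this_cycle=True))
    pos = n0
    fscs.extend(newborns)

    # 2-3. differentiation sweep: layer-1 FSCs convert to FCs (newborns at
    # p_fc/2), anterior FSCs convert to ECs; independent uniforms per cell
    p_fc = params.p_fc
    half_p = p_fc / 2.0
    p_ec = params.p_ec
    survivors: list[FscRecord] = []
    sapp = survivors.append
    marked_fc = 0
    for f in fscs:
        ui = buf[pos]
        pos += 1
        if f.layer == 1:
            if ui < (half_p if f.born_this_cycle else p_fc):
                if f.marked:
                    marked_fc += 1
            else:
                sapp(f)
        elif ui < p_ec:
            if f.marked:
                state.marked_ec_count += 1
            else:
                state.unmarked_ec_count += 1
        else:
            sapp(f)
    state.marked_fc_last_cycle += marked_fc
    state.cumulative_marked_fc += marked_fc
    state.fscs = fscs = survivors

    # 4. EC turnover (newly derived ECs only; same rules for both marks)
    r, d = params.ec_return, params.ec_death
    rd = r + d
    for marked_flag in (True, False):
        n = state.marked_ec_count if marked_flag else state.unmarked_ec_count
        for _ in range(n):
            ui = buf[pos]
            pos += 1
            if ui < r:
                n -= 1
                fscs.append(FscRecord(layer=3, marked=marked_flag))
            elif ui < rd:
                n -= 1
        if marked_flag:
            state.marked_ec_count = n
        else:
            state.unmarked_ec_count = n

    # 5. restore the census
    _rebalance(state, params, rng)

    state.cycle_index += 1
    state.fc_history.append(state.marked_fc_last_cycle)
    return state


def snapshot(
    state: GermariumState,
    params: CycleParams,
    rng: np.random.Generator,
    germarium_id: str = "g0",
    genotype: str = "control",
    day: float = 0.0,
    score_edu: bool = True,
) -> Observation:
    """Score the germarium as a microscopist would at a fixed timepoint.

    Marked FSC counts per layer are the state's scored configuration — the
    layer occupancy at the start of the most recent budding cycle, the
    cells at risk of producing the immediate FCs reported alongside.  Each
    marked FSC is
    independently EdU-positive with its layer's EdU index (a 1-hour S-phase
    pulse).  ECs are quiescent and never score EdU.  The immediate-FC flag
    reports marked FC production in the most recent cycle; the any-FC flag
    reports marked FC output within the residence window (FCs transit the
    ovariole in about 5 days).
    """
    m1, m2, m3 = state.scored_layers
    if score_edu:
        edu = [int(rng.binomial(m, e)) if m > 0 else 0
               for m, e in zip((m1, m2, m3), params.edu_index)]
        edu_l1, edu_l2, edu_l3 = edu
        edu_ec: Optional[int] = 0
    else:
        edu_l1 = edu_l2 = edu_l3 = None  # type: ignore[assignment]
        edu_ec = None
    return Observation(
        germarium_id=germarium_id,
        genotype=genotype,
        day=day,
        n_marked_l1=m1,
        n_marked_l2=m2,
        n_marked_l3=m3,
        edu_l1=edu_l1,
        edu_l2=edu_l2,
        edu_l3=edu_l3,
        n_marked_ec=state.marked_ec_count,
        edu_ec=edu_ec,
        immediate_fc_present=state.marked_fc_last_cycle >= 1,
        any_fc_present=sum(state.fc_history) >= 1,
    )


def simulate_cohort(config: SimConfig) -> ScoringTable:
    """Simulate ``config.n_germaria`` independent germaria and score each at
    every snapshot day.

    Fully reproducible from ``config.seed``; per-germarium random streams
    are spawned from one root seed sequence, so increasing ``n_germaria``
    never reshuffles earlier germaria.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_germaria)
    days = sorted(config.snapshot_days)
    observations: list[Observation] = []
    per_germarium: list[list[Observation]] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        state = init_germarium(config.params, config.labeling, rng, fc_window=config.fc_window)
        done_cycles = 0
        rows: list[Observation] = []
        for day in days:
            target = config.cycles_for_day(day)
            while done_cycles < target:
                step_cycle(state, config.params, rng)
                done_cycles += 1
            rows.append(
                snapshot(
                    state,
                    config.params,
                    rng,
                    germarium_id=f"g{i:05d}",
                    genotype=config.genotype,
                    day=day,
                    score_edu=day in config.edu_days,
                )
            )
        per_germarium.append(rows)
    # group rows by day so each (genotype, day) block is contiguous
    for j in range(len(days)):
        observations.extend(rows[j] for rows in per_germarium)
    return ScoringTable(
        observations=observations,
        metadata={"seed": str(config.seed), "n_germaria": str(config.n_germaria)},
    )


def summarize_cohort(table: ScoringTable) -> list[dict]:
    """Cohort summary per (genotype, day).

    Reports the mean marked-FSC count over all germaria (including empty
    ones), layer-occupancy proportions among marked FSCs, per-layer EdU
    indices of marked FSCs, the fraction of germaria retaining any marked
    FSC, the fraction retaining a marked FSC alongside marked FCs, and the
    mean marked-EC count among germaria with at least one marked FSC.
    """
    if len(table) == 0:
        raise EmptyTableError("cannot summarize an empty table")
    groups: dict[tuple[str, float], list[Observation]] = {}
    for o in table:
        groups.setdefault((o.genotype, o.day), []).append(o)

    out: list[dict] = []
    for (genotype, day), obs in sorted(groups.items()):
        n = len(obs)
        marked = [o.n_marked_fsc for o in obs]
        total_marked = sum(marked)
        by_layer = [
            sum(o.n_marked_l1 for o in obs),
            sum(o.n_marked_l2 for o in obs),
            sum(o.n_marked_l3 for o in obs),
        ]
        layer_props = (
            [c / total_marked for c in by_layer] if total_marked else [0.0, 0.0, 0.0]
        )
        edu_idx: list[Optional[float]] = []
        for layer_attr, edu_attr, count in zip(
            ("n_marked_l1", "n_marked_l2", "n_marked_l3"),
            ("edu_l1", "edu_l2", "edu_l3"),
            by_layer,
        ):
            scored = [o for o in obs if getattr(o, edu_attr) is not None]
            denom = sum(getattr(o, layer_attr) for o in scored)
            num = sum(getattr(o, edu_attr) for o in scored)
            edu_idx.append(num / denom if denom else None)
        with_fsc = [o for o in obs if o.n_marked_fsc >= 1]
        out.append(
            {
                "genotype": genotype,
                "day": day,
                "n_germaria": n,
                "mean_marked_fsc": total_marked / n,
                "var_marked_fsc": float(np.var(marked)),
                "layer_occupancy": layer_props,
                "edu_index_by_layer": edu_idx,
                "frac_with_marked_fsc": len(with_fsc) / n,
                "frac_with_fsc_and_fc": sum(1 for o in with_fsc if o.any_fc_present) / n,
                "mean_marked_ec_given_fsc": (
                    sum(o.n_marked_ec for o in with_fsc) / len(with_fsc)
                    if with_fsc
                    else 0.0
                ),
            }
        )
    return out
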