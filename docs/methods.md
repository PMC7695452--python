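# Methods

## The system being modeled

The *Drosophila* germarium maintains ~16 Follicle Stem Cells (FSCs) in
three anteroposterior rings (layers 1–3, posterior first) just anterior to
the Fas3 border.  Every ~12-hour budding cycle the community produces
follicle cells (FCs) from layer 1 and escort cells (ECs) from layers 2–3.
Maintenance is by population asymmetry: division and differentiation are
stochastic, uncorrelated, per-cell events, and individual marked lineages
drift — some to extinction, some to dominance — while the community stays
balanced.  Lineage experiments mark a random subset of FSCs (MARCM) and
score, per germarium, the marked FSC count per layer, EdU incorporation
(a 1-hour S-phase pulse at the 6-day timepoint), marked EC counts, and the
presence of marked "immediate FCs" — the FC layer apposed to the newest
encapsulated cyst, which must have been produced during the most recent
budding cycle.

## The immediate-FC estimator

Let `p` be the per-cycle probability that a layer-1 FSC becomes an FC and
`q` its per-cycle division probability.  Division is assumed to occur, on
average, midway through a cycle, so a newborn layer-1 FSC is exposed to
conversion for half a cycle and faces probability `p/2`.  A single
layer-1 FSC lineage therefore yields at least one FC in a cycle with
probability

    P(p, q) = p + (1 − p)·q·(p/2) = p + pq/2 − p²q/2.

A germarium with `k` independent marked layer-1 FSCs shows no marked
immediate FC with probability `(1 − P)^k`.  The estimator:

1. groups informative germaria by `k ∈ {1, 2, 3}` marked layer-1 FSCs;
   germaria with an empty marked layer 1 but a marked immediate FC join
   the `k = 1` group as FC-positive (their layer-1 FSC just converted);
   germaria with `k = 0` and no marked FC carry no signal and are
   excluded, as are `k > 3` (they almost always contain marked immediate
   FCs);
2. takes the k-th root of each group's no-FC fraction
   (`per_fsc_no_fc_fraction`) to put it on the per-FSC scale;
3. pools the adjusted fractions with weights equal to group sizes;
4. computes `q = (EdU₁ / EdU_overall_control) × 7/16`, anchoring the
   division budget to the observation that about 7 of 16 FSCs divide per
   cycle; the layer-1 EdU index may come from a mutant genotype, the
   denominator is always the control overall index;
5. solves `0 = (q/2)p² − (1 + q/2)p + (1 − x̄)` for the root in [0, 1]:

       p = [(1 + q/2) − sqrt((1 + q/2)² − 2q(1 − x̄))] / q.

The minus root is the unique root in the unit interval and reproduces the
boundary cases `p(x̄=1) = 0` and `p(x̄=0) = 1` exactly.  For `q < 1e-9`
the closed-form limit `p = 1 − x̄` avoids 0/0.  The discriminant is
non-negative for all valid inputs; a guard raises on float pathology.

Validation of the k-th-root step uses a brute-force oracle (simulated
independent Bernoulli FSCs); validation of the whole estimator is by
parameter recovery from the simulator (below).

## Companion metrics

* **Expected FC yield per cycle**: `N₁ · (1 + q/2) · p` — the layer-1
  census inflated by the half-cycle presence of newborns, times the
  conversion probability.  Both division-budget variants are exposed: the
  literal `q = 7/16` (yield 5.71 from the control census 7.6 and
  p = 0.616) and the EdU-adjusted `q = 0.5822` (yield 6.04).  The
  arithmetic as printed in the source study rounds to 6.1; the exact `q`
  behind that figure is not recoverable, so both variants are reported
  rather than silently reconciling them.
* **Founder FCs per cycle**: the reciprocal of the mean fraction of the
  egg-chamber monolayer occupied by a single founder's patch (1/0.178 ≈
  5.6) — the independent cross-check on the FC yield.
* **EC per anterior FSC**: marked ECs per germarium divided by the
  inferred anterior-FSC census over the period, the census being the
  average of the control 6-day value (the proxy for day 0 in every
  genotype) and the genotype's value at the endpoint.  For control data
  at 6 days the two coincide.  Only germaria retaining at least one
  marked FSC contribute, so every contributor could have produced marked
  ECs throughout the period.
* **Reporter normalization**: `(observed% − null%) / (100% − null%)`
  expresses a pathway reporter's intensity in marked cells (as % of
  unmarked neighbors) as a multiple of the normal pathway-induced level,
  after subtracting the pathway-null baseline measured in null-mutant
  clones.

## Statistical procedures

* **'N-1' chi-squared two-proportion test**: the Pearson chi-squared
  statistic of the 2×2 table scaled by `(N−1)/N`, reported as a signed z
  (sign of `p̂₁ − p̂₂`) with a two-sided normal p-value
  (`erfc(|z|/√2)`).  Degenerate margins return statistic 0, p = 1.
  Two-sided p-values throughout.
* **EdU layer-distribution test**: asks whether a genotype's
  proliferation gradient across layers differs from the control *pattern*
  independent of its overall level.  The genotype's overall index `M` is
  the weighted mean of its per-layer indices with weights equal to the
  control layer-occupancy distribution; expected per-layer indices
  preserve `M` but impose the control shape:
  `E_L = M × control_L / control_overall`.  Expected counts `E_L·n_L` are
  compared with observed EdU counts by Pearson chi-squared, df = layers−1.
  The scaling by `control_L / control_overall` is the only one under
  which a genotype exactly proportional to controls scores zero; it
  requires `control_overall` to be the weight-blended control index (the
  self-consistent value, used by default in the CLI).  This construction
  is isolated in one function so an alternative reading can be swapped in.
  Layers with no scored cells are dropped with a warning and df reduced;
  one remaining layer is degenerate (statistic 0, df 0, p 1).
* **Binomial labeling pmf**: each of `n = 16` FSCs is independently
  marked at clone induction with probability `mean/n`; the marked count
  is Binomial(16, 0.2) for the control mean of 3.2.

## The simulator

One germarium is a list of FSC records (layer, marked flag, born-this-cycle
flag) at the integer census (8, 5, 3), rounded from the measured
steady-state 7.6/5.3/2.8, plus pools of marked and unmarked newly derived
ECs.  Each cycle applies, in order:

1. **Division** — every FSC divides with its layer's probability
   `q_div = (0.582, 0.349, 0.143)`, from the control EdU gradient
   (33.4/20.0/8.2% against the 25.1% overall index) scaled by 7/16;
   daughters are born in place and flagged.
2. **FC conversion** — layer-1 residents convert with `p_fc = 0.616`,
   newborns with `p_fc/2` (the half-cycle rule taken literally).
3. **EC conversion** — layer-2/3 FSCs convert with `p_ec = 1.4/8 =
   0.175`, set so the 8-cell anterior census yields the stated ~1.4 ECs
   per cycle.
4. **EC turnover** — each newly derived EC reverts to a layer-3 FSC with
   `ec_return = 0.24` or is lost with `ec_death = 0.12`.  The 2:1
   return-dominated split reflects the inference that FSCs entering EC
   territory frequently return; the magnitudes were calibrated once so
   the marked-EC count per germarium (among germaria retaining a marked
   FSC) plateaus near ~1.4 by 12 days, matching the observed 1.2 → 1.5
   trajectory.  Both pools obey identical rules, so marking stays
   neutral.  The pre-existing bulk EC population does not turn over and
   is not modeled.
5. **Census rebalancing** — the per-layer census is restored exactly:
   shortfall is refilled by compensatory divisions of uniformly random
   survivors (mark inherited); overflow (a cycle whose newborns exceed
   its losses) cancels uniformly random surviving newborns — divisions
   that found no vacancy, niche capacity limiting effective division;
   residual imbalance moves uniformly random FSCs between adjacent
   layers toward depleted layers.  All rules are mark-blind.

Under control parameters the expected division count is
`8·0.582 + 5·0.349 + 3·0.143 ≈ 6.8` per cycle, realizing the
seven-of-sixteen budget.

**Scoring convention.**  A snapshot reports the layer configuration at the
*start* of the most recent cycle together with that cycle's immediate-FC
output.  This realizes the estimator's own stationarity assumption — the
scored layer-1 FSCs are the cells that were at risk of producing the
observed immediate FCs — and makes the germarium-level no-FC probability
exactly `(1 − P)^k` given `k` (verified by simulation).  Scoring the
end-of-cycle configuration instead would interpose a full census
restoration (replacing ~60% of layer 1 from layer 2) between the at-risk
set and the scored counts; the estimator is then biased low by ≈0.08 —
a useful caution for interpreting real scoring, where the microscopist
sees a germarium at an unknown phase of its cycle.  EdU positivity is
drawn per marked FSC from its layer's index at snapshot time; ECs are
quiescent and never score EdU.  EdU fields are omitted (absent, not
zero) on days without an EdU pulse — by default only day 6, matching the
scoring protocol.  The immediate-FC flag is `marked FC output of the last
cycle ≥ 1`; the any-FC flag uses a 10-cycle residence window (~5 days of
ovariole transit), configurable.

**Cohorts.**  Initial labeling marks each of the 16 FSCs independently
with probability 3.2/16.  Each germarium gets its own random stream
spawned from one root seed sequence, so cohorts are reproducible bit-for-
bit from `(config, seed)` and enlarging a cohort never reshuffles earlier
germaria.  Snapshot days must be whole numbers of 12-hour cycles.

## What the generator does and does not emulate

The synthetic tables reproduce: binomial initial labeling; neutral drift
of the marked-FSC mean with monotonically growing variance and a growing
zero class; the posterior-to-anterior division gradient; steady-state
layer occupancy near 48/32/19%; immediate-FC statistics consistent with
the forward conversion model; and marked-EC accumulation that saturates.
They do not emulate: germline-cyst dynamics or Fas3 expression; radial
position (all FSCs within a layer are equivalent); signaling gradients as
mechanisms (Wnt/JAK-STAT enter only through the phenomenological
per-layer rates); inter-experiment heterogeneity (a real control series
pools 31 experiments with batch effects); fractional steady-state
censuses (7.6/5.3/2.8 are rounded to 8/5/3, slightly raising layer-1
occupancy); or scoring at an unknown cycle phase.  Passing recovery tests
therefore shows the estimator is consistent under its own model
assumptions at realistic sample sizes — not that those assumptions hold
in any particular experiment.

## Problem sizes and numerical choices

Parameter-recovery experiments use cohorts of 1,750 scored germaria,
which yield ≈556 informative ones under control parameters — the
informative sample size of the control series they emulate (556
informative germaria across 31 experiments scoring ≥50 ovarioles each).
A single such cohort recovers p within ±0.05 (estimator SD ≈ 0.024); the
mean bias over 200 replicate cohorts is below 0.01, the residue coming
from k-th-root concavity at finite group sizes.  The neutrality and
drift checks use 600–1,000 germaria over 24 cycles.  Monte-Carlo oracle
checks (single-FSC forward equivalence, k-th-root recovery) use
0.6–1.2 × 10⁵ trials with 3–3.5 SE tolerances.  The quadratic round-trip
is verified to 1e-9 on the full 101 × 101 unit-square grid; probability
clamps only trim float dust at the boundaries.  `q` values above 1 (from
extreme EdU ratios at small samples) are clipped to 1 with a warning
rather than rejected.

## Known limitations

* The estimator is exactly consistent only under the adopted scoring
  convention; end-of-cycle scoring yields a quantifiable downward bias
  (above).
* The EC-turnover split (return vs death) is not identifiable from the
  emulated observables; only the total loss rate is calibrated, and the
  2:1 default is one admissible choice, exposed as two parameters.
* Bootstrap confidence intervals for p̂ (CLI `--bootstrap`) resample
  germaria and inherit the estimator's small-group volatility; they are
  percentile intervals, not bias-corrected.
* Mutant-genotype presets are not built in; any genotype is expressible
  by constructing `CycleParams` directly (e.g. lowered `q_div` and `p_fc`
  with an anterior-shifted census for a STAT-deficient phenotype).
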