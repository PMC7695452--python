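"""Worked control arithmetic: FC yield, founder FCs, EC ratio, reporters.

Each block evaluates one closed-form quantity from the control measurements
and prints what the number means.
"""

from fsclineage import (
    division_probability,
    ec_per_afsc,
    expected_fc_yield,
    founder_fc_per_cycle,
    normalized_pathway_activity,
    percent_increase,
)

# Expected follicle cells produced per 12-hour budding cycle from the
# control layer-1 census (7.6 FSCs) converting at p = 0.616, with the
# census inflated by q/2 because newborn FSCs are present for half a cycle.
q = division_probability(edu_layer1=33.4, edu_overall_control=25.1)
print(f"q (layer-1 division prob.)      : {q:.4f}")
print(f"FC yield, EdU-adjusted q        : {expected_fc_yield(7.6, 0.616, q):.3f} per cycle")
print(f"FC yield, literal q = 7/16      : {expected_fc_yield(7.6, 0.616, 7/16):.3f} per cycle")

# Independent cross-check: a single founder FC's descendants occupy 17.8%
# of the egg-chamber monolayer on average, so ~5.6 founders seed each cyst.
print(f"founder FCs from patch fraction : {founder_fc_per_cycle(0.178):.2f} per cycle")

# Escort-cell production: marked ECs per inferred marked anterior FSC.
r6 = ec_per_afsc(1.2, afsc_control_6d=2.2, afsc_at_t=2.2, period="0-6d")
r12 = ec_per_afsc(1.5, afsc_control_6d=2.2, afsc_at_t=2.7, period="0-12d")
print(f"EC/aFSC ratio 0-6d              : {r6.ratio:.3f}")
print(f"EC/aFSC ratio 0-12d             : {r12.ratio:.3f}")
print(f"increase 6d -> 12d              : {percent_increase(r6.ratio, r12.ratio):.1f}%"
      " (far below the doubling expected without EC loss)")

# Reporter normalization: activity as a multiple of the normal
# pathway-induced level after subtracting the pathway-null baseline.
print(f"JAK-STAT fold (UAS-Hop, 200%)   : {normalized_pathway_activity(200, 40):.2f}x normal")
print(f"Wnt residual (dnTCF, 63.1%)     : {100*normalized_pathway_activity(63.1, 39.4):.1f}% of normal")
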