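"""Significance tests used on clone-scoring proportions.

The 'N-1' chi-squared test compares two scored proportions via a signed z
score; the EdU layer-distribution test asks whether a genotype's
proliferation gradient across the three FSC layers differs from the control
pattern independent of its overall level.
"""

from fsclineage import LayerEduData, edu_layer_distribution_test, n1_chi2_two_proportions, proportion_se

# Two genotypes scored for immediate-FC presence: 25/100 vs 10/100.
result = n1_chi2_two_proportions(25, 100, 10, 100)
print(f"'N-1' chi2 = {result.statistic:.3f}, z = {result.z:+.3f}, p = {result.p_value:.4g}")
print(f"SE of the first proportion: {proportion_se(25, 100):.4f}")
print()

# Control gradient: 33.4/20.0/8.2 % EdU across layers 1-3, layer occupancy
# weights from the control censuses 7.6/5.3/2.8.
weights = (7.6 / 15.7, 5.3 / 15.7, 2.8 / 15.7)
control_edu = (33.4, 20.0, 8.2)
blended = sum(w * e for w, e in zip(weights, control_edu))

# A flattened gradient (uniform EdU at the control overall level, 200 cells
# per layer) against the control pattern:
uniform = int(round(200 * blended / 100))
flat = LayerEduData(layers=((uniform, 200), (uniform, 200), (uniform, 200)))
r = edu_layer_distribution_test(flat, weights, control_edu, blended)
print(f"flattened gradient: chi2 = {r.statistic:.2f}, df = {r.df}, p = {r.p_value:.3g}")

# A gradient proportional to control (half the overall level) is no
# pattern change at all:
half = LayerEduData(layers=((33, 200), (20, 200), (8, 200)))
r = edu_layer_distribution_test(half, weights, control_edu, blended)
print(f"proportional gradient: chi2 = {r.statistic:.3f}, p = {r.p_value:.3g}")
print()
print("A large chi2 with df=2 flags a reshaped proliferation gradient, the")
print("signature of uniform (rather than graded) JAK-STAT pathway activity.")
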