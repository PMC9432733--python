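"""Three-arm group comparison with compact letter display.

Simulates small sham / RF-like / muscimol-like arms, pools each
culture's normalized MBR, and runs the comparison layer: Kruskal-Wallis
omnibus, Conover-Iman all-pairs post-hoc, epsilon-squared effect size
and compact letters (arms sharing a letter are not significantly
different at alpha = 0.05).
"""

from meaburst import ProtocolSpec, builtin_presets, compare_groups, simulate_arm

protocol = ProtocolSpec(baseline_duration=600.0, exposure_duration=300.0,
                        post_duration=600.0, n_channels=12)
presets = builtin_presets()
arms = {}
for i, (name, n) in enumerate({"sham": 4, "rf": 4, "mu": 4}.items()):
    arm = simulate_arm(presets[name], n, seed=11, arm_index=i, protocol=protocol)
    arms[name] = arm["R_MBR"].to_numpy()

res = compare_groups(arms)
print(f"Kruskal-Wallis H = {res.h:.2f}, p = {res.p:.2g}, "
      f"epsilon-squared = {res.eps_squared:.2f}")
print("pairwise Conover p values:")
print(res.pairwise.round(4).to_string())
print("letters:", res.letters)

print("\nDistinct letters for sham and mu mean the muscimol-like suppression"
      " of normalized MBR is statistically separated from sham; epsilon-"
      "squared near 1 marks a near-complete ordering of the groups.")
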