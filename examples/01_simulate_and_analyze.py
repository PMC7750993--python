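"""Simulate twin-pair data from a causal diagram and run the full
bidirectional co-twin regression analysis.

The generating model here is "X causes Y": each trait has a familial
(shared) component, and X has a direct effect on Y.  The analysis fits
three GEE models per direction on the double-entered pairs, bootstraps
the coefficient changes, and maps the joint pattern to a verdict.
"""

from icefalcon import bidirectional, calibrate, interpret, simulate_pairs

# Calibrate the diagram to target within-pair correlations of 0.79 (X)
# and 0.37 (Y) and a cross-trait correlation of 0.30.
spec = calibrate(rho_x=0.79, rho_y=0.37, r_xy=0.30, diagram="b",
                 n_pairs=2000, seed=11)
print("generating spec:", spec, "\n")

data = simulate_pairs(spec)
forward, reverse = bidirectional(data, n_boot=1000, seed=7)

for label, res in (("X -> Y", forward), ("Y -> X", reverse)):
    print(f"direction {label}")
    print(res.to_frame().to_string(index=False, float_format="%.4f"))
    print(f"attenuation: self {res.attenuation_self:.1f}%, "
          f"cotwin {res.attenuation_cotwin:.1f}%\n")

# The causal signature: in the X -> Y direction the cross-pair slope
# attenuates to null while the self slope is unchanged; in the reverse
# direction a conditional cross-pair association emerges.
print(interpret((forward, reverse)))
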