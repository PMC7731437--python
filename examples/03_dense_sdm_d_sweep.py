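"""Sensitivity of SDM cover to the brightness multiplier d.

In a dense standing-dead canopy the lower stratum is shaded and darker
than the sunlit top layer, so at the default d = 1 only the top layer
passes the brightness rule and SDM cover is underestimated. Sweeping
d = 1, 0.7, 0.5 progressively admits the darker stratum.
"""

from quadratcover import generate_quadrat, preprocess_image, scene_preset, sweep_d

quad = generate_quadrat(scene_preset("dense-sdm", seed=1))
img = preprocess_image(quad.image)

curve = sweep_d(img, g1=60.0, g2=60.0, d_values=[1.0, 0.7, 0.5])
print(f"true SDM fraction: {100 * quad.true_fractions['sdm']:.1f}%")
for _, row in curve.iterrows():
    print(f"d = {row['d']:.1f}: extracted SDM cover {row['sdm_cover_pct']:.1f}%")
print("Cover rises as d falls: lowering d recovers the shaded lower "
      "canopy that d = 1 misses.")
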