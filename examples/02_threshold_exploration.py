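"""Choose g1, g2 from reference green-vegetation pixels.

Mirrors the data-exploration step of the workflow: compute min / max /
mean / std of the normalized (G - R) and (G - B) differences over pixels
known to be green vegetation. The minima are the candidate thresholds —
the largest values that still admit every reference pixel.
"""

from quadratcover import explore_gv_thresholds, generate_quadrat, preprocess_image, scene_preset

quad = generate_quadrat(scene_preset("default", seed=1))
img = preprocess_image(quad.image)
reference = quad.label_mask("gv")  # in the field: a hand-drawn GV region

stats = explore_gv_thresholds(img, reference)
print(f"{stats.n_pixels} reference GV pixels")
for name, s in (("g1 (G-R)", stats.g1), ("g2 (G-B)", stats.g2)):
    print(f"{name}: min={s.min:7.2f} max={s.max:7.2f} "
          f"mean={s.mean:7.2f} std={s.std:6.2f}")
print("Pick thresholds at (or just below) the minima; under normal light "
      "they land above 60, which is why 60 is the default.")
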