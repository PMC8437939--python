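"""Follow a shrinking specimen through a synthetic drying sequence.

A square specimen shrinks, bulges outward (convex period), then its
sides cave in (concave collapse) -- the trajectory of the l descriptor
rises above 100 and finally drops below it, with m flagging every
non-uniform frame.
"""

from softshape import analyze_series, apply_swelling, apply_warp, rasterize_reference

square = rasterize_reference("rectangle").image
frames = [
    square,
    apply_swelling(square, 0.92),
    apply_warp(apply_swelling(square, 0.85), 0.20, "convex"),
    apply_warp(apply_swelling(square, 0.78), 0.30, "convex"),
    apply_warp(apply_swelling(square, 0.70), 0.25, "concave"),
]
moisture = [1.0, 0.78, 0.56, 0.36, 0.20]

report = analyze_series(frames, covariates=moisture, method="none")
print(report.to_frame()[["frame", "covariate", "shape", "i", "j", "k", "l", "m"]]
      .round(2).to_string(index=False))
for n, old, new in report.transitions:
    print(f"frame {n}: shape changed {old} -> {new}")
print("i tracks the shrinking area; l > 100 marks the convex (bulging)")
print("period and l < 100 the concave collapse, mirrored by the m flag.")
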