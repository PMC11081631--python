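"""Simulate one cell's z-stack, measure its ROI color, and compute the
logit-normalized brightness.

The printed ΔB is negative because the pigmented disk is darker than the
background; Y = 255 + Δ for a gray cell, and Ynorm is its logit, the
covariate every downstream correlation uses.
"""

from pigcorr import ImageSimParams, brightness_record, generate_cell_image, measure_cell

params = ImageSimParams(pigment_level=0.6, seed=42)  # fairly dark cell
stack = generate_cell_image(params, cell_id="demo_cell")
print(f"stack: {stack.n_planes} planes of {stack.shape[0]}x{stack.shape[1]} px")

record = measure_cell(stack, roi=params.roi)
print(
    "background-subtracted means (dR, dG, dB):",
    record.delta.round(3),
    "across-plane SD:",
    record.delta_sd.round(3),
)

bright = brightness_record(record.cell_id, record.delta)
print(f"Y = {bright.Y:.3f} (0-255 scale; 255 would be background-colored)")
print(f"Ynorm = {bright.Ynorm:.4f} (logit of Y/255; darker cell -> lower value)")
print(f"true in-disk dimming was {params.background_level * params.pigment_level:.0f}")
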