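"""Rasterize one tissue block and segment it back into islet records.

Segmentation thresholds each hormone channel, closes small gaps
(capillaries), and measures every connected islet structure: total area,
sub-pixel circularity, Feret diameter and per-hormone areas.
"""

import isletmorph as im
from isletmorph.synth import render_block

cfg = im.GeneratorConfig(n_blocks=1, section_size_px=(2000, 2000), seed=3)
donor = im.generate_donor(cfg)
image = render_block(donor, 1)

records = im.segment_structures(image, im.SegParams())
tissue = im.tissue_area(image)

print(f"section: {image.shape[1]}x{image.shape[0]} px at "
      f"{image.pixel_size_um} um/px, tissue {tissue:.3e} um^2")
print(f"segmented {len(records)} structures (ground truth: {len(donor.islets)})")
r = max(records, key=lambda r: r.area_um2)
print(f"largest islet: area {r.area_um2:.0f} um^2 "
      f"(d_eff {im.effective_diameter(r.area_um2):.0f} um), "
      f"circularity {r.circularity:.2f}, Feret {r.feret_um:.0f} um, "
      f"beta share {r.beta_area_um2 / r.hormone_area_um2:.2f}")
# Measured areas track the rasterized truth to ~1%; the beta share of
# hormone-positive pixels reflects the size-dependent composition model.
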