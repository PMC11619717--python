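"""Simulate a block-tissue phantom scan and form band-power images.

Builds a small FFPE-block-like phantom (cancer core, fat lobes, one
collagen band in paraffin), scans it with the virtual four-channel
polarimetric scanner on the 41-bin frequency grid, and averages the
reference-normalised spectral intensity of each pixel over 0.5-2.5 THz.
"""

import thzpol as tp

labels = tp.make_label_map(tp.demo_block_phantom(24, 24, collagen_axis_deg=40.0))
optics = tp.default_optics_map("block")
geometry = tp.IncidenceGeometry(theta_deg=30.0)
config = tp.AcquisitionConfig.grid_41(noise_sigma=0.0, epsilon_leakage=0.02, seed=0)

cube = tp.simulate_scan(labels, optics, geometry, config, medium="block")
images = tp.power_spectrum_image(cube, tp.BAND_41)

print("per-class HH band-power means (paraffin reference = 1.0):")
stats = tp.region_stats(images["HH"], labels)
print(stats[["n_pixels", "mean", "std"]].round(4))
print()
print("contrast cancer vs fat:     "
      f"{tp.class_contrast(stats, 'cancer', 'fat'):+.3f}")
print("contrast cancer vs collagen: "
      f"{tp.class_contrast(stats, 'cancer', 'collagen'):+.3f}")
print()
print("Strongly reflecting cancer sits above collagen, which sits above")
print("fat — the ordering that gives co-polarised images their colour")
print("semantics. The paraffin background scores exactly 1 because the")
print("reference trace is recorded on bare paraffin.")
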