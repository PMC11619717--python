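"""Recover a collagen fibre orientation from a sample-rotation sweep.

An oriented fibrous layer acts as a linear retarder: its cross-polarised
reflection scales as sin^2(2(theta0 + phi)) as the sample is rotated by
phi on the scanning window.  The sweep rescans the phantom at each angle
and a linear least-squares fit of that law recovers theta0 (mod 90 deg).
"""

import numpy as np

import thzpol as tp

TRUE_AXIS = 20.0
labels = tp.make_label_map(
    tp.uniform_phantom(tp.TissueClass.COLLAGEN, 8, 8, optic_axis_deg=TRUE_AXIS))
optics = tp.default_optics_map("block")
geometry = tp.IncidenceGeometry()
config = tp.AcquisitionConfig.grid_68(noise_sigma=0.0, epsilon_leakage=0.0, seed=1)

angles = list(range(0, 180, 10))
series = tp.rotation_sweep(labels, optics, geometry, config, angles,
                           channel="VH", mask_classes={tp.TissueClass.COLLAGEN})

print("rotation angle -> cross-pol band power (unnormalised):")
for phi, p in zip(series.angles_deg, series.crosspol_power):
    bar = "#" * int(60 * p / series.crosspol_power.max())
    print(f"  {phi:5.0f} deg  {p:.3e}  {bar}")

fit = tp.estimate_axis_orientation(series)
print(f"\ntrue fibre axis:      {TRUE_AXIS:.1f} deg")
print(f"recovered axis:       {fit.theta0_deg:.2f} deg (mod 90)")
print(f"fit residual (rms):   {fit.residual_rms:.2e}")

# the six-angle protocol: with a near-vertical axis the 130-deg rotation
# brings the fibres closest to 45 deg from the polariser axes
labels87 = tp.make_label_map(
    tp.uniform_phantom(tp.TissueClass.COLLAGEN, 8, 8, optic_axis_deg=87.0))
six = tp.rotation_sweep(labels87, optics, geometry, config,
                        [0, 30, 60, 90, 130, 160],
                        mask_classes={tp.TissueClass.COLLAGEN})
best = six.angles_deg[int(np.argmax(six.crosspol_power))]
print(f"\nsix-angle sweep of an 87-deg axis: strongest cross-pol at "
      f"{best:.0f} deg rotation")
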