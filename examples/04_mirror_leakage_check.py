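"""The gold-mirror sanity check: cross-polarisation from polariser leakage.

A calibration mirror cannot mix polarisations, so any cross-polarised
signal it returns measures the wire-grid polarisers' leakage.  With a
leakage fraction eps on both the emitter and detector side, the channel
matrix becomes [[1+eps^2, 2*eps], [2*eps, 1+eps^2]] and the cross/co
amplitude ratio is exactly 2*eps/(1+eps^2).
"""

import numpy as np

import thzpol as tp

for eps in (0.0, 0.02):
    config = tp.AcquisitionConfig.grid_41(epsilon_leakage=eps, seed=0)
    cube = tp.mirror_scan(config, rows=2, cols=2)
    co = np.abs(cube.channels["VV"]).max()
    cross = np.abs(cube.channels["VH"]).max()
    ratio = cross / co
    print(f"leakage eps = {eps:.2f}:  cross/co amplitude ratio = {ratio:.5f}"
          f"   (closed form {2 * eps / (1 + eps**2):.5f})")

print("\nWith perfect polarisers the mirror's cross-pol channels are")
print("identically zero; 2% leakage puts ~4% of the co-pol amplitude into")
print("them — small but visible, which is why cross-pol imaging of weakly")
print("birefringent tissue needs the leakage figure on record.")
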