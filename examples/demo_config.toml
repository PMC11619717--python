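# Demo configuration for the thzpol CLI.
#   thzpol all -c examples/demo_config.toml -o thzpol_out

[phantom]
rows = 16
cols = 16
step_um = 150.0
collagen_axis_deg = 40.0
medium = "block"
seed = 0

[acquisition]
preset = "grid_41"      # 20 ps window, df = 0.05 THz: 41 bins in 0.5-2.5 THz
noise_sigma = 0.0
n_average = 5
epsilon_leakage = 0.02
seed = 0

[band]
f1 = 0.5
f2 = 2.5

[mueller]
scheme = "emitter"

[rotation]
angles = [0, 30, 60, 90, 130, 160]
channel = "VH"
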