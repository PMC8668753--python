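# Example pipeline configuration: synthetic study at reduced size.
# Availability inputs are generated (no external data needed); all
# randomness flows from the single seed below.
out_dir: msfr_out
seed: 1
synthetic:
  n_hauls: 600
  n_animals: 30
  days: 60
  n_strandings: 300
timeframes: [2, 4, 6, 8]
shape_m: [1.0, 1.5]
chains: 2
iterations: 2000
burn_in: 200
n_boot: 500
buffer_draws: 100
rescale_per_species: true
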