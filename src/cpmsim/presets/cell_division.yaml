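# Proliferation: 20 founder cells seeded in a radius-35 circle around the
# grid midpoint; target volumes grow 2 px/MCS and cells split through the
# centroid (minor-axis line) once they reach twice the base volume.
grid: {width: 500, height: 500}
kinds:
  - {name: cell, color: [255, 200, 0]}
hamiltonian:
  temperature: 20
  adhesion:
    J:
      - [0, 8]
      - [8, 4]
  volume:
    lambda: [0, 50]
    target: [0, 100]
processes:
  - {type: seed_circle, counts: {1: 20}, radius: 35, burn_in: 30}
  - {type: grow_divide, kinds: [1], growth_rate: 2, division_volume: 200}
schedule: {n_mcs: 40000, seed: 0}
outputs: {png_every: 1000, log_every: 100, draw_mode: cell}
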