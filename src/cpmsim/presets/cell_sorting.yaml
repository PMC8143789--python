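# Differential-adhesion cell sorting: two cell types demix because
# heterotypic contacts (J = 11) cost more than the mean homotypic contact
# ((14 + 2) / 2 = 8). Classic Graner-Glazier parameter set.
grid: {width: 200, height: 200}
kinds:
  - {name: light, color: [0, 128, 255]}
  - {name: dark, color: [255, 96, 96]}
hamiltonian:
  temperature: 10
  adhesion:
    J:
      - [0, 16, 16]
      - [16, 14, 11]
      - [16, 11, 2]
  volume:
    lambda: [0, 2, 2]
    target: [0, 40, 40]
processes:
  - {type: seed_circle, counts: {1: 50, 2: 50}, radius: 67, burn_in: 50}
schedule: {n_mcs: 2000, seed: 0}
outputs: {png_every: 100, log_every: 10, draw_mode: kind}
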