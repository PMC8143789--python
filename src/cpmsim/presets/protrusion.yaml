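# Single migrating cell with the protrusion (activity) term, between two
# immutable round obstacles placed 50 px left and right of the cell.
# Parameter set: strongly migratory regime (lambda_act 200, memory 80 MCS).
grid: {width: 200, height: 200}
kinds:
  - {name: cell, color: [64, 200, 120]}
  - {name: obstacle, color: [120, 120, 120], immutable: true}
hamiltonian:
  temperature: 20
  adhesion:
    J:
      - [0, 20, 20]
      - [20, 0, 20]
      - [20, 20, 0]
  volume:
    lambda: [0, 50, 0]
    target: [0, 500, 0]
  perimeter:
    lambda: [0, 2, 0]
    target: [0, 340, 0]
  act:
    lambda: [0, 200, 0]
    max_act: [0, 80, 0]
processes:
  - {type: obstacles, kind: 2, centers: [[50, 100], [150, 100]], radius: 10}
  - {type: seed_disc, kind: 1, radius: 12.6}
schedule: {n_mcs: 15000, seed: 0}
outputs: {png_every: 250, log_every: 10, draw_mode: kind}
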