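# Signal-sensitivity fit: two conditions whose signal offset on the second
# theta component is baseline + sensitivity * s for signal levels s = -1, +1.
# `waddyn fit --config fit.yaml --observed fates.csv --out posterior.csv`
family: elliptic_umbilic
sigma: 0.25
dt: 0.02
conditions:
  - name: s-1
    t_grid: [0.0, 3.0, 4.5]
    theta_knots: [[-2.0, 0.0], [-6.0, 0.0], [-6.0, 0.0]]
  - name: s+1
    t_grid: [0.0, 3.0, 4.5]
    theta_knots: [[-2.0, 0.0], [-6.0, 0.0], [-6.0, 0.0]]
fit:
  parameters:
    - name: baseline
      component: 1
      low: -0.3
      high: 0.3
    - name: sensitivity
      component: 1
      low: -0.3
      high: 0.3
      condition_weights: {"s-1": -1.0, "s+1": 1.0}
  n_particles: 200
  n_generations: 4
  n_cells: 100
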