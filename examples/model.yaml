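# Symmetric binary-flip landscape driven through the progenitor-destroying
# fold: the control parameter a ramps from the tristable regime (-2) to -6
# and holds while the cells settle into the two committed fates.
family: elliptic_umbilic
theta: [-1.0, 0.1]
sigma: 0.2
dt: 0.02
conditions:
  - name: ramp
    t_grid: [0.0, 3.0, 4.5]
    theta_knots: [[-2.0, 0.0], [-6.0, 0.0], [-6.0, 0.0]]
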