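{
  "_comment": "Bystander-help scan of the canonical 4-click. Below the switch the suppressive (Tr1) response holds; above it the cytotoxic (Tc) response; transition_h pins the sensitive switch point where twin trajectories diverge (positive Lyapunov estimate). bistable_h is a level at which random initial conditions split between both outcomes.",
  "assembly": {"fixture": "fig1_4click"},
  "backend": "ode",
  "ode": {"t_end": 800.0, "n_samples": 801},
  "scan": {
    "h_grid": [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.042906, 4.5, 5.0],
    "transition_h": 4.042906,
    "stable_low_h": 3.0,
    "stable_high_h": 5.0,
    "bistable_h": 3.75,
    "lag": 1,
    "n_inits": 50
  },
  "seed": 0
}
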