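{
  "_comment": "Resting-state run of the canonical 4-click (no bystander help): converges to a stable coexistence dominated by Tr1; the Tr1 trajectory peaks near 0.9 on the normalized response scale. t_end 2500 lets the slowly damped oscillation (dominant eigenvalue about -0.004 +/- 0.065i) settle below the convergence threshold.",
  "assembly": {"fixture": "fig1_4click"},
  "backend": "ode",
  "ode": {"t_end": 2500.0, "n_samples": 2501},
  "seed": 0
}
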