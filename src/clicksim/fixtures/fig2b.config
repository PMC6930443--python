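{
  "_comment": "Tnk-knockdown preset: Tnk starts absent and the Tc->Tnk maturation rate is reduced five-fold. Without Tnk control the helper lineage surges, Th suppresses Tr1, and the cytotoxic response takes over (Tc_dominant).",
  "assembly": {
    "fixture": "fig1_4click",
    "overrides": {
      "Tnk.initial_abundance": 0.0,
      "Tc->Tnk.maturation_rate": 0.03068
    }
  },
  "backend": "ode",
  "ode": {"t_end": 800.0, "n_samples": 801},
  "seed": 0
}
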