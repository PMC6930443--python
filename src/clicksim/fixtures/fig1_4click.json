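{
  "_comment": "Canonical 4-click: cytotoxic (Tc -> Tnk) and type-1 helper (Th -> Tr1) lineages wired as a directed kill cycle. Rates are the shipped calibrated defaults (arbitrary time units, abundances on the normalized response scale); under these values the resting state (help level 0) is a stable coexistence dominated by Tr1.",
  "populations": [
    {
      "id": "Tc",
      "lineage": "cytotoxic",
      "stage": "young",
      "growth_rate": 4.9501,
      "death_rate": 0.202,
      "help_coefficient": 1.4832,
      "initial_abundance": 0.05
    },
    {
      "id": "Tnk",
      "lineage": "cytotoxic",
      "stage": "mature",
      "growth_rate": 0.8166,
      "death_rate": 0.0904,
      "help_coefficient": 0.0,
      "initial_abundance": 0.05
    },
    {
      "id": "Th",
      "lineage": "helper",
      "stage": "young",
      "growth_rate": 7.2624,
      "death_rate": 0.0603,
      "help_coefficient": 1.4485,
      "initial_abundance": 0.05
    },
    {
      "id": "Tr1",
      "lineage": "helper",
      "stage": "mature",
      "growth_rate": 0.4935,
      "death_rate": 0.0916,
      "help_coefficient": 0.0,
      "initial_abundance": 0.05
    }
  ],
  "kill_edges": [
    {"killer": "Tc", "victim": "Tnk", "kill_rate": 2.4283, "mechanism": "antigen trogocytosis"},
    {"killer": "Tnk", "victim": "Th", "kill_rate": 3.1428, "mechanism": "NK receptor"},
    {"killer": "Th", "victim": "Tr1", "kill_rate": 0.6261, "mechanism": "Fas/FasL"},
    {"killer": "Tr1", "victim": "Tc", "kill_rate": 0.4254, "mechanism": "CTLA4 transendocytosis"}
  ],
  "maturation_edges": [
    {"source": "Tc", "target": "Tnk", "rate": 0.1534},
    {"source": "Th", "target": "Tr1", "rate": 0.7322}
  ],
  "bystander_inputs": [
    {"target": "Th", "help_level": 0.0},
    {"target": "Tc", "help_level": 0.0}
  ],
  "carrying_capacity": 1.3077
}
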