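{
  "components": {
    "docked": {"mean": 29.3, "sigma": 2.0, "label": "docked"},
    "undocked": {"mean": 39.5, "sigma": 6.7, "label": "undocked"},
    "ilov": {"mean": 44.0, "sigma": 12.0, "label": "other"}
  },
  "variants": [
    {"name": "WT_light", "radical": "ASQ", "docked": "docked", "undocked": "undocked", "fraction_undocked": 1.0},
    {"name": "EN_dark", "radical": "NSQ", "docked": "docked", "undocked": "undocked", "fraction_undocked": 0.0},
    {"name": "H378R_light", "radical": "ASQ", "docked": "docked", "undocked": "undocked", "fraction_undocked": 0.81},
    {"name": "H378K_light", "radical": "ASQ", "docked": "docked", "undocked": "undocked", "fraction_undocked": 0.91},
    {"name": "H378N_light", "radical": "ASQ", "docked": "docked", "undocked": "undocked", "fraction_undocked": 0.95},
    {"name": "H378R_EN_dark", "radical": "NSQ", "docked": "docked", "undocked": "undocked", "fraction_undocked": 0.47},
    {"name": "H378K_EN_dark", "radical": "NSQ", "docked": "docked", "undocked": "undocked", "fraction_undocked": 0.57},
    {"name": "H378N_EN_dark", "radical": "NSQ", "docked": "docked", "undocked": "undocked", "fraction_undocked": 0.63},
    {"name": "iLOV", "radical": "NSQ", "docked": null, "undocked": "ilov", "fraction_undocked": 1.0}
  ]
}
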