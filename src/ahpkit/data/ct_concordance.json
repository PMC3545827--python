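{
  "responders": ["radiology", "ear_surgery", "neurology", "emergency_neurology", "emergency"],
  "note": "Published upper-triangle Spearman rho (p) values; null marks entries the source suppressed as non-significant.",
  "categories": {
    "radiology|ear_surgery": null,
    "radiology|neurology": null,
    "radiology|emergency_neurology": {"rho": 1.0, "p": 0.040},
    "radiology|emergency": {"rho": 1.0, "p": 0.040},
    "ear_surgery|neurology": {"rho": 1.0, "p": 0.040},
    "ear_surgery|emergency_neurology": null,
    "ear_surgery|emergency": null,
    "neurology|emergency_neurology": null,
    "neurology|emergency": null,
    "emergency_neurology|emergency": {"rho": 1.0, "p": 0.040}
  },
  "needs": {
    "radiology|ear_surgery": {"rho": 0.73, "p": 0.004},
    "radiology|neurology": null,
    "radiology|emergency_neurology": {"rho": 0.82, "p": 0.001},
    "radiology|emergency": {"rho": 0.77, "p": 0.002},
    "ear_surgery|neurology": {"rho": 0.86, "p": 0.000},
    "ear_surgery|emergency_neurology": {"rho": 0.74, "p": 0.003},
    "ear_surgery|emergency": {"rho": 0.61, "p": 0.018},
    "neurology|emergency_neurology": null,
    "neurology|emergency": null,
    "emergency_neurology|emergency": {"rho": 0.90, "p": 0.000}
  }
}
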