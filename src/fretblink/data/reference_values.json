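{
  "mEos3.2-JF646": {
    "donor": "mEos3.2",
    "acceptor": "JF646",
    "tau_donor_ns": 3.6,
    "tau_donor_acceptor_ns": 1.8,
    "fret_efficiency": 0.49,
    "forster_radius_nm": 6.01,
    "donor_quantum_yield": 0.55,
    "acceptor_extinction_max_per_M_cm": 152000,
    "photon_budget_donor": 20000,
    "photon_budget_pair": 94000,
    "switching_events_donor": 1.56,
    "switching_events_pair": 1.74,
    "intensity_reduction_percent": 39,
    "localization_precision_donor_nm": 15,
    "localization_precision_pair_nm": 28
  },
  "PA-JF549-JF646": {
    "donor": "PA-JF549",
    "acceptor": "JF646",
    "tau_donor_ns": 2.9,
    "tau_donor_acceptor_ns": 2.1,
    "fret_efficiency": 0.28,
    "forster_radius_nm": 5.81,
    "donor_quantum_yield": 0.88,
    "acceptor_extinction_max_per_M_cm": 152000,
    "intensity_reduction_percent": 19,
    "localization_precision_donor_nm": 11.9,
    "localization_precision_pair_nm": 13.3
  }
}
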