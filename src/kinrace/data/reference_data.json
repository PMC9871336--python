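{
  "description": "Published measurement summaries for KIF1A / kinesin-1 loop-12 constructs (BRB80 and BRB12 buffers, pH 6.9), used as worked-example inputs and for ledger validation.",
  "table1": [
    {"construct": "1A_393", "dwell_s": 1.8, "dwell_ci": 0.08, "run_length_um": 3.0, "run_length_ci": 0.02},
    {"construct": "1A-K1L12", "dwell_s": 0.3, "dwell_ci": 0.03, "run_length_um": 0.5, "run_length_ci": 0.004},
    {"construct": "Kin1", "dwell_s": 1.5, "dwell_ci": 0.1, "run_length_um": 0.8, "run_length_ci": 0.02},
    {"construct": "K1-1AL12", "dwell_s": 1.4, "dwell_ci": 0.1, "run_length_um": 0.9, "run_length_ci": 0.02}
  ],
  "loop12_ledger": [
    {"construct": "WT", "lysine_count": 6, "net_charge": 4, "parent": null},
    {"construct": "SuperK", "lysine_count": 9, "net_charge": 7, "parent": "WT"},
    {"construct": "K1L12", "lysine_count": 1, "net_charge": 1, "parent": null},
    {"construct": "4Q", "lysine_count": 2, "net_charge": 0, "parent": "WT"},
    {"construct": "5Q", "lysine_count": 1, "net_charge": -1, "parent": "WT"}
  ],
  "charge_run_length": {
    "BRB12": [
      {"construct": "1A_393", "net_charge": 4, "run_length_um": 14.3, "run_length_ci": 0.4},
      {"construct": "1A-K1L12", "net_charge": 1, "run_length_um": 6.7, "run_length_ci": 0.1},
      {"construct": "4Q", "net_charge": 0, "run_length_um": 2.6, "run_length_ci": 0.1},
      {"construct": "5Q", "net_charge": -1, "run_length_um": 1.2, "run_length_ci": 0.1}
    ],
    "BRB80": [
      {"construct": "SuperK", "net_charge": 7, "run_length_um": 5.6, "run_length_ci": 0.05},
      {"construct": "1A_393", "net_charge": 4, "run_length_um": 3.0, "run_length_ci": 0.02},
      {"construct": "1A-K1L12", "net_charge": 1, "run_length_um": 0.5, "run_length_ci": 0.004},
      {"construct": "4Q", "net_charge": 0, "run_length_um": null, "run_length_ci": null, "note": "N.D. in BRB80"},
      {"construct": "5Q", "net_charge": -1, "run_length_um": null, "run_length_ci": null, "note": "N.D. in BRB80"}
    ]
  },
  "buffers": [
    {
      "name": "BRB80",
      "pipes_mM": 80,
      "ionic_strength_mM": 184,
      "note": "80 mM PIPES, 1 mM EGTA, 1 mM MgCl2, 2 mM MgATP, pH 6.9; printed ionic strength (speciation computed externally)."
    },
    {
      "name": "BRB12",
      "pipes_mM": 12,
      "ionic_strength_mM": 36,
      "note": "12 mM PIPES, 1 mM EGTA, 1 mM MgCl2, 2 mM MgATP, pH 6.9; printed ionic strength (speciation computed externally)."
    }
  ],
  "affinity_constants": {
    "1A_393": {"K_D_ADP_uM": [1.3, 0.8], "K_D_ATP_uM": [1.7, 1.0], "k_on_Mt_BRB80": [10.6, 0.5]},
    "1A-K1L12": {"K_D_ADP_uM": [5.1, 4.3], "K_D_ATP_uM": [7.2, 5.1], "k_on_Mt_BRB80": [9.1, 2.5]}
  },
  "velocity_um_s": {"1A_393_BRB80": 1.7},
  "run_length_fold_pair_um": {"numerator": [3.0, 0.02], "denominator": [0.5, 0.004]}
}
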