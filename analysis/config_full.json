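{
  "cohort": {
    "n_per_group": [59, 80, 19],
    "sampling_rate": 2500.0,
    "epoch_ms": 8000.0,
    "n_epochs": 4,
    "score_effect": 0.7
  },
  "emd": {"ensemble_size": 50},
  "target_rate": 500.0,
  "n_perm": 5000,
  "cv_folds": 10,
  "final_k": 3,
  "seed": 1,
  "out_dir": "results/full"
}
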