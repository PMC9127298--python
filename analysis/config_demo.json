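{
  "cohort": {
    "n_per_group": [3, 2, 2],
    "sampling_rate": 256.0,
    "epoch_ms": 2000.0,
    "n_epochs": 2,
    "score_effect": 0.0
  },
  "emd": {"ensemble_size": 3},
  "target_rate": 128.0,
  "n_perm": 200,
  "cv_folds": 2,
  "final_k": 3,
  "seed": 7,
  "out_dir": "results/demo"
}
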