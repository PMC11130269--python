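{
  "required": {
    "models": "object",
    "n_scenarios": "int",
    "plsr_components": "int"
  },
  "model_metrics": ["rmse_median", "rmse_p2_5", "rmse_p97_5"]
}
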