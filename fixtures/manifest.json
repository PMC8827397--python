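{
  "command": "simulate",
  "preset": "smoke",
  "seed": 1,
  "n_cores": 12,
  "n_years": 30,
  "start_year": 1987,
  "treesam_version": "0.1.0"
}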