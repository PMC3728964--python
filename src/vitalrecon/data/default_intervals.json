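{
  "_comment": "Default per-parameter sampling intervals for artificial species. These are this package's own choice: wide enough that every vital rate can increase, decrease or stay flat in size and in time, while random draws remain demographically viable over a 100-year horizon.",
  "surv_icpt": [0.0, 1.5],
  "surv_size": [-0.3, 0.5],
  "surv_time": [-0.008, 0.008],
  "surv_size_time": [-0.0015, 0.0015],
  "grow_icpt": [0.05, 0.4],
  "grow_size": [0.7, 0.95],
  "grow_time": [-0.0015, 0.0015],
  "grow_size_time": [-0.0004, 0.0004],
  "grow_sd": [0.15, 0.35],
  "fec_icpt": [-2.5, -0.5],
  "fec_size": [-0.2, 0.5],
  "fec_time": [-0.008, 0.008],
  "fec_size_time": [-0.0015, 0.0015],
  "off_icpt": [0.2, 0.8],
  "off_time": [-0.002, 0.002],
  "off_sd": [0.15, 0.35],
  "smax_icpt": [-4.0, 0.0],
  "smax_time": [-0.03, 0.03]
}
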