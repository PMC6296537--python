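{
  "version": 1,
  "description": "Default red/white discrimination cutoffs for the four headline parameters. direction 'below' means values strictly below the cutoff are classified red; 'above' means strictly above.",
  "cutoffs": {
    "median_attenuation": {"cutoff": 0.568, "direction": "below", "units": "mm^-1"},
    "mean_backscatter": {"cutoff": 5.35, "direction": "below", "units": ""},
    "mean_grayscale": {"cutoff": 120.1, "direction": "below", "units": "native grayscale"},
    "att95_over_median_grayscale": {"cutoff": 0.022, "direction": "above", "units": "mm^-1"}
  }
}
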