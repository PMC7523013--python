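# Example scenario config for `olfnav simulate` / `olfnav pipeline`.
# Any ScenarioConfig field can be overridden; unknown keys are rejected.
seed: 42
days: 6
n_birds: 100
coast_lon: 10.25
westward_bias_coeff: 0.9
track_duration_min: 15.0
synoptic_dir: 270.0
synoptic_kappa: 1.0
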